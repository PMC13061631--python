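"""Ensemble tree-SHAP attribution of per-residue contributions."""

import numpy as np
import pytest
import xgboost as xgb

from pepagg import synthdata
from pepagg.alphabet import AA_ORDER, vector_from_mapping
from pepagg.attribution import (
    ContributionReport,
    ShapEnsembleModel,
    dipeptide_attribution,
    rank_amino_acids,
    shap_ensemble,
    tree_shap_values,
)
from pepagg.encoders import dipeptide_feature_names, encode_records


def _planted_dataset(beta_map, n=800, seed=0, noise=0.0):
    beta = vector_from_mapping(beta_map)
    cfg = synthdata.SyntheticConfig(n_peptides=n, beta=beta, label_noise=noise, seed=seed)
    recs = synthdata.planted_labels(synthdata.sample_peptides(cfg), cfg)
    return encode_records(recs, "composition")


class TestLocalAccuracy:
    def test_shap_sums_to_model_margin(self):
        """Exact TreeSHAP: per-sample contributions plus the base value
        reproduce the model's log-odds output (float32 rounding)."""
        ds = _planted_dataset({"V": 3.0, "F": -3.0}, n=300)
        model = xgb.XGBClassifier(n_estimators=60, random_state=0, n_jobs=1, tree_method="hist")
        model.fit(ds.X, ds.y)
        values, base = tree_shap_values(model, ds.X)
        margins = model.get_booster().predict(xgb.DMatrix(ds.X), output_margin=True)
        np.testing.assert_allclose(values.sum(axis=1) + base, margins, atol=1e-5)


class TestShapEnsemble:
    def test_planted_signs_recovered(self):
        ds = _planted_dataset({"V": 2.0, "F": -2.0}, n=1000, seed=1)
        report = shap_ensemble(ds.X, ds.y, n_splits=20, seed=1)
        assert report.mean_shap["V"] > 0
        assert report.mean_shap["F"] < 0

    def test_deterministic_under_fixed_seed(self):
        ds = _planted_dataset({"V": 2.0, "F": -2.0}, n=300, seed=2)
        r1 = shap_ensemble(ds.X, ds.y, n_splits=5, seed=9)
        r2 = shap_ensemble(ds.X, ds.y, n_splits=5, seed=9)
        assert r1.mean_shap == r2.mean_shap
        assert r1.ranking == r2.ranking

    def test_null_labels_give_small_attributions(self):
        """With labels independent of features every residue's mean |SHAP|
        sits below a permutation-null noise floor."""
        ds = _planted_dataset({}, n=600, seed=3)  # beta = 0: labels are coin flips
        report = shap_ensemble(ds.X, ds.y, n_splits=10, seed=3)
        rng = np.random.default_rng(3)
        null_max = []
        for k in range(5):
            y_perm = rng.permutation(ds.y)
            if y_perm.sum() in (0, len(y_perm)):
                continue
            null = shap_ensemble(ds.X, y_perm, n_splits=10, seed=100 + k)
            null_max.append(max(abs(v) for v in null.mean_shap.values()))
        floor = 2.0 * max(null_max)
        assert max(abs(v) for v in report.mean_shap.values()) <= floor

    def test_curves_defined_only_on_observed_proportions(self):
        ds = _planted_dataset({"V": 2.0}, n=300, seed=4)
        report = shap_ensemble(ds.X, ds.y, n_splits=5, seed=4)
        j = AA_ORDER.index("V")
        observed = ds.X[ds.X[:, j] > 0, j]
        curve = report.curves["V"]
        assert curve.grid.size > 0
        assert curve.grid.min() >= observed.min() - 1e-12
        assert curve.grid.max() <= observed.max() + 1e-12

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).dirichlet(np.ones(20), size=30)
        with pytest.raises(ValueError):
            ShapEnsembleModel(X, np.ones(30, dtype=int))


class TestEnsembleStability:
    def test_split_averaging_stabilises_rankings(self):
        """Rankings from two disjoint half-datasets agree better (higher
        Kendall tau, averaged over replicates) with 50-split ensembles
        than with a single split."""
        from scipy.stats import kendalltau

        from pepagg.benchmarks import ATTRIBUTION_BETA

        taus = {50: [], 1: []}
        for seed in range(10):
            cfg = synthdata.SyntheticConfig(n_peptides=1000,
                                            beta=ATTRIBUTION_BETA.copy() * 0.4,
                                            label_noise=0.05, seed=seed)
            recs = synthdata.planted_labels(synthdata.sample_peptides(cfg), cfg)
            ds = encode_records(recs, "composition")
            half = len(ds.X) // 2

            def ranking(X, y, n_splits, s):
                rep = shap_ensemble(X, y, n_splits=n_splits, seed=s)
                return [rep.ranking.index(aa) for aa in AA_ORDER]

            for ns in (50, 1):
                ra = ranking(ds.X[:half], ds.y[:half], ns, seed)
                rb = ranking(ds.X[half:], ds.y[half:], ns, seed + 1000)
                taus[ns].append(kendalltau(ra, rb).statistic)
        assert np.mean(taus[50]) > np.mean(taus[1])


class TestRanking:
    def _report(self, mean_shap):
        names = list(AA_ORDER)
        ranking = sorted(names, key=lambda f: (-mean_shap[f], f))
        signs = {f: "+" if mean_shap[f] > 0 else "-" if mean_shap[f] < 0 else "0"
                 for f in names}
        return ContributionReport(
            feature_names=names, mean_shap=mean_shap,
            sd_over_splits={f: 0.0 for f in names}, ranking=ranking, signs=signs,
            curves={}, n_splits=1, seed=0,
        )

    def test_head_and_tail(self):
        shap = {f: 0.0 for f in AA_ORDER}
        shap["V"], shap["F"] = 0.3, -0.3
        ranked = rank_amino_acids(self._report(shap))
        assert ranked[0] == ("V", "+")
        assert ranked[-1] == ("F", "-")

    def test_all_zero_is_alphabetical_and_zero_tagged(self):
        ranked = rank_amino_acids(self._report({f: 0.0 for f in AA_ORDER}))
        assert [f for f, _ in ranked] == list(AA_ORDER)
        assert {s for _, s in ranked} == {"0"}


class TestDipeptideAttribution:
    def test_planted_motif_ranks_high(self):
        """Labels boosted by the presence of a Gly-Ser motif put GS at the
        top of the motif ranking."""
        cfg = synthdata.SyntheticConfig(n_peptides=800, beta=np.zeros(20),
                                        label_noise=0.0, seed=6)
        recs = synthdata.sample_peptides(cfg)
        rng = np.random.default_rng(6)
        labelled = []
        for rec in recs:
            p = 0.85 if "GS" in rec.sequence else 0.25
            labelled.append(rec.__class__(id=rec.id, sequence=rec.sequence,
                                          source=rec.source,
                                          sequence_label=bool(rng.random() < p)))
        ds = encode_records(labelled, "dipeptide")
        report = dipeptide_attribution(ds.X, ds.y, dipeptide_feature_names(),
                                       n_splits=10, seed=6)
        assert "GS" in report.top(5)

    def test_absent_motif_has_zero_contribution(self):
        ds = _planted_dataset({"V": 2.0}, n=200, seed=7)
        # recode as dipeptide features where motif "WW" never occurs
        cfg = synthdata.SyntheticConfig(n_peptides=200, seed=7)
        recs = synthdata.planted_labels(synthdata.sample_peptides(cfg), cfg)
        recs = [r for r in recs if "WW" not in r.sequence]
        dds = encode_records(recs, "dipeptide")
        report = dipeptide_attribution(dds.X, dds.y, dipeptide_feature_names(),
                                       n_splits=5, seed=7)
        assert report.mean_shap["WW"] == 0.0
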