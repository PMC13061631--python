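"""Aggregation-propensity prediction and substitution recommendation.

An ensemble of XGBoost classifiers (100 by default), each trained on a
different seeded 80% subsample of the composition-encoded dataset,
predicts a sequence's aggregation propensity as the fraction of members
voting "aggregating".  For a sequence called aggregating, the
recommender ranks single aggregation-reducing substitutions in the
resin-proximal window (positions 2–12 counted from the C terminus),
where on-resin aggregation is decided.

The aggregation-reducing tool modelled here is the pseudoproline
building block: Ser and Thr can be coupled as proline-like dipeptide
derivatives that disrupt beta-sheet formation and revert to the native
residue on global deprotection.  In composition space this is
surrogated as transferring the residue's count to proline.  Because a
composition model is position-blind, a candidate position is scored on
the growing-chain prefixes that actually contain it: for every
synthesis prefix of length >= 6 including the position, the ensemble
vote fraction is computed for the original and the substituted
sequence, and the candidate's score is the drop in the worst-case
(maximum) prefix vote.  Candidates are ranked by score, ties going to
the position closer to the resin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .alphabet import require_canonical
from .curation import PeptideRecord
from .encoders import EncoderConfig, composition_vector, encode_records

__all__ = [
    "AggregationEnsemble",
    "AggregationEnsembleResults",
    "Candidate",
    "Recommendation",
    "train_ensemble",
    "predict_aggregation",
    "recommend",
]

RESIN_WINDOW = (2, 12)
MIN_PREFIX = 6
REPLACEABLE_DEFAULT = frozenset("ST")

#: Default member configuration: depth-1 (additive) boosting with mild
#: regularisation.  Aggregation propensity on composition vectors is a
#: sum of per-residue effects, and additive members both match that
#: structure and keep counterfactual substitution scores monotone where
#: deep default trees produce spurious local reversals.  Pass
#: ``member_params={}`` for plain library-default XGBoost members.
DEFAULT_MEMBER_PARAMS: dict = {
    "max_depth": 1,
    "n_estimators": 300,
    "learning_rate": 0.1,
    "min_child_weight": 10,
    "reg_lambda": 10.0,
}


@dataclass(frozen=True)
class Candidate:
    """One ranked substitution: replace ``residue`` at ``position``
    (1-based from the resin) with ``substitution``."""

    position: int
    residue: str
    substitution: str
    original_vote: float  # max prefix vote fraction, original sequence
    counterfactual_vote: float  # same prefixes, substituted sequence
    score: float  # original_vote − counterfactual_vote


@dataclass
class Recommendation:
    sequence: str
    vote_fraction: float
    verdict: bool
    candidates: list[Candidate] = field(default_factory=list)
    no_substitutable_positions: bool = False

    def summary(self) -> str:
        verdict = "aggregating" if self.verdict else "non-aggregating"
        lines = [
            f"sequence (N->C): {self.sequence}",
            f"ensemble vote fraction: {self.vote_fraction:.2f} -> {verdict}",
        ]
        if self.verdict and self.no_substitutable_positions:
            lines.append("no substitutable positions in the resin-proximal window")
        for rank, c in enumerate(self.candidates, start=1):
            lines.append(
                f"  #{rank}: {c.residue}{c.position} (from resin) -> {c.substitution}  "
                f"max prefix vote {c.original_vote:.2f} -> {c.counterfactual_vote:.2f}  "
                f"score {c.score:+.2f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "position_from_resin": c.position,
                    "residue": c.residue,
                    "substitution": c.substitution,
                    "original_vote": c.original_vote,
                    "counterfactual_vote": c.counterfactual_vote,
                    "score": c.score,
                }
                for i, c in enumerate(self.candidates)
            ]
        )


class AggregationEnsemble:
    """Model: an n-member XGBoost voting ensemble on composition features.

    Parameters
    ----------
    X, y
        Composition-encoded feature matrix (20 columns in alphabetical
        residue order) and binary sequence-level labels.
    n_members
        Ensemble size (100 by default).
    subsample
        Fraction of the data each member trains on (seeded random
        subsample without replacement).
    member_params
        XGBoost keyword overrides for every member; defaults to
        :data:`DEFAULT_MEMBER_PARAMS` (additive boosting), ``{}`` gives
        library-default members.
    sign_consistent
        If True (default), a pilot logistic fit on the full data learns
        each composition feature's direction and every member is trained
        under the matching monotone constraint.  Members then agree with
        their own global trend everywhere, which makes counterfactual
        substitution scores provably monotone in the learned directions
        — unconstrained trees show spurious local reversals that corrupt
        candidate ranking on small datasets.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_members: int = 100,
                 subsample: float = 0.8, encoder: EncoderConfig | None = None,
                 member_params: dict | None = None, sign_consistent: bool = True):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y).astype(int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-d with one label per row")
        if len(np.unique(self.y)) < 2:
            raise ValueError("labels contain a single class")
        if n_members < 1:
            raise ValueError("n_members must be positive")
        if not (0.0 < subsample <= 1.0):
            raise ValueError("subsample must lie in (0, 1]")
        self.n_members = int(n_members)
        self.subsample = subsample
        self.encoder = encoder or EncoderConfig()
        self.member_params = dict(DEFAULT_MEMBER_PARAMS) if member_params is None else dict(member_params)
        self.sign_consistent = sign_consistent

    @classmethod
    def from_records(cls, records: list[PeptideRecord], n_members: int = 100,
                     subsample: float = 0.8, encoder: EncoderConfig | None = None) -> "AggregationEnsemble":
        ds = encode_records(records, "composition", encoder)
        return cls(ds.X, ds.y, n_members=n_members, subsample=subsample, encoder=ds.config)

    def _learned_directions(self) -> tuple[int, ...]:
        """Per-feature monotone directions from a pilot logistic fit.

        Composition features live on the simplex, so only coefficient
        contrasts are identified; signs are read off the mean-centred
        coefficients."""
        from sklearn.linear_model import LogisticRegression

        pilot = LogisticRegression(max_iter=2000).fit(self.X, self.y)
        coef = pilot.coef_[0] - pilot.coef_[0].mean()
        return tuple(int(np.sign(c)) for c in coef)

    def fit(self, seed: int = 0) -> "AggregationEnsembleResults":
        """Train all members on seeded subsamples; returns the Results
        object carrying the fitted members and the seed manifest."""
        n = len(self.X)
        k = max(1, int(round(self.subsample * n)))
        members, member_seeds, manifest = [], [], []
        constraints = self._learned_directions() if self.sign_consistent else None
        if constraints is not None:
            manifest.append(f"monotone directions (pilot logistic): {constraints}")
        for i in range(self.n_members):
            derived = (seed + i) & 0x7FFFFFFF
            attempt = 0
            while True:
                rng = np.random.default_rng(derived)
                idx = rng.choice(n, size=k, replace=False)
                if len(np.unique(self.y[idx])) > 1 or k == n:
                    break
                # single-class subsample: retry with the next derived seed
                attempt += 1
                manifest.append(f"member {i}: single-class subsample at seed {derived}, resampled")
                derived = (derived + self.n_members) & 0x7FFFFFFF
                if attempt > 100:
                    raise ValueError("could not draw a two-class subsample")
            extra = {} if constraints is None else {"monotone_constraints": constraints}
            model = XGBClassifier(random_state=derived, n_jobs=1, tree_method="hist",
                                  verbosity=0, **extra, **self.member_params)
            model.fit(self.X[idx], self.y[idx])
            members.append(model)
            member_seeds.append(derived)
        return AggregationEnsembleResults(
            members=members, member_seeds=member_seeds, encoder=self.encoder,
            master_seed=seed, manifest=manifest,
        )


@dataclass
class AggregationEnsembleResults:
    """Fitted ensemble: vote-fraction prediction plus recommendation."""

    members: list
    member_seeds: list[int]
    encoder: EncoderConfig
    master_seed: int
    manifest: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def _votes_matrix(self, compositions: np.ndarray) -> np.ndarray:
        """Fraction of members voting aggregating, per row."""
        votes = np.zeros(len(compositions))
        for m in self.members:
            votes += m.predict(compositions).astype(float)
        return votes / self.n_members

    def vote_fraction(self, sequence: str) -> float:
        """Fraction of ensemble members predicting aggregation."""
        require_canonical(sequence)
        comp = composition_vector(sequence, self.encoder)[None, :]
        return float(self._votes_matrix(comp)[0])

    def predict(self, sequence: str) -> tuple[float, bool]:
        """(vote fraction, verdict); aggregating iff strictly > 0.5."""
        vf = self.vote_fraction(sequence)
        return vf, vf > 0.5

    def synthesis_vote_fraction(self, sequence: str) -> float:
        """Worst-case growing-chain vote: the maximum ensemble vote
        fraction over all synthesis prefixes of length >= 6, i.e. the
        position-aware aggregation propensity of actually synthesizing
        the sequence C→N."""
        require_canonical(sequence)
        synth = sequence[::-1]
        lengths = range(min(MIN_PREFIX, len(synth)), len(synth) + 1)
        comps = np.stack([composition_vector(synth[:L][::-1], self.encoder) for L in lengths])
        return float(self._votes_matrix(comps).max())

    def recommend(
        self,
        sequence: str,
        replaceable: frozenset[str] | set[str] = REPLACEABLE_DEFAULT,
        window: tuple[int, int] = RESIN_WINDOW,
        substitution: str = "P",
    ) -> Recommendation:
        """Rank single substitutions in the resin-proximal window.

        ``sequence`` is written N→C; positions are counted 1-based from
        the resin (C terminus).  Only positions inside ``window`` whose
        residue is in ``replaceable`` become candidates; each is scored
        by the drop in the maximum ensemble vote fraction over all
        synthesis prefixes of length >= 6 that contain the position.
        """
        require_canonical(sequence)
        if len(sequence) < 5:
            raise ValueError("sequence must have at least 5 residues")
        if not replaceable:
            raise ValueError("replaceable residue set must be non-empty")
        vf, verdict = self.predict(sequence)
        rec = Recommendation(sequence=sequence, vote_fraction=vf, verdict=verdict)
        if not verdict:
            return rec

        n = len(sequence)
        synth = sequence[::-1]  # synthesis order, index 0 = resin position 1
        lo, hi = window
        positions = [p for p in range(max(lo, 1), min(hi, n) + 1)
                     if synth[p - 1] in replaceable]
        if not positions:
            rec.no_substitutable_positions = True
            return rec

        # vote fraction of every original prefix of length >= MIN_PREFIX
        prefix_lengths = list(range(MIN_PREFIX, n + 1))
        orig_comps = np.stack([composition_vector(synth[:L][::-1], self.encoder)
                               for L in prefix_lengths])
        orig_votes = dict(zip(prefix_lengths, self._votes_matrix(orig_comps)))

        candidates = []
        for p in positions:
            lengths = [L for L in prefix_lengths if L >= p]
            cf_synth = synth[: p - 1] + substitution + synth[p:]
            cf_comps = np.stack([composition_vector(cf_synth[:L][::-1], self.encoder)
                                 for L in lengths])
            cf_votes = self._votes_matrix(cf_comps)
            orig_max = max(orig_votes[L] for L in lengths)
            cf_max = float(cf_votes.max())
            candidates.append(Candidate(
                position=p, residue=synth[p - 1], substitution=substitution,
                original_vote=float(orig_max), counterfactual_vote=cf_max,
                score=float(orig_max - cf_max),
            ))
        candidates.sort(key=lambda c: (-c.score, c.position))
        rec.candidates = candidates
        return rec

    def summary(self) -> str:
        lines = [
            f"AggregationEnsemble: {self.n_members} XGBoost members, "
            f"master seed {self.master_seed}",
            f"member seeds: {self.member_seeds[:5]}{'...' if self.n_members > 5 else ''}",
        ]
        lines += self.manifest
        return "\n".join(lines)


def train_ensemble(X: np.ndarray, y: np.ndarray, n_members: int = 100,
                   seed: int = 0, subsample: float = 0.8,
                   encoder: EncoderConfig | None = None) -> AggregationEnsembleResults:
    """Train the voting ensemble (see :class:`AggregationEnsemble`)."""
    return AggregationEnsemble(X, y, n_members=n_members, subsample=subsample,
                               encoder=encoder).fit(seed=seed)


def predict_aggregation(model: AggregationEnsembleResults, sequence: str) -> tuple[float, bool]:
    """Ensemble vote fraction and verdict for one sequence (N→C)."""
    return model.predict(sequence)


def recommend(model: AggregationEnsembleResults, sequence: str,
              replaceable: frozenset[str] | set[str] = REPLACEABLE_DEFAULT,
              window: tuple[int, int] = RESIN_WINDOW) -> Recommendation:
    """Ranked aggregation-reducing substitutions for one sequence."""
    return model.recommend(sequence, replaceable=replaceable, window=window)
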