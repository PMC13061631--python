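"""Synthetic benchmark generator: sequences, planted labels, UV traces.

The generator emulates the study conditions of a flow-SPPS aggregation
dataset end to end, with a known ground truth:

* peptide sequences are drawn composition-first — per-peptide amino-acid
  weights from a Dirichlet prior, residue counts multinomial, order
  uniformly random — so composition, not order, is the primitive;
* aggregation labels follow a logistic model on the normalised
  composition, ``p = expit(beta · c + bias)``, optionally flipped with a
  small label-noise probability.  The default sign pattern of ``beta``
  makes Ser, Ile, Val and Thr the strongest promoters and Phe, Asp, Tyr
  and Arg the strongest reducers, with milder secondary contributions
  (Gln/Leu positive, Cys/His/Pro negative), matching the qualitative
  per-residue picture in SPPS practice;
* each synthesis gets one Gaussian deprotection peak per coupling; from
  the planted onset step onward the peak's FWHM grows and its height
  decays geometrically per step (broadening saturates at a configurable
  cap so late peaks stay inside the acquisition window), plus additive
  detector noise.  Aggregating syntheses receive an onset drawn uniformly
  from steps 5–15 (clipped to the sequence length), the window where
  on-resin aggregation is empirically observed.

A positional variant (``positional=True``) plants the signal in the
contrast between the resin-proximal and resin-distal halves instead of
the whole-sequence composition; it serves as the negative control for
sequence-shuffling experiments and defaults off.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .alphabet import AA_ORDER, composition, vector_from_mapping
from .curation import PeptideRecord
from .traces import SynthesisTrace

__all__ = [
    "DEFAULT_BETA",
    "SyntheticConfig",
    "TraceModelConfig",
    "sample_peptides",
    "planted_labels",
    "synth_trace",
    "make_benchmark",
    "bayes_accuracy",
]

GAUSS_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Planted per-residue log-odds: strong promoters S,I,V,T (+2), strong
#: reducers F,D,Y,R (−2), mild secondary contributors Q,L (+1) and
#: C,H,P (−1), all others neutral.
DEFAULT_BETA = vector_from_mapping(
    {"S": 2.0, "I": 2.0, "V": 2.0, "T": 2.0,
     "Q": 1.0, "L": 1.0,
     "F": -2.0, "D": -2.0, "Y": -2.0, "R": -2.0,
     "C": -1.0, "H": -1.0, "P": -1.0}
)

ONSET_WINDOW = (5, 15)


def _as_20_vector(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (20,):
        raise ValueError(f"{name} must be a 20-vector in AA_ORDER, got shape {arr.shape}")
    return arr


@dataclass
class SyntheticConfig:
    """Generator settings for sequences and planted labels."""

    n_peptides: int = 500
    length_range: tuple[int, int] = (8, 20)
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    bias: float = 0.0
    label_noise: float = 0.05
    composition_prior: np.ndarray = field(default_factory=lambda: np.full(20, 0.5))
    seed: int = 0
    #: plant the label on the prefix-minus-suffix composition contrast
    #: instead of the whole-sequence composition (shuffling control)
    positional: bool = False

    def __post_init__(self) -> None:
        self.beta = _as_20_vector(self.beta, "beta")
        self.composition_prior = _as_20_vector(self.composition_prior, "composition_prior")
        lo, hi = self.length_range
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be positive")
        if lo < 5 or hi < lo:
            raise ValueError("length_range must satisfy 5 <= min <= max")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if np.any(self.composition_prior <= 0):
            raise ValueError("composition_prior entries must be positive")


@dataclass
class TraceModelConfig:
    """Phenomenological peak model for synthetic deprotection traces.

    Peaks are Gaussian in time.  From the onset step onward the FWHM is
    multiplied by ``(1 + broadening_per_step)`` once per step *including
    the onset step itself* (so the onset is the first broadened peak) and
    capped at ``max_broadening`` times the baseline; the height decays by
    ``(1 − height_decay_per_step)`` per step on the same schedule.
    """

    baseline_height: float = 1.0
    baseline_fwhm: float = 8.0
    broadening_per_step: float = 0.25
    height_decay_per_step: float = 0.1
    max_broadening: float = 4.0
    peak_points: int = 240
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_fwhm <= 0 or self.baseline_height <= 0:
            raise ValueError("baseline height and FWHM must be positive")
        if self.peak_points < 20:
            raise ValueError("peak_points must be at least 20")
        if self.broadening_per_step < 0:
            raise ValueError("broadening_per_step must be non-negative")
        if not (0.0 <= self.height_decay_per_step < 1.0):
            raise ValueError("height_decay_per_step must lie in [0, 1)")
        if self.max_broadening < 1.0:
            raise ValueError("max_broadening must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def window_seconds(self) -> float:
        """Acquisition window: wide enough that even a maximally broadened
        peak leaves the outer 5% of samples at baseline."""
        sigma_max = self.baseline_fwhm * self.max_broadening / GAUSS_FWHM_PER_SIGMA
        return 8.0 * sigma_max


def sample_peptides(config: SyntheticConfig) -> list[PeptideRecord]:
    """Draw ``n_peptides`` composition-first random peptide sequences."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0])
    lo, hi = config.length_range
    records = []
    for i in range(config.n_peptides):
        length = int(rng.integers(lo, hi + 1))
        weights = rng.dirichlet(config.composition_prior)
        counts = rng.multinomial(length, weights)
        letters = np.repeat(list(AA_ORDER), counts)
        rng.shuffle(letters)
        records.append(PeptideRecord(id=f"synth-{i:05d}", sequence="".join(letters), source="synthetic"))
    return records


def _planted_logit(record: PeptideRecord, config: SyntheticConfig) -> float:
    if not config.positional:
        return float(config.beta @ record.composition()) + config.bias
    # positional variant: resin-proximal half vs resin-distal half
    synth = record.synthesis_order
    half = len(synth) // 2
    c_prox = composition(synth[:half]) if half else np.zeros(20)
    c_dist = composition(synth[half:])
    return float(config.beta @ (c_prox - c_dist)) + config.bias


def planted_labels(records: list[PeptideRecord], config: SyntheticConfig) -> list[PeptideRecord]:
    """Attach Bernoulli labels from the planted logistic model.

    Each record's aggregation probability is ``expit(beta · c + bias)``
    on its normalised composition; the drawn label is then flipped with
    probability ``label_noise``.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 1])
    out = []
    for rec in records:
        p = expit(_planted_logit(rec, config))
        label = bool(rng.random() < p)
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = not label
        out.append(replace(rec, sequence_label=label))
    return out


def synth_trace(
    record: PeptideRecord,
    onset_step: int | None,
    trace_config: TraceModelConfig,
    rng: np.random.Generator | None = None,
) -> SynthesisTrace:
    """Emit one Gaussian deprotection peak per coupling step.

    Steps before ``onset_step`` (or all steps when it is None) reproduce
    the baseline peak; from the onset step onward the FWHM grows and the
    height decays geometrically per step as configured.
    """
    n = len(record.sequence)
    if onset_step is not None and not (1 <= onset_step <= n):
        raise ValueError(f"onset_step {onset_step} outside [1, {n}]")
    tc = trace_config
    if rng is None:
        rng = np.random.default_rng([tc.seed & 0x7FFFFFFF, zlib.crc32(record.id.encode())])
    t = np.linspace(0.0, tc.window_seconds, tc.peak_points)
    center = tc.window_seconds / 2.0
    residues = list(record.synthesis_order)
    peaks = []
    for step in range(1, n + 1):
        if onset_step is None or step < onset_step:
            mult, hfac = 1.0, 1.0
        else:
            k = step - onset_step + 1  # onset step carries one increment
            mult = min((1.0 + tc.broadening_per_step) ** k, tc.max_broadening)
            hfac = (1.0 - tc.height_decay_per_step) ** k
        sigma = tc.baseline_fwhm * mult / GAUSS_FWHM_PER_SIGMA
        y = tc.baseline_height * hfac * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        if tc.noise_sd > 0:
            y = y + rng.normal(0.0, tc.noise_sd, size=t.size)
        peaks.append((t.copy(), y))
    return SynthesisTrace(id=record.id, residues=residues, peaks=peaks, onset_step=onset_step)


def make_benchmark(
    config: SyntheticConfig,
    trace_config: TraceModelConfig | None = None,
) -> tuple[list[PeptideRecord], list[SynthesisTrace]]:
    """Convenience bundle: labelled records plus matching traces.

    Aggregating records receive an onset drawn uniformly from synthesis
    steps 5–15 (clipped to the sequence length); non-aggregating records
    get none.  Fully reproducible from the two config seeds.

    Aggregation labels in the real pipeline come from the trace analyzer,
    which replaces His/Cys peaks by neighbour interpolation; an onset
    whose broadening lives entirely on a trailing His/Cys run would be
    invisible to it.  The generator therefore shifts such an onset to the
    last preceding step with a detectable peak (a record with no such
    step becomes non-aggregating), keeping labels and traces consistent.
    """
    tc = trace_config if trace_config is not None else TraceModelConfig(seed=config.seed)
    records = planted_labels(sample_peptides(config), config)
    rng_onset = np.random.default_rng([config.seed & 0x7FFFFFFF, 2])
    rng_noise = np.random.default_rng([tc.seed & 0x7FFFFFFF, 3])
    out_records: list[PeptideRecord] = []
    traces: list[SynthesisTrace] = []
    lo, hi = ONSET_WINDOW
    for rec in records:
        if rec.sequence_label:
            onset = int(min(rng_onset.integers(lo, hi + 1), len(rec.sequence)))
            onset = _detectable_onset(rec, onset)
        else:
            onset = None
        rec = replace(rec, sequence_label=onset is not None, onset_step=onset)
        out_records.append(rec)
        traces.append(synth_trace(rec, onset, tc, rng=rng_noise))
    return out_records, traces


def _detectable_onset(record: PeptideRecord, onset: int) -> int | None:
    """Move an onset to a step where the analyzer can call it exactly.

    The analyzer replaces His/Cys peaks by neighbour interpolation, which
    (a) erases broadening that lives only on a trailing His/Cys run and
    (b) bleeds an onset's broadening backwards across an adjacent run,
    shifting the detected onset early.  A planted onset is therefore only
    placed on a step whose own residue and predecessor are both
    non-special; the sampled onset is moved to the nearest such step
    (earlier on ties, never step 1, which is the AF reference).  Returns
    None when the sequence admits no such step.
    """
    synth = record.synthesis_order
    valid = [s for s in range(2, len(synth) + 1)
             if synth[s - 1] not in "HC" and synth[s - 2] not in "HC"]
    if not valid:
        return None
    return min(valid, key=lambda s: (abs(s - onset), s))


def bayes_accuracy(config: SyntheticConfig, n_mc: int = 100_000, seed: int | None = None) -> float:
    """Accuracy of the Bayes-optimal classifier under the planted model.

    For a composition ``c`` the optimal decision attains accuracy
    ``max(q, 1 − q)`` with ``q = (1 − ε)·p + ε·(1 − p)`` the label
    probability after noise ``ε``.  This is exact per composition and
    averaged by Monte Carlo over the generator's own composition law
    (Dirichlet weights, multinomial counts, random length).
    """
    mc = _config_for_mc(config, n_mc, seed)
    records = sample_peptides(mc)
    logits = np.array([_planted_logit(r, mc) for r in records])
    p = expit(logits)
    q = (1.0 - config.label_noise) * p + config.label_noise * (1.0 - p)
    return float(np.mean(np.maximum(q, 1.0 - q)))


def _config_for_mc(config: SyntheticConfig, n_mc: int, seed: int | None) -> SyntheticConfig:
    return SyntheticConfig(
        n_peptides=n_mc,
        length_range=config.length_range,
        beta=config.beta.copy(),
        bias=config.bias,
        label_noise=config.label_noise,
        composition_prior=config.composition_prior.copy(),
        seed=config.seed if seed is None else seed,
        positional=config.positional,
    )
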