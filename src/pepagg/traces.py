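"""UV deprotection-trace analysis: peak metrics, aggregation factor, calls.

Each Fmoc deprotection during flow SPPS produces one UV absorbance peak.
On-resin aggregation broadens (and usually lowers) that peak.  The
aggregation factor of coupling step *n* compares its peak with the first
coupling's peak of the same synthesis, on a percent scale::

    AF = W^n − H^n,   W^n = 100 · FWHM_n / FWHM_1,   H^n = 100 · height_n / height_1

A step with AF strictly above the threshold (default 20, i.e. net
broadening beyond 20% of the first peak) is called aggregating, and a
sequence is aggregating as soon as any of its steps is.  Histidine and
cysteine couplings run at a different reactor temperature which broadens
the peak for non-aggregation reasons, so their metrics are replaced by
interpolation between the neighbouring couplings before AF is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MalformedPeakError",
    "UnusableTraceError",
    "DeprotectionPeakMetrics",
    "SynthesisTrace",
    "AggregationProfile",
    "peak_metrics",
    "aggregation_factor",
    "interpolate_special_residues",
    "classify",
]

#: Residues whose couplings need a temperature change on the synthesizer,
#: broadening the deprotection peak for reasons unrelated to aggregation.
SPECIAL_RESIDUES = frozenset("HC")


class MalformedPeakError(ValueError):
    """Raised when a time series does not contain a usable single peak."""


class UnusableTraceError(ValueError):
    """Raised when no coupling step of a trace yields usable metrics."""


@dataclass(frozen=True)
class DeprotectionPeakMetrics:
    """Height and full width at half maximum of one deprotection peak.

    ``step`` is the 1-based coupling index counted from the resin (the C
    terminus), i.e. synthesis order.
    """

    height: float
    fwhm: float
    step: int = 0
    residue: str = ""

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValueError(f"peak height must be positive, got {self.height}")
        if not (self.fwhm > 0):
            raise ValueError(f"peak FWHM must be positive, got {self.fwhm}")


@dataclass
class SynthesisTrace:
    """Ordered per-coupling deprotection peaks of one synthesis.

    ``residues[i]`` is the amino acid added at step i+1 (synthesis order,
    C→N); ``peaks[i]`` is its ``(t_seconds, absorbance)`` sample arrays.
    ``onset_step`` carries the planted onset for synthetic traces and is
    ignored by the analyzer.
    """

    id: str
    residues: list[str]
    peaks: list[tuple[np.ndarray, np.ndarray]]
    onset_step: int | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def sequence(self) -> str:
        """Sequence written N→C (reverse of synthesis order)."""
        return "".join(reversed(self.residues))


@dataclass
class AggregationProfile:
    """Per-step AF values and aggregation calls for one synthesis.

    ``af_values[i]`` is the AF of step i+1 on the percent scale; the first
    step is its own reference, so ``af_values[0] == 0`` exactly.
    ``onset_step`` is the first (1-based) step whose AF exceeds the
    threshold, or None for a non-aggregating synthesis.
    """

    af_values: np.ndarray
    step_labels: np.ndarray
    sequence_label: bool
    onset_step: int | None
    interpolated_steps: set[int] = field(default_factory=set)
    threshold: float = 20.0


def peak_metrics(t: np.ndarray, absorbance: np.ndarray) -> DeprotectionPeakMetrics:
    """Extract (height, FWHM) from a single-peak time series.

    The baseline is the median of the first and last 5% of samples; the
    height is the maximum above baseline; the FWHM is the distance between
    the two half-maximum crossings flanking the maximum, each located by
    linear interpolation between the bracketing samples.

    Raises
    ------
    MalformedPeakError
        if the signal has no positive excursion above baseline or fewer
        than two half-maximum crossings.
    ValueError
        if the time axis is not strictly increasing or there are fewer
        than 20 samples.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and absorbance must be 1-d arrays of equal length")
    if t.size < 20:
        raise ValueError(f"need at least 20 samples, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")

    n_edge = max(1, int(round(0.05 * t.size)))
    baseline = float(np.median(np.concatenate([y[:n_edge], y[-n_edge:]])))
    i_max = int(np.argmax(y))
    height = float(y[i_max] - baseline)
    if height <= 0:
        raise MalformedPeakError("no peak above baseline")

    half = baseline + height / 2.0

    def _cross(lo: int, hi: int, rising: bool) -> float | None:
        # scan away from the maximum for the first crossing of `half`
        rng = range(hi, lo, -1) if rising else range(lo, hi)
        for i in rng:
            y0, y1 = (y[i - 1], y[i]) if rising else (y[i], y[i + 1])
            t0, t1 = (t[i - 1], t[i]) if rising else (t[i], t[i + 1])
            if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))
        return None

    left = _cross(0, i_max, rising=True)
    right = _cross(i_max, t.size - 2, rising=False)
    if left is None or right is None:
        raise MalformedPeakError("fewer than two half-maximum crossings")
    fwhm = right - left
    if fwhm <= 0:
        raise MalformedPeakError("non-positive FWHM")
    return DeprotectionPeakMetrics(height=height, fwhm=fwhm)


def aggregation_factor(peak: DeprotectionPeakMetrics, reference: DeprotectionPeakMetrics) -> float:
    """AF of ``peak`` relative to the first coupling's ``reference`` peak.

    Returns W^n − H^n on the percent scale: 0 for a peak identical to the
    reference, positive when broadening outpaces the height.
    """
    if reference.height <= 0 or reference.fwhm <= 0:
        raise ValueError("reference peak must have positive height and width")
    w_n = 100.0 * peak.fwhm / reference.fwhm
    h_n = 100.0 * peak.height / reference.height
    return w_n - h_n


def interpolate_special_residues(
    metrics: list[DeprotectionPeakMetrics],
    residues: list[str],
    special: frozenset[str] | set[str] = SPECIAL_RESIDUES,
) -> tuple[list[DeprotectionPeakMetrics], set[int]]:
    """Replace His/Cys peak metrics by interpolation between neighbours.

    Height and FWHM of every step whose residue is in ``special`` are
    replaced by linear interpolation (in step index) between the nearest
    non-special steps before and after; a leading or trailing run copies
    the nearest valid neighbour.  Returns the new metrics list and the set
    of 1-based step indices that were replaced.
    """
    if len(metrics) != len(residues):
        raise ValueError("metrics and residues length mismatch")
    is_special = [r in special for r in residues]
    if all(is_special):
        raise UnusableTraceError("every coupling step is a special residue")
    valid = [i for i, s in enumerate(is_special) if not s]
    if not any(is_special):
        return list(metrics), set()

    idx = np.array(valid, dtype=float)
    heights = np.array([metrics[i].height for i in valid])
    widths = np.array([metrics[i].fwhm for i in valid])
    out: list[DeprotectionPeakMetrics] = []
    replaced: set[int] = set()
    for i, m in enumerate(metrics):
        if not is_special[i]:
            out.append(m)
            continue
        # np.interp clamps to the boundary values, which implements the
        # copy-nearest-neighbour rule for leading/trailing special steps
        h = float(np.interp(i, idx, heights))
        w = float(np.interp(i, idx, widths))
        out.append(DeprotectionPeakMetrics(height=h, fwhm=w, step=m.step, residue=m.residue))
        replaced.add(i + 1)
    return out, replaced


def classify(
    trace: SynthesisTrace,
    threshold: float = 20.0,
    strict: bool = True,
    special: frozenset[str] | set[str] = SPECIAL_RESIDUES,
) -> AggregationProfile:
    """Full analysis of one synthesis trace.

    Extracts peak metrics per coupling step, interpolates special-residue
    steps, computes AF per step against the (possibly interpolated) first
    coupling, and calls the onset as the first step whose AF exceeds
    ``threshold`` (strictly by default).  A sequence is aggregating iff an
    onset exists; step labels are False before the onset and True from it
    onward.
    """
    if len(trace) < 2:
        raise ValueError("need at least two coupling steps")
    metrics: list[DeprotectionPeakMetrics] = []
    for i, (t, y) in enumerate(trace.peaks):
        try:
            m = peak_metrics(t, y)
        except (MalformedPeakError, ValueError) as exc:
            raise MalformedPeakError(f"step {i + 1}: {exc}") from exc
        metrics.append(DeprotectionPeakMetrics(m.height, m.fwhm, step=i + 1, residue=trace.residues[i]))

    metrics, replaced = interpolate_special_residues(metrics, trace.residues, special)
    ref = metrics[0]
    af = np.array([aggregation_factor(m, ref) for m in metrics])
    af[0] = 0.0  # self-reference, exact by definition

    exceeds = af > threshold if strict else af >= threshold
    onset: int | None = int(np.argmax(exceeds)) + 1 if exceeds.any() else None
    steps = np.arange(1, len(metrics) + 1)
    labels = np.zeros(len(metrics), dtype=bool) if onset is None else steps >= onset
    return AggregationProfile(
        af_values=af,
        step_labels=labels,
        sequence_label=onset is not None,
        onset_step=onset,
        interpolated_steps=replaced,
        threshold=threshold,
    )
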