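"""Dataset curation and label framings for peptide-synthesis records.

The modelling dataset is built from heterogeneous synthesis logs by
applying, in order: the canonical-alphabet filter, the minimum-length
floor (5 residues), truncation to the first 20 synthesis steps (the
C-terminal 20 residues, since SPPS elongates C→N and aggregation is a
resin-proximal phenomenon), and exact-duplicate removal.  Whole-sequence
labels mark a peptide aggregating iff any retained step aggregated;
stepwise labels expand each peptide into per-prefix rows.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AA_SET, composition, require_canonical

__all__ = [
    "PeptideRecord",
    "CurationReport",
    "StepwiseRow",
    "curate",
    "stepwise_labels",
    "shuffle_sequence",
]

MAX_SYNTHESIS_STEPS = 20
MIN_LENGTH = 5


@dataclass(frozen=True)
class PeptideRecord:
    """One curated synthesis: sequence, provenance and aggregation label.

    ``sequence`` is stored N→C (standard writing order); synthesis runs
    C→N, so synthesis step k adds ``sequence[-k]``.  ``onset_step`` is the
    1-based aggregation onset counted from the resin (C terminus), None
    for a non-aggregating synthesis.
    """

    id: str
    sequence: str
    source: str = ""
    sequence_label: bool | None = None
    onset_step: int | None = None

    def __post_init__(self) -> None:
        if self.onset_step is not None:
            if self.onset_step < 1 or self.onset_step > len(self.sequence):
                raise ValueError(
                    f"onset_step {self.onset_step} outside sequence of length {len(self.sequence)}"
                )

    @property
    def synthesis_order(self) -> str:
        """Sequence in synthesis order, first synthesized residue first."""
        return self.sequence[::-1]

    def composition(self) -> np.ndarray:
        return composition(self.sequence)


@dataclass
class CurationReport:
    n_input: int = 0
    n_non_canonical: int = 0
    n_too_short: int = 0
    n_truncated: int = 0
    n_duplicates: int = 0
    n_output: int = 0
    warnings: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"input records           {self.n_input}",
            f"dropped: non-canonical  {self.n_non_canonical}",
            f"dropped: shorter than {MIN_LENGTH} {self.n_too_short}",
            f"truncated to {MAX_SYNTHESIS_STEPS} steps   {self.n_truncated}",
            f"dropped: duplicates     {self.n_duplicates}",
            f"curated records         {self.n_output}",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def curate(records: list[PeptideRecord]) -> tuple[list[PeptideRecord], CurationReport]:
    """Apply the standard filters and return curated records plus a report.

    Truncation keeps the C-terminal ``MAX_SYNTHESIS_STEPS`` residues (the
    first 20 synthesis steps).  If truncation removes the onset step, the
    retained fragment never aggregated, so its label is recomputed as
    non-aggregating.  Duplicates are exact sequence matches after
    truncation; the first occurrence wins.  An empty result is reported as
    a warning, not raised.
    """
    report = CurationReport(n_input=len(records))
    out: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in records:
        if not rec.sequence or any(ch not in AA_SET for ch in rec.sequence):
            report.n_non_canonical += 1
            continue
        if len(rec.sequence) < MIN_LENGTH:
            report.n_too_short += 1
            continue
        if len(rec.sequence) > MAX_SYNTHESIS_STEPS:
            report.n_truncated += 1
            truncated = rec.sequence[-MAX_SYNTHESIS_STEPS:]
            if rec.onset_step is not None and rec.onset_step > MAX_SYNTHESIS_STEPS:
                rec = replace(rec, sequence=truncated, sequence_label=False, onset_step=None)
            else:
                rec = replace(rec, sequence=truncated)
        if rec.sequence in seen:
            report.n_duplicates += 1
            continue
        seen.add(rec.sequence)
        out.append(rec)
    report.n_output = len(out)
    if not out and records:
        report.warnings.append("curation removed every record")
    return out, report


@dataclass(frozen=True)
class StepwiseRow:
    """One per-prefix training row: the first ``prefix_length`` synthesis
    steps of record ``id`` with its aggregated-by-now label."""

    id: str
    prefix_length: int
    label: bool


def stepwise_labels(
    record: PeptideRecord,
    window_before: int | None = None,
    window_after: int | None = None,
) -> list[StepwiseRow]:
    """Expand a record into per-synthesis-step rows.

    Default framing: once aggregation occurs every later coupling is
    aggregating, so prefixes shorter than the onset are False and all from
    the onset onward are True; a non-aggregating record yields all-False
    rows.

    Windowed framing (both windows given, each 0–10): only steps in
    [onset − window_before, onset + window_after] are labelled True; steps
    before the window are False; steps after the window are dropped from
    the dataset entirely (the post-onset tail carries little information).
    """
    windowed = window_before is not None or window_after is not None
    if windowed:
        if window_before is None or window_after is None:
            raise ValueError("window_before and window_after must be given together")
        if not (0 <= window_before <= 10 and 0 <= window_after <= 10):
            raise ValueError("windows must lie in [0, 10]")

    n = len(record.sequence)
    onset = record.onset_step
    rows: list[StepwiseRow] = []
    for step in range(1, n + 1):
        if onset is None:
            rows.append(StepwiseRow(record.id, step, False))
        elif not windowed:
            rows.append(StepwiseRow(record.id, step, step >= onset))
        else:
            if step < onset - window_before:
                rows.append(StepwiseRow(record.id, step, False))
            elif step <= onset + window_after:
                rows.append(StepwiseRow(record.id, step, True))
            # steps past the window are excluded
    return rows


def shuffle_sequence(record: PeptideRecord, seed: int) -> PeptideRecord:
    """Return the record with its residues uniformly permuted.

    The permutation is deterministic in ``(record.id, seed)`` so shuffled
    datasets are reproducible.  Composition and length are preserved
    exactly; the onset step (a positional quantity) is dropped.
    """
    require_canonical(record.sequence)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(record.id.encode())])
    letters = np.array(list(record.sequence))
    shuffled = "".join(letters[rng.permutation(len(letters))])
    return replace(record, sequence=shuffled, onset_step=None)
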