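"""File formats: FASTA sequences, labels CSV, the trace CSV dialect.

All tables are plain UTF-8 CSV with a header row.

* labels CSV — ``id, sequence, label, onset_step`` (sequence N→C, label
  0/1, onset_step blank for non-aggregating records);
* trace CSV — one row per sample point:
  ``id, step, residue, t_seconds, absorbance`` with ``step`` the 1-based
  coupling index from the resin;
* profile CSV — ``id, step, residue, af, step_label, interpolated``;
* summary CSV — ``id, sequence_label, onset_step``.

FASTA record IDs carry provenance as ``id|source``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import PeptideRecord
from .traces import AggregationProfile, SynthesisTrace

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels_csv",
    "write_labels_csv",
    "read_traces_csv",
    "write_traces_csv",
    "write_profiles_csv",
    "write_summary_csv",
    "write_stepwise_csv",
    "write_feature_matrix",
]


def write_fasta(records: list[PeptideRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=f"{rec.id}|{rec.source}" if rec.source else rec.id,
                  description="")
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        rec_id, _, source = sr.id.partition("|")
        out.append(PeptideRecord(id=rec_id, sequence=str(sr.seq), source=source))
    return out


def write_labels_csv(records: list[PeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence for r in records],
            "label": [int(bool(r.sequence_label)) for r in records],
            "onset_step": [r.onset_step if r.onset_step is not None else pd.NA for r in records],
        }
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path, source: str = "") -> list[PeptideRecord]:
    df = pd.read_csv(path, dtype={"id": str, "sequence": str})
    out = []
    for row in df.itertuples(index=False):
        onset = getattr(row, "onset_step", None)
        onset = None if pd.isna(onset) else int(onset)
        label = getattr(row, "label", None)
        out.append(
            PeptideRecord(id=row.id, sequence=row.sequence, source=source,
                          sequence_label=None if label is None or pd.isna(label) else bool(int(label)),
                          onset_step=onset)
        )
    return out


def write_stepwise_csv(rows, path: str | Path) -> None:
    """Per-prefix rows (id, prefix_length, label) as CSV."""
    pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "prefix_length": [r.prefix_length for r in rows],
            "label": [int(r.label) for r in rows],
        }
    ).to_csv(path, index=False)


def write_feature_matrix(dataset, path: str | Path) -> None:
    """Dense feature-matrix CSV plus the encoder config that produced it.

    Columns are the dataset's feature names preceded by ``id`` and
    ``label``; the encoder config is serialised as JSON next to the
    matrix (``<path>.config.json``).
    """
    import json

    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df.insert(0, "label", dataset.y)
    df.insert(0, "id", dataset.ids)
    df.to_csv(path, index=False)
    config = dict(dataset.config.to_dict(), representation=dataset.representation)
    Path(str(path) + ".config.json").write_text(json.dumps(config, indent=2) + "\n")


def write_traces_csv(traces: list[SynthesisTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        for step, ((t, y), residue) in enumerate(zip(tr.peaks, tr.residues), start=1):
            frames.append(pd.DataFrame({
                "id": tr.id, "step": step, "residue": residue,
                "t_seconds": t, "absorbance": y,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_traces_csv(path: str | Path) -> list[SynthesisTrace]:
    df = pd.read_csv(path, dtype={"id": str, "residue": str})
    required = {"id", "step", "residue", "t_seconds", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing column(s): {sorted(missing)}")
    traces = []
    for trace_id, group in df.groupby("id", sort=False):
        residues, peaks = [], []
        for step, g in group.groupby("step", sort=True):
            residues.append(str(g["residue"].iloc[0]))
            peaks.append((g["t_seconds"].to_numpy(float), g["absorbance"].to_numpy(float)))
        traces.append(SynthesisTrace(id=str(trace_id), residues=residues, peaks=peaks))
    return traces


def write_profiles_csv(profiles: dict[str, AggregationProfile],
                       traces: dict[str, SynthesisTrace], path: str | Path) -> None:
    rows = []
    for trace_id, prof in profiles.items():
        residues = traces[trace_id].residues
        for i, af in enumerate(prof.af_values):
            rows.append({
                "id": trace_id, "step": i + 1, "residue": residues[i],
                "af": af, "step_label": int(prof.step_labels[i]),
                "interpolated": int((i + 1) in prof.interpolated_steps),
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def write_summary_csv(profiles: dict[str, AggregationProfile], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": list(profiles),
            "sequence_label": [int(p.sequence_label) for p in profiles.values()],
            "onset_step": [p.onset_step if p.onset_step is not None else pd.NA
                           for p in profiles.values()],
        }
    ).to_csv(path, index=False)
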