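#!/usr/bin/env python
"""Optional reanalysis of the published AFPS dataset (never run by CI).

Reruns the composition-vector fivefold cross-validation on the real
curated dataset and reports the gap to the published headline accuracy
(59.5% +/- 1.9% for the composition representation).  The deposit is at
https://zenodo.org/records/14824562; download it manually and point this
script at a CSV extracted from it.

The deposit's native layout is not parsed; instead a column-mapping
adapter turns any CSV with one row per synthesis into curated records:

    python scripts/zenodo_check.py --csv data.csv \
        --id-col synthesis_id --sequence-col sequence --label-col aggregating

``--label-col`` may hold booleans/0-1 integers, or be omitted in favour
of ``--af-col`` holding the maximum aggregation factor per synthesis
(labels then derive from the AF > 20 rule).
"""

import argparse

import pandas as pd

from pepagg.curation import PeptideRecord, curate
from pepagg.encoders import encode_records
from pepagg.train_eval import fivefold_cv

PUBLISHED_ACCURACY_PCT = 59.5
PUBLISHED_SD_PCT = 1.9


def load_records(args: argparse.Namespace) -> list[PeptideRecord]:
    df = pd.read_csv(args.csv)
    records = []
    for i, row in df.iterrows():
        if args.label_col:
            label = bool(int(row[args.label_col]))
        else:
            label = float(row[args.af_col]) > 20.0
        records.append(
            PeptideRecord(
                id=str(row[args.id_col]) if args.id_col else f"row-{i}",
                sequence=str(row[args.sequence_col]).strip().upper(),
                source="zenodo",
                sequence_label=label,
            )
        )
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--csv", required=True, help="CSV extracted from the deposit")
    parser.add_argument("--sequence-col", default="sequence")
    parser.add_argument("--id-col", default=None)
    parser.add_argument("--label-col", default=None)
    parser.add_argument("--af-col", default=None)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    if not args.label_col and not args.af_col:
        parser.error("give either --label-col or --af-col")

    records = load_records(args)
    curated, report = curate(records)
    print(report)

    ds = encode_records(curated, "composition")
    res = fivefold_cv(ds.X, ds.y, "xgboost", seed=args.seed,
                      representation_name="composition")
    acc_pct = 100.0 * res.mean_accuracy
    sd_pct = 100.0 * res.sd_accuracy
    print(f"composition-vector fivefold CV: {acc_pct:.1f}% +/- {sd_pct:.1f}%")
    print(f"published:                      {PUBLISHED_ACCURACY_PCT:.1f}% +/- {PUBLISHED_SD_PCT:.1f}%")
    print(f"gap: {acc_pct - PUBLISHED_ACCURACY_PCT:+.1f} percentage points "
          "(seed- and curation-sensitive; informational only)")


if __name__ == "__main__":
    main()
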