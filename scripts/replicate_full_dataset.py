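#!/usr/bin/env python
"""Optional replication of the published 206-monomer validation study.

The deposited validation set (Materials Cloud,
doi:10.24435/materialscloud:2x-9j, file ``input.csv``) is not bundled:
it must be downloaded separately, and scoring the full set takes on the
order of an hour of RHF/STO-3G runs on one CPU.  Given the input CSV
(and, if available, a tagged ground-truth CSV), this script runs the
pipeline and reports class counts plus — with ground truth — class and
head/tail accuracies in the same token-equivalent sense as `hta validate`.

Example:
    python scripts/replicate_full_dataset.py --input input.csv \
        --truth truth.csv --output out.csv
"""

from __future__ import annotations

import argparse
import csv
from collections import Counter
from pathlib import Path

from headtail.harness import PipelineConfig, run_pipeline, score_dataset


def main() -> None:
    ap = argparse.ArgumentParser(
        description=__doc__,
        formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--input", required=True, type=Path,
                    help="downloaded validation CSV (polymer_name,smiles)")
    ap.add_argument("--truth", type=Path, default=None,
                    help="optional CSV: polymer_name,tagged_smiles"
                         "[,polymer_class]")
    ap.add_argument("--output", type=Path, default=Path("replication_out.csv"))
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--fix-lactones", action="store_true")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, fix_lactones=args.fix_lactones)
    rows = run_pipeline(args.input, cfg, output_csv=args.output)

    print(f"{len(rows)} records -> {args.output}")
    print("status counts:", dict(Counter(r.status for r in rows)))
    print("class counts: ", dict(Counter(r.polymer_class or "(none)"
                                         for r in rows)))

    if args.truth is not None:
        with open(args.truth, newline="", encoding="utf-8") as fh:
            truths = list(csv.DictReader(fh))
        rep = score_dataset(rows, truths)
        if any(e["class_correct"] is not None for e in rep.per_entry):
            n_cls = sum(bool(e["class_correct"]) for e in rep.per_entry
                        if e["class_correct"] is not None)
            print(f"class accuracy:     {rep.class_accuracy:.3f} "
                  f"({n_cls}/{rep.n})")
        n_ht = sum(e["headtail_correct"] for e in rep.per_entry)
        print(f"head/tail accuracy: {rep.headtail_accuracy:.3f} "
              f"({n_ht}/{rep.n})")
        for cls, d in sorted(rep.per_class_breakdown().items()):
            print(f"  {cls:14s} {d['headtail_correct']}/{d['n']}")


if __name__ == "__main__":
    main()
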