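#!/usr/bin/env python
"""Performance report: per-subject metrics, row-percent confusion matrices
and the set-up comparison table, written under results/.
"""
import argparse
from pathlib import Path

import pandas as pd

from gaitspeed.evaluate import compare_configurations, evaluate_predictions

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--in-dir", type=Path, default=Path("scratch/predictions"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
results = {}
for pred_path in sorted(args.in_dir.glob("predictions_*.csv")):
    stem = pred_path.stem.replace("predictions_", "")  # e.g. dual_5s
    setup, wl = stem.rsplit("_", 1)
    cell = (setup, float(wl.rstrip("s")))
    preds = pd.read_csv(pred_path)
    rep = evaluate_predictions(preds, configuration=cell)
    results[cell] = rep
    rep.confusion.to_frame(percent=True).round(2).to_csv(
        args.out_dir / f"confusion_rowpct_{stem}.csv")
    acc = rep.aggregate["accuracy"]
    print(f"{stem}: pooled accuracy {rep.pooled['accuracy']:.3f}, "
          f"subject mean {acc['mean']:.3f} "
          f"(range {acc['min']:.3f}-{acc['max']:.3f})")
    print(rep.confusion.to_frame(percent=True).round(1))

table = compare_configurations(results)
table.to_csv(args.out_dir / "comparison.csv", index=False,
             float_format="%.6g")
print(f"wrote {args.out_dir}/comparison.csv "
      f"({len(table)} rows across {len(results)} configurations)")
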