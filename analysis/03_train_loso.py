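#!/usr/bin/env python
"""Leave-one-subject-out cross-validation per sensor set-up.

Trains the gradient-boosted tree classifier once per held-out participant
(participant-grouped: the test subject never contributes training windows)
and writes the per-window prediction tables.
"""
import argparse
from pathlib import Path

import pandas as pd

from gaitspeed.classify import DEFAULT_PARAMS, run_loso

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--in-dir", type=Path, default=Path("scratch/features"))
ap.add_argument("--out-dir", type=Path, default=Path("scratch/predictions"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
for feat_path in sorted(args.in_dir.glob("features_*.csv")):
    matrix = pd.read_csv(feat_path)
    preds = run_loso(matrix, DEFAULT_PARAMS, seed=args.seed)
    out = args.out_dir / feat_path.name.replace("features_", "predictions_")
    preds.to_csv(out, index=False, float_format="%.10g")
    acc = float((preds["true"] == preds["predicted"]).mean())
    print(f"{feat_path.stem}: pooled LOSO accuracy {acc:.3f} -> {out}")
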