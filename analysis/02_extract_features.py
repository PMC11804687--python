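#!/usr/bin/env python
"""Segment the simulated recordings into non-overlapping windows and
compute the statistical feature matrix for each sensor set-up.

Windows default to 5 s; the dual set-up emits 161 features per window,
single-sensor set-ups 78.
"""
import argparse
from pathlib import Path
from types import SimpleNamespace

from gaitspeed.features import WindowSpec, build_catalogue, build_feature_matrix
from gaitspeed.io import LabelTrack, read_recording_csv

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--in-dir", type=Path, default=Path("scratch/recordings"))
ap.add_argument("--out-dir", type=Path, default=Path("scratch/features"))
ap.add_argument("--window", type=float, default=5.0)
ap.add_argument("--setups", nargs="+", default=["thigh", "back", "dual"])
args = ap.parse_args()

sets = []
for thigh_path in sorted(args.in_dir.glob("*_thigh.csv")):
    pid = thigh_path.name[: -len("_thigh.csv")]
    sets.append(SimpleNamespace(
        thigh=read_recording_csv(thigh_path),
        back=read_recording_csv(args.in_dir / f"{pid}_back.csv"),
        labels=LabelTrack.from_csv(args.in_dir / f"{pid}_labels.csv"),
    ))
print(f"loaded {len(sets)} participants from {args.in_dir}")

args.out_dir.mkdir(parents=True, exist_ok=True)
for setup in args.setups:
    matrix = build_feature_matrix(sets, setup, WindowSpec(args.window))
    out = args.out_dir / f"features_{setup}_{args.window:g}s.csv"
    matrix.to_csv(out, index=False, float_format="%.10g")
    counts = matrix["label"].value_counts().to_dict()
    print(f"{setup}: {len(matrix)} windows x {len(build_catalogue(setup))} "
          f"features, labels {counts} -> {out}")
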