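"""Spatial clustering of death sites within each annual-cycle stage.

Projects death coordinates to planar km and applies the Average Nearest
Neighbor z-test per stage of death (classic, uncorrected formulas, as in
the standard GIS tool).  Writes spatial.csv.
"""

import argparse
from pathlib import Path

from fullcycle.pipeline import default_run_config, run_spatial
from fullcycle.simulate import read_tracking_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    ap.add_argument("--area-method", default="bounding_rectangle",
                    choices=["bounding_rectangle", "convex_hull"])
    args = ap.parse_args()

    cfg = default_run_config(seed=args.seed)
    cfg.area_method = args.area_method
    records = read_tracking_csv(Path(args.out) / "tracking.csv")
    table = run_spatial(cfg, records, args.out)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
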