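"""Simulate the study landscape: terrain, winter/summer climate, masks,
trail network and presence records with a known occupancy truth.

Writes results/synth/: ASCII-grid rasters, trails.geojson, occurrences.csv
and truth.json (the generative parameters)."""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from common import parse_args, stage_dir

from edelweiss import geodata, synthetic


def main() -> None:
    cfg, seeds = parse_args(__doc__)
    out = stage_dir(cfg, "synth")
    truth = synthetic.SyntheticTruth(seed=seeds[0], **cfg.truth)
    rasters = synthetic.make_landscape(truth, seed=seeds[0])
    trails = synthetic.make_trails(truth, rasters, n_trails=cfg.n_trails, seed=seeds[1])
    occ = synthetic.sample_occurrences(truth, rasters, cfg.n_occurrences, seed=seeds[2])
    p_star = synthetic.true_occupancy(truth, rasters)

    for name, raster in rasters.items():
        geodata.write_ascii_grid(raster, os.path.join(out, f"{name}.asc"))
    trails.to_geojson(os.path.join(out, "trails.geojson"))
    geodata.write_points_csv(occ, os.path.join(out, "occurrences.csv"))
    truth.to_json(os.path.join(out, "truth.json"))

    elev = rasters["elevation"].values
    temp = rasters["temperature"].values
    print(f"landscape {elev.shape[0]}x{elev.shape[1]} cells, "
          f"elevation {elev.min():.0f}-{elev.max():.0f} m")
    print(f"temperature-elevation correlation r = "
          f"{np.corrcoef(elev.ravel(), temp.ravel())[0, 1]:+.3f}")
    print(f"true occupancy: {(p_star.values > 0.5).sum()} cells with P* > 0.5 "
          f"(domain mean {np.nanmean(p_star.values):.4f})")
    print(f"{len(trails)} trails, {len(occ)} presence records -> {out}")


if __name__ == "__main__":
    main()
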