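"""Project seed number and mass over the suitable range, now and in 2050.

Couples the simplified plot-level fitness models to the masked probability
maps; per-km2 output is weighted by the cell's probability of occurrence.
Writes results/project/ (summary JSON, per-cell CSVs, output rasters)."""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import parse_args, stage_dir

from edelweiss import geodata, projection
from edelweiss.demography import FitnessModel


def main() -> None:
    cfg, _ = parse_args(__doc__)
    sdm_dir = os.path.join(cfg.outdir, "sdm")
    demog = os.path.join(cfg.outdir, "demog")
    out = stage_dir(cfg, "project")

    with open(os.path.join(demog, "fitness_models.json")) as fh:
        models = {k: FitnessModel.from_dict(v) for k, v in json.load(fh).items()}
    masked_now = geodata.read_ascii_grid(os.path.join(sdm_dir, "prob_current_masked.asc"))
    masked_fut = geodata.read_ascii_grid(os.path.join(sdm_dir, "prob_future_masked.asc"))

    area = (masked_now.spec.cell_size / 1000.0) ** 2
    summary = projection.project_range(
        models["number_plot"], models["mass_plot"], masked_now, masked_fut,
        p_min=cfg.p_min, cell_area_km2=area, weight=cfg.occupancy_weight,
    )
    projection.report(summary, out)
    for scen in (summary.current, summary.future):
        print(f"{scen.label}: {scen.habitat.n_cells} suitable cells; "
              f"seeds {scen.mean_seeds_km2:.3g} +/- {scen.se_seeds_km2:.2g} km^-2; "
              f"mass {scen.mean_mass_kg_km2:.1f} +/- {scen.se_mass_kg_km2:.1f} kg km^-2")


if __name__ == "__main__":
    main()
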