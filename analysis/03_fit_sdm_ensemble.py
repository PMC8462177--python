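"""Fit the ensemble species distribution model and map habitat.

Repeated 80/20 split-sample fits of the registered learners, TSS > 0.80
member filter, equal-weight ensemble, permutation variable importance,
response curves, probability maps for the current and future climate, and
habitat accounting under the substrate / land-cover / altitude masks.
Writes results/sdm/."""

import json
import os
import sys
import warnings

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from common import parse_args, stage_dir

from edelweiss import geodata, sdm


def main() -> None:
    cfg, seeds = parse_args(__doc__)
    synth = os.path.join(cfg.outdir, "synth")
    occ = os.path.join(cfg.outdir, "occ")
    out = stage_dir(cfg, "sdm")

    with open(os.path.join(occ, "screening.json")) as fh:
        predictors = json.load(fh)["retained"]
    data = geodata.read_points_csv(os.path.join(occ, "dataset.csv"))
    load = lambda n: geodata.read_ascii_grid(os.path.join(synth, f"{n}.asc"), n)
    rasters = {p: load(p) for p in predictors}
    future = {
        p: load(f"{p}_future") if os.path.exists(os.path.join(synth, f"{p}_future.asc")) else rasters[p]
        for p in predictors
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ensemble, members = sdm.fit_sdm(
            data, predictors, learners=list(cfg.learners), reps=cfg.reps,
            calib_frac=cfg.calib_frac, tss_min=cfg.tss_min, seed=seeds[4],
        )
    held_out = [m.tss for m in members if not m.resubstitution]
    print(f"{len(members)} member models fitted "
          f"({len(cfg.learners)} learners x ({cfg.reps} splits + 1 full fit))")
    print(f"held-out TSS: median {np.median(held_out):.3f}, range "
          f"[{min(held_out):.3f}, {max(held_out):.3f}]")
    print(f"{len(ensemble.members)} members retained with TSS > {cfg.tss_min}")
    y = (data["label"] == "presence").to_numpy().astype(int)
    ens_tss, _ = sdm.tss(ensemble.predict_prob(data), y)
    print(f"ensemble resubstitution TSS = {ens_tss:.3f}")

    for p in predictors:
        imp = sdm.permutation_importance(ensemble, data, p, n_perm=3, seed=seeds[4])
        print(f"  permutation importance [{p}] = {imp:.3f}")
        grid = np.linspace(data[p].min(), data[p].max(), 50)
        sdm.response_curve(ensemble, data, p, grid).to_csv(
            os.path.join(out, f"response_{p}.csv"), index=False
        )

    prob_now = sdm.predict_map(ensemble, rasters)
    prob_fut = sdm.predict_map(ensemble, future)
    elevation = load("elevation")
    masks = dict(substrate_mask=load("substrate_mask"), landcover_mask=load("landcover_mask"),
                 altitude=elevation)
    masked_now, removed_now = sdm.apply_masks(prob_now, alt_min=cfg.alt_min, **masks)
    masked_fut, removed_fut = sdm.apply_masks(prob_fut, alt_min=cfg.alt_min, **masks)
    area = (prob_now.spec.cell_size / 1000.0) ** 2
    hab_now = sdm.habitat_summary(masked_now, cfg.p_min, area, "current", removed_now)
    hab_fut = sdm.habitat_summary(masked_fut, cfg.p_min, area, "future", removed_fut)
    loss = sdm.net_loss(hab_now, hab_fut)
    print(f"habitat P(occ) > {cfg.p_min}: {hab_now.n_cells} cells now, "
          f"{hab_fut.n_cells} in 2050 -> net loss {loss:+.1f}%")
    print(f"  masked out (current): {removed_now}")

    for name, raster in (("prob_current", prob_now), ("prob_future", prob_fut),
                         ("prob_current_masked", masked_now), ("prob_future_masked", masked_fut)):
        geodata.write_ascii_grid(raster, os.path.join(out, f"{name}.asc"))
    with open(os.path.join(out, "sdm_summary.json"), "w") as fh:
        json.dump({
            "member_tss": {f"{m.learner_id}_rep{m.rep}": m.tss for m in members},
            "n_members_retained": len(ensemble.members),
            "ensemble_resubstitution_tss": ens_tss,
            "habitat_current_cells": hab_now.n_cells,
            "habitat_future_cells": hab_fut.n_cells,
            "habitat_net_loss_pct": loss,
        }, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
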