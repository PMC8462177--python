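"""Build the model-ready presence / pseudo-absence dataset.

Reads results/synth/, collapses duplicate presences to grid cells, fits the
95% surface range envelope, draws 10:1 pseudo-absences outside it, screens
predictors by explained deviance (>= 0.30) and pairwise Spearman
correlation (< 0.70), and writes results/occ/."""

import json
import os
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import parse_args, stage_dir

from edelweiss import geodata, occurrence


def main() -> None:
    cfg, seeds = parse_args(__doc__)
    synth = os.path.join(cfg.outdir, "synth")
    out = stage_dir(cfg, "occ")
    preds = list(cfg.predictors)
    rasters = {p: geodata.read_ascii_grid(os.path.join(synth, f"{p}.asc"), p) for p in preds}
    occ = geodata.read_points_csv(os.path.join(synth, "occurrences.csv"))

    spec = rasters[preds[0]].spec
    pts = geodata.assign_cells(occ, spec)
    pres = geodata.dedupe_presences(pts)
    print(f"deduplication: {len(pts)} presence points -> {len(pres)} occupied cells")
    for p in preds:
        pres = geodata.extract_at_points(rasters[p], pres, column=p)
    pres = pres.dropna(subset=preds)

    env = occurrence.fit_envelope(pres, preds, q=cfg.envelope_q)
    rr, cc = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij")
    cx, cy = spec.cell_center(rr.ravel(), cc.ravel())
    cand = pd.DataFrame({"x": cx, "y": cy, "row": rr.ravel(), "col": cc.ravel()})
    for p in preds:
        cand[p] = rasters[p].values[cand["row"], cand["col"]]
    cand = cand.dropna(subset=preds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = occurrence.sample_pseudo_absences(
            env, cand, n_presence=len(pres), ratio=cfg.pa_ratio, seed=seeds[3],
            presence_cells=set(zip(pres["row"], pres["col"])),
        )
    print(f"pseudo-absences: {len(pa)} cells outside the {cfg.envelope_q:.0%} envelope")

    pres = pres.copy()
    pres["label"] = "presence"
    data = pd.concat([pres, pa], ignore_index=True)[["x", "y", "row", "col", "label", *preds]]
    y = (data["label"] == "presence").to_numpy().astype(int)
    imps = {p: occurrence.univariate_importance(data[p].to_numpy(), y) for p in preds}
    corr = occurrence.spearman_matrix(data, preds)
    screen = occurrence.screen_predictors(imps, corr, d2_min=cfg.d2_min, rho_max=cfg.rho_max)
    for p in preds:
        print(f"  D2[{p}] = {imps[p]:.3f}")
    for name, reason in screen.dropped:
        print(f"  dropped {name}: {reason}")
    print(f"retained predictors: {screen.retained}")

    geodata.write_points_csv(data, os.path.join(out, "dataset.csv"))
    env.to_json(os.path.join(out, "envelope.json"))
    with open(os.path.join(out, "screening.json"), "w") as fh:
        json.dump({"importances": imps, "retained": screen.retained,
                   "dropped": screen.dropped}, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
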