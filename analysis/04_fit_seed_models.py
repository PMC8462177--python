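"""Fit the four seed-production models (number/mass x plot/inflorescence).

Generates the demography tables at presence-like cells of the fitted
favorability map, measures trail distances, prepares the standardized
design (logit favorability), and runs backward-AIC simplification of the
Poisson / cube-root-Gaussian mixed models. Writes results/demog/."""

import json
import os
import sys
import warnings

sys.path.insert(0, os.path.dirname(__file__))
from common import parse_args, stage_dir

from edelweiss import geodata, synthetic
from edelweiss.pipeline import fit_demography_models
from edelweiss.synthetic import SyntheticTruth


def main() -> None:
    cfg, seeds = parse_args(__doc__)
    synth = os.path.join(cfg.outdir, "synth")
    sdm_dir = os.path.join(cfg.outdir, "sdm")
    out = stage_dir(cfg, "demog")

    truth = SyntheticTruth.from_json(os.path.join(synth, "truth.json"))
    trails = geodata.TrailSet.from_geojson(os.path.join(synth, "trails.geojson"))
    favorability = geodata.read_ascii_grid(
        os.path.join(sdm_dir, "prob_current.asc"), "favorability"
    )
    plots, infl, _ = synthetic.make_demography(
        truth, favorability, trails, n_sites=cfg.n_sites,
        plots_per_site=cfg.plots_per_site, seed=seeds[5],
    )
    print(f"{len(plots)} plots in {cfg.n_sites} sites; "
          f"{len(infl)} sampled inflorescences")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = fit_demography_models(plots, infl, stepwise=cfg.stepwise)

    for name, model in models.items():
        tab = model.coef_table()
        print(f"\n== {name} (family {model.family}, AIC {model.aic:.1f}, "
              f"Rm2 {model.rm2:.2f}, Rc2 {model.rc2:.2f}) ==")
        for term, row in tab.iterrows():
            star = "*" if row["ci_lo"] > 0 or row["ci_hi"] < 0 else " "
            print(f"  {term:38s} {row['estimate']:+.2f} "
                  f"[{row['ci_lo']:+.2f}, {row['ci_hi']:+.2f}] {star}")

    plots.to_csv(os.path.join(out, "plots.csv"), index=False)
    infl.to_csv(os.path.join(out, "inflorescences.csv"), index=False)
    with open(os.path.join(out, "fitness_models.json"), "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
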