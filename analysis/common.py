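"""Shared glue for the numbered analysis drivers: default paths and seeds."""

import argparse
import os

from edelweiss.pipeline import PipelineConfig, _stage_seeds

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def parse_args(description: str) -> tuple[PipelineConfig, list[int]]:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1, help="master seed")
    parser.add_argument("--out", default=RESULTS, help="results directory")
    args = parser.parse_args()
    cfg = PipelineConfig(outdir=args.out, seed=args.seed)
    return cfg, _stage_seeds(cfg.seed)


def stage_dir(cfg: PipelineConfig, name: str) -> str:
    path = os.path.join(cfg.outdir, name)
    os.makedirs(path, exist_ok=True)
    return path
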