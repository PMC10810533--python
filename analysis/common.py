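"""Shared run configuration for the numbered analysis drivers.

The drivers walk one synthetic dataset through the whole pipeline, stage
by stage, writing everything under ``results/run`` by default.  The
default scale (12 taxa across the four genome-architecture categories,
80 families, 150 codons) is small enough to run on a laptop in minutes
while still exercising every stage.
"""

import argparse

from lsgf.pipeline import RunConfig
from lsgf.simulate import SimulationConfig


def run_config(args) -> RunConfig:
    return RunConfig(
        outdir=args.outdir,
        seed=args.seed,
        simulate=SimulationConfig(
            n_taxa=12,
            category_scheme={"EF": 0.375, "NEF": 0.25, "HE": 0.25, "KA": 0.125},
            n_families=80,
            n_codons=150,
            seed=args.seed,
        ),
        min_aa=80,
        min_members=3,
        selection_max_families=10,
    )


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", default="results/run")
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()
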