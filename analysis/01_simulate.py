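#!/usr/bin/env python
"""Simulate the study dataset: a ciliate-like species tree with EF/NEF/He/Ka
clades, gene-family histories with births, losses and duplications, codon
alignments under group-specific selection regimes, and transcriptome-like
FASTA files with allelic variants and composition-divergent contaminants."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, run_config

from lsgf.pipeline import _update_manifest, stage_simulate

args = parse_args(__doc__)
cfg = run_config(args)
info = stage_simulate(cfg)
_update_manifest(cfg, "simulate", info)
print(f"simulated {info['n_taxa']} taxa, {info['n_families']} families "
      f"({info['n_extinct']} lost entirely), {info['n_transcripts']} transcripts")
print(f"outputs under {cfg.outdir}/simulate/")
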