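#!/usr/bin/env python
"""Fit the group-level codon models per refined family: the RELAX-style
selection-intensity test (K per non-reference group, LRT with |G|-1 df)
and the BUSTED[S]-style episodic diversifying selection screen per group,
with BH-FDR corrected q values."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, run_config

from lsgf.pipeline import _update_manifest, stage_selection

args = parse_args(__doc__)
cfg = run_config(args)
info = stage_selection(cfg)
_update_manifest(cfg, "selection", info)
print(f"fitted {info['n_families_fit']} families: {info['n_relax_tests']} RELAX tests "
      f"({info['n_relax_significant']} significant at q <= {cfg.q_threshold}), "
      f"{info['n_busted_tests']} BUSTED tests")
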