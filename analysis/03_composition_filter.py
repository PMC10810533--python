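#!/usr/bin/env python
"""Score every curated ORF by GC3s and Wright's ENc and keep those inside
the 10-90th percentile GC3s band of the conserved-gene reference set; this
is the composition screen that removes contaminant ORFs."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, run_config

from lsgf.pipeline import _update_manifest, stage_compose

args = parse_args(__doc__)
cfg = run_config(args)
info = stage_compose(cfg)
_update_manifest(cfg, "compose", info)
print(f"GC3s band [{info['band_lower_gc3s']:.3f}, {info['band_upper_gc3s']:.3f}]: "
      f"kept {info['n_kept']}/{info['n_candidates']} ORFs "
      f"({info['n_discarded']} discarded as composition outliers)")
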