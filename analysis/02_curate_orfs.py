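#!/usr/bin/env python
"""Call the largest complete ORF per transcript under the ciliate genetic
code (TAA/TAG = Gln) and collapse allelic variants at 97% identity."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, run_config

from lsgf.pipeline import _update_manifest, stage_curate

args = parse_args(__doc__)
cfg = run_config(args)
info = stage_curate(cfg)
_update_manifest(cfg, "curate", info)
print(f"called {info['n_orfs']} ORFs from {info['n_transcripts']} transcripts; "
      f"{info['n_representatives']} representatives after allelic collapse")
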