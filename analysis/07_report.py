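#!/usr/bin/env python
"""Assemble the summary tables: per-category family counts and sizes,
upset-style sharing, per-branch gains/duplications, and the selection
summary (group, genes, mean branches, positively selected at q <= 0.1)."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, run_config

from lsgf.pipeline import _update_manifest, stage_report

args = parse_args(__doc__)
cfg = run_config(args)
info = stage_report(cfg)
_update_manifest(cfg, "report", info)
report = json.loads((Path(cfg.outdir) / "report" / "report.json").read_text())
print(f"report written under {cfg.outdir}/report/")
for row in report["selection_summary"]:
    print(f"  {row['group']}: {row['positively_selected']}/{row['genes']} "
          f"positively selected (proportion {row['proportion']})")
if report.get("group_size_tests"):
    print(f"  group size tests: {report['group_size_tests']}")
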