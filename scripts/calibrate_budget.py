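#!/usr/bin/env python
"""Re-derive the reference-budget channel layout from scratch.

Runs the staged integer search in ``egunet.calibration`` against the
published per-module budget increments and base totals, verifies the winner
with the real budget engine, and prints the layout plus its engine-computed
figures. The result is frozen in ``egunet.calibration.reference_budget_config``;
this script exists so the freeze is reproducible.

Usage: python scripts/calibrate_budget.py
"""

import sys
from dataclasses import replace

sys.path.insert(0, "src")

from egunet.backbone import BackboneConfig
from egunet.calibration import REFERENCE_DELTAS, search_layout
from egunet.model import ModelConfig, module_deltas


def main():
    layout = search_layout(max_dev=1.0)
    print("search result:", layout)
    cfg = ModelConfig(
        backbone=BackboneConfig(stage_channels=layout["stage_channels"],
                                blocks_per_stage=layout["blocks_per_stage"]),
        num_classes=9,
        decoder_channels=layout["decoder_channels"],
        gn_groups=4,
    )
    deltas = module_deltas(cfg)
    print("\nengine verification (224x224, GMAC convention):")
    for key, vals in deltas.items():
        ref = REFERENCE_DELTAS.get(key)
        print(f"  {key:12s} params {vals['params_m']:8.4f} M  macs {vals['gmacs']:7.4f} G"
              + (f"   (reference {ref[0]} M / {ref[1]} G)" if ref else ""))


if __name__ == "__main__":
    main()
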