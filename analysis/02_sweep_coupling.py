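#!/usr/bin/env python
"""Locate the homogeneous working point G* by sweeping global coupling.

Scores each G on the grid against the target BOLD with static-FC
correlation, sliding-window FCD KS and phase-FCD KS; the phase-FCD KS
minimum defines G*. Writes sweep_g.csv and sweep_summary.yaml.

Usage: python analysis/02_sweep_coupling.py [--config analysis/config.yaml]
"""

import argparse
import json
import logging

from burdendmf.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default="analysis/config.yaml")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = RunConfig.from_yaml(args.config)
    print(json.dumps(run_pipeline(cfg, "sweep-g"), indent=2))


if __name__ == "__main__":
    main()
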