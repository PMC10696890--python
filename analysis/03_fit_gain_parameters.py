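#!/usr/bin/env python
"""Fit the burden-to-gain coefficients at the working point G*.

Runs the constrained Gaussian-process optimization of the six bias/scaling
coefficients (or a restricted subset, per bounds_mode) against the target's
phase-FCD distribution. Writes fit_trace.csv and fit_summary.yaml.

Usage: python analysis/03_fit_gain_parameters.py [--config analysis/config.yaml]
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
    print(json.dumps(run_pipeline(cfg, "fit-gains"), indent=2))


if __name__ == "__main__":
    main()
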