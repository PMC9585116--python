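#!/usr/bin/env python
"""Generate the synthetic two-city biomonitoring study.

Writes the chemical database, cohort, per-batch/per-mode feature tables
(with technical replicates and blanks), wristband profiles, and the
ground-truth sidecar under results/pipeline/.
"""

import argparse

from exposcreen.config import PipelineConfig
from exposcreen.pipeline import stage_generate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    info = stage_generate(cfg)
    print(f"wrote study inputs to {cfg.outdir}")
    print(f"  formulas in suspect database : {info['n_formulas']}")
    print(f"  participants (75/city)       : {info['n_participants']}")
    print(f"  samples incl. blanks         : {info['n_samples']}")
    print(f"  extracted features           : {info['n_features']}")
    print(f"  feature table rows           : {info['n_feature_rows']}")
    print(f"  wristband rows               : {info['n_wristband_rows']}")


if __name__ == "__main__":
    main()
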