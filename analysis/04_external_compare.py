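#!/usr/bin/env python
"""Wristband cross-platform matching and geographic correlations.

Links the targeted silicone-wristband screen (ng/g/week) to serum suspect
chemicals by shared formula and detection-frequency rank, and correlates
per-participant detected-chemical counts with tract-level CalEnviroScreen
style percentiles (pesticide percentile vs pesticide counts, pollution
burden vs total counts), per city.
"""

import argparse

from exposcreen.config import PipelineConfig
from exposcreen.pipeline import stage_compare


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    s = stage_compare(cfg)
    print(f"wristband chemicals detected          : {s['n_wristband_chemicals_detected']}")
    print(f"  with formula in serum database      : {s['n_overlap_possible']}")
    print(f"  also detected in maternal serum     : {s['n_overlap_detected_in_serum']}")
    print(f"formula+rank cross-platform matches   : {s['n_crossplatform_matches']}")
    if s["serum_wristband_rho"] is not None:
        print(f"serum abundance vs wristband ng/g/week rho: "
              f"{s['serum_wristband_rho']:.3f} (p = {s['serum_wristband_rho_p']:.3f})")
    for g in s["geo_correlations"]:
        print(f"{g['city']:<13} {g['category']:<9} vs {g['percentile']:<24} "
              f"rho = {g['rho']:+.3f}  p = {g['p']:.4f}  (n = {g['n']})")


if __name__ == "__main__":
    main()
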