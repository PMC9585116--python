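#!/usr/bin/env python
"""Blank-filter, formula-match, deduplicate and harmonize the feature tables.

Reads the tables written by 01_generate_study.py, applies the 2x water-blank
rule, matches features to database formulas (5 ppm, score >= 70), collapses
duplicates within batch across ionization modes (15 ppm / 0.5 min, keeping
the highest detection frequency), and harmonizes chemicals across the three
batches with connected-component transitivity.  Writes harmonized.csv,
detections.csv, dedup_report.json and qc_report.json.
"""

import argparse

from exposcreen.config import PipelineConfig
from exposcreen.pipeline import stage_features


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed, outdir=args.outdir)
    qc = stage_features(cfg)
    from exposcreen import io

    dedup = io.read_json(f"{cfg.outdir}/dedup_report.json")
    print(f"features in                     : {qc['n_input_features']}")
    print(f"after blank filtering           : {qc['n_after_blank_filter']}")
    print(f"formula-matched (score >= 70)   : {qc['n_formula_matched']}"
          f"  (unmatched: {qc['n_unmatched']})")
    for b, n in sorted(dedup["within_batch_removed"].items()):
        print(f"duplicates removed, batch {b}     : {n}")
    print(f"harmonized suspect chemicals    : {qc['n_harmonized_chemicals']}")


if __name__ == "__main__":
    main()
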