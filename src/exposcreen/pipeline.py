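"""Stage orchestration: generate -> features -> analyze -> compare.

Each stage reads and writes CSV/JSON interfaces under the configured output
directory, so stages can be rerun independently; ``run_pipeline`` executes
all of them and writes a manifest (config hash, seeds, row counts) that
suffices to reproduce the run.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as ann
from . import cohort as coh
from . import external as ext
from . import features as feat
from . import io
from .combat import correct_batch_effects
from .config import PipelineConfig
from .errors import ConfigError
from .synth import (
    generate_chemical_db,
    generate_cohort,
    generate_feature_tables,
    generate_wristband_data,
    make_ground_truth,
)
from .types import COVARIATES, STUDY_MATRICES


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ("db", "cohort", "truth", "features", "wristband")
    return {
        n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, ss.spawn(len(names)))
    }


# ---------------------------------------------------------------------------
# Stage 1: generate
# ---------------------------------------------------------------------------


def stage_generate(cfg: PipelineConfig) -> dict:
    """Generate every synthetic input table and write it to the run directory."""
    cfg.validate()
    out = Path(cfg.outdir)
    seeds = _stage_seeds(cfg.seed)
    db = generate_chemical_db(cfg.db.n_formulas, cfg.db.max_isomers, seeds["db"])
    cohort = generate_cohort(cfg.cohort.n_per_city, seed=seeds["cohort"])
    truth = make_ground_truth(db, cfg.effects, seed=seeds["truth"])
    features, samples = generate_feature_tables(
        db,
        cohort,
        batch_plan=cfg.batch_plan,
        truth=truth,
        seed=seeds["features"],
        config=cfg.feature_gen,
    )
    fresno = cohort.loc[cohort["city"] == "Fresno", "participant_id"]
    wearers = fresno.iloc[: cfg.n_wristband_participants].tolist()
    wristband = generate_wristband_data(
        db, wearers, seed=seeds["wristband"], config=cfg.wristband
    )
    io.write_chemdb(db, out / "chemdb.csv")
    io.write_csv(cohort, out / "cohort.csv")
    io.write_csv(samples, out / "samples.csv")
    io.write_csv(features, out / "features.csv")
    io.write_csv(wristband, out / "wristband.csv")
    io.write_truth(truth, out / "truth.json")
    return {
        "n_formulas": len(db),
        "n_participants": len(cohort),
        "n_samples": len(samples),
        "n_feature_rows": len(features),
        "n_features": features["feature_id"].nunique(),
        "n_wristband_rows": len(wristband),
    }


# ---------------------------------------------------------------------------
# Stage 2: feature pipeline
# ---------------------------------------------------------------------------


def run_feature_pipeline(features, samples, db, cfg: PipelineConfig):
    """Blank-filter, match, dedup within batch/mode, harmonize across batches.

    Returns ``(harmonized_table, detections, dedup_report, qc_report)``.
    Detection frequencies used for duplicate ranking are computed within the
    feature's own batch (its only source of samples).
    """
    t = cfg.thresholds
    filtered = feat.filter_blank_features(features, samples, t.blank_ratio)
    matched = feat.match_formulas(filtered, db, t.match_ppm, t.score_threshold)
    per_sample = feat.average_replicates(
        filtered[filtered["feature_id"].isin(matched["feature_id"])]
    )
    sinfo = samples.set_index("sample_id")
    study_ids = set(samples.loc[samples["matrix"].isin(STUDY_MATRICES), "sample_id"])
    per_sample = per_sample[per_sample["sample_id"].isin(study_ids)]
    abund_all = per_sample.pivot(
        index="feature_id", columns="sample_id", values="abundance"
    ).fillna(0.0)

    batch_of_feature = matched.set_index("feature_id")["batch"]
    batch_of_sample = sinfo["batch"]
    dfreq = {}
    per_batch_tables = {}
    dedup_report = {"within_batch_removed": {}, "groups": {}}
    for b, meta_b in matched.groupby("batch", sort=True):
        cols = [
            c for c in abund_all.columns if batch_of_sample.get(c) == b
        ]
        ab = abund_all.loc[
            abund_all.index.intersection(meta_b["feature_id"]), cols
        ]
        det = feat.call_detections(ab, t.detection_threshold)
        freq_b = det.frequency
        for fid, fr in freq_b.items():
            dfreq[fid] = fr
        by_mode = {m: g for m, g in meta_b.groupby("mode", sort=True)}
        merged, dgroups = feat.merge_modes(by_mode, freq_b, t.dup_ppm, t.dup_rt)
        dedup_report["within_batch_removed"][int(b)] = int(len(meta_b) - len(merged))
        dedup_report["groups"][int(b)] = [
            {"members": sorted(g.members), "retained": g.retained_id}
            for g in dgroups
            if len(g.members) > 1
        ]
        ab_merged = ab.loc[ab.index.intersection(merged["feature_id"]), cols]
        per_batch_tables[int(b)] = (merged.reset_index(drop=True), ab_merged)

    dfreq = pd.Series(dfreq)
    table = feat.harmonize_batches(per_batch_tables, dfreq, t.dup_ppm, t.dup_rt)
    if cfg.drop_unreplicated_across_batches and len(table.meta):
        keep = table.meta.loc[table.meta["n_batches"] > 1, "chemical"]
        table.meta = table.meta[table.meta["chemical"].isin(keep)].reset_index(drop=True)
        table.abundance = table.abundance.loc[keep]
        table.provenance = {c: table.provenance[c] for c in keep}
    detections = feat.call_detections(table.abundance, t.detection_threshold)
    qc = {
        "n_input_features": int(features["feature_id"].nunique()),
        "n_after_blank_filter": int(filtered["feature_id"].nunique()),
        "n_formula_matched": int(len(matched)),
        "n_unmatched": int(matched.attrs.get("n_unmatched", 0)),
        "n_harmonized_chemicals": int(len(table.meta)),
        "matrix_blank_note": "matrix blanks and spikes are reported but not used "
        "for filtering; the water blank is the procedural blank",
    }
    return table, detections, dedup_report, qc


def stage_features(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.outdir)
    features = io.read_csv(out / "features.csv")
    samples = io.read_csv(out / "samples.csv")
    db = io.read_chemdb(out / "chemdb.csv")
    table, detections, dedup_report, qc = run_feature_pipeline(
        features, samples, db, cfg
    )
    io.write_csv(io.harmonized_to_long(table.abundance), out / "harmonized.csv")
    io.write_csv(table.meta, out / "harmonized_meta.csv")
    det_long = detections.detected.reset_index().melt(
        id_vars="chemical", var_name="sample_id", value_name="detected"
    )
    io.write_csv(det_long.sort_values(["chemical", "sample_id"]), out / "detections.csv")
    io.write_json(dedup_report, out / "dedup_report.json")
    io.write_json(qc, out / "qc_report.json")
    return qc


# ---------------------------------------------------------------------------
# Stage 3: cohort analysis
# ---------------------------------------------------------------------------


def _matrix_samples(samples: pd.DataFrame, matrix: str) -> pd.DataFrame:
    return samples[samples["matrix"] == matrix]


def analyze_matrix(
    abundance: pd.DataFrame,
    samples: pd.DataFrame,
    cohort: pd.DataFrame,
    db,
    cfg: PipelineConfig,
    matrix: str = "maternal",
) -> dict:
    """Propensity-match, batch-correct, and test one biological matrix.

    Returns a dict with the matched cohort, corrected abundances,
    differential results (annotated), batch-mixing diagnostics, and
    per-participant detected counts.
    """
    t = cfg.thresholds
    msamp = _matrix_samples(samples, matrix)
    have = cohort["participant_id"].isin(msamp["participant_id"])
    sub = cohort[have].reset_index(drop=True)
    model = coh.estimate_propensity(sub, COVARIATES)
    matched = coh.match_nearest_neighbor(model, sub, matrix=matrix)
    matched_ids = set(matched.fresno_ids) | set(matched.sf_ids)
    msamp = msamp[msamp["participant_id"].isin(matched_ids)]
    sample_ids = [s for s in abundance.columns if s in set(msamp["sample_id"])]
    ab = abundance[sample_ids]
    pid_of = msamp.set_index("sample_id")["participant_id"]
    city_of = msamp.set_index("sample_id")["participant_id"].map(
        cohort.set_index("participant_id")["city"]
    )
    batch_of = msamp.set_index("sample_id")["batch"]

    logged = coh.log_transform(ab, t.zero_sub)
    design = pd.get_dummies(
        cohort.set_index("participant_id")
        .loc[pid_of.reindex(sample_ids), list(COVARIATES)]
        .astype(str),
        drop_first=True,
        dtype=float,
    )
    design.index = sample_ids
    corrected = correct_batch_effects(logged, batch_of, design)
    corrected_nat = np.exp(corrected)
    detections = feat.call_detections(corrected_nat, t.detection_threshold)
    ratio_source = corrected_nat if cfg.ratio_on_corrected else ab
    diff = coh.differential_detection(
        detections.detected, city_of, abundance=ratio_source, alpha=t.alpha
    )
    mixing = {
        "pre": coh.batch_mixing_check(logged, batch_of).weighted_r2
        if len(set(batch_of)) > 1 and logged.shape[1] > 2
        else 0.0,
        "post": coh.batch_mixing_check(corrected, batch_of).weighted_r2
        if len(set(batch_of)) > 1 and corrected.shape[1] > 2
        else 0.0,
    }
    # annotation: detection-frequency ranked isomer assignment
    formula = {c: c.rsplit("#", 1)[0] for c in diff["chemical"]}
    ann_table = pd.DataFrame(
        {
            "chemical": diff["chemical"],
            "formula": [formula[c] for c in diff["chemical"]],
            "detection_frequency": detections.frequency.reindex(diff["chemical"]).to_numpy(),
        }
    )
    annotations = ann.annotate_chemicals(ann_table, db)
    diff = diff.merge(
        annotations[["chemical", "isomer", "final_score", "categories"]],
        on="chemical",
        how="left",
    )
    counts = detections.detected.sum(axis=0)
    counts.index = counts.index.map(pid_of)
    return {
        "model": model,
        "matched": matched,
        "corrected": corrected,
        "corrected_nat": corrected_nat,
        "detections": detections,
        "differential": diff,
        "annotations": annotations,
        "mixing": mixing,
        "detected_counts": counts,
        "city_of": city_of,
        "sample_pid": pid_of,
    }


def stage_analyze(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.outdir)
    abundance = io.harmonized_from_long(io.read_csv(out / "harmonized.csv"))
    samples = io.read_csv(out / "samples.csv")
    cohort = io.read_csv(out / "cohort.csv")
    db = io.read_chemdb(out / "chemdb.csv")
    summary = {}
    results = {}
    for matrix in cfg.matrices:
        res = analyze_matrix(abundance, samples, cohort, db, cfg, matrix)
        results[matrix] = res
        io.write_csv(res["matched"].as_frame(), out / f"matched_pairs_{matrix}.csv")
        io.write_csv(
            res["differential"].sort_values("chemical"),
            out / f"differential_results_{matrix}.csv",
        )
        io.write_csv(res["annotations"], out / f"annotations_{matrix}.csv")
        corrected_long = io.harmonized_to_long(res["corrected"])
        io.write_csv(corrected_long, out / f"corrected_{matrix}.csv")
        io.write_json(res["mixing"], out / f"batch_mixing_{matrix}.json")
        counts = res["detected_counts"]
        city = cohort.set_index("participant_id")["city"]
        summary[matrix] = {
            "n_pairs": len(res["matched"].pairs),
            "n_differential": int(res["differential"]["differential"].sum()),
            "mean_detected_fresno": float(counts[city.reindex(counts.index) == "Fresno"].mean()),
            "mean_detected_sf": float(
                counts[city.reindex(counts.index) == "SanFrancisco"].mean()
            ),
            "batch_r2_pre": res["mixing"]["pre"],
            "batch_r2_post": res["mixing"]["post"],
        }
    # maternal-cord paired correlation on log abundances
    if {"maternal", "cord"} <= set(results):
        r = _maternal_cord_r(results)
        if r is not None:
            summary["maternal_cord_pearson_r"] = r
    if cfg.make_figures:
        _make_figures(results, cohort, out)
    io.write_json(summary, out / "analyze_summary.json")
    return summary


def _maternal_cord_r(results: dict):
    mat = results["maternal"]
    crd = results["cord"]
    m_log = np.log(mat["corrected_nat"])
    c_log = np.log(crd["corrected_nat"])
    m_pid = mat["sample_pid"]
    c_pid = crd["sample_pid"]
    common_pid = sorted(set(m_pid) & set(c_pid))
    common_chem = m_log.index.intersection(c_log.index)
    if len(common_pid) < 3 or len(common_chem) == 0:
        return None
    m_cols = {m_pid[s]: s for s in m_log.columns if m_pid[s] in common_pid}
    c_cols = {c_pid[s]: s for s in c_log.columns if c_pid[s] in common_pid}
    pids = [p for p in common_pid if p in m_cols and p in c_cols]
    x = m_log.loc[common_chem, [m_cols[p] for p in pids]].to_numpy().ravel()
    y = c_log.loc[common_chem, [c_cols[p] for p in pids]].to_numpy().ravel()
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return None
    return coh.paired_correlation(x[mask], y[mask])


def _make_figures(results: dict, cohort: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    city = cohort.set_index("participant_id")["city"]
    for matrix, res in results.items():
        counts = res["detected_counts"]
        fig, axis = plt.subplots(figsize=(6, 4))
        for c, color in (("Fresno", "tab:orange"), ("SanFrancisco", "tab:blue")):
            vals = counts[city.reindex(counts.index) == c]
            axis.hist(vals, bins=15, alpha=0.6, label=c, color=color)
        axis.set_xlabel("suspect chemicals detected per participant")
        axis.set_ylabel("participants")
        axis.legend()
        fig.savefig(figdir / f"detected_counts_{matrix}.png", dpi=120)
        plt.close(fig)
        diff = res["differential"]
        dd = diff[diff["differential"]]
        if len(dd):
            fig, axis = plt.subplots(figsize=(7, 4))
            axis.scatter(dd["df_fresno"], dd["df_sf"],
                         s=20 + 10 * np.log1p(dd.get("abundance_ratio", 1.0)))
            axis.set_xlabel("detection frequency, Fresno")
            axis.set_ylabel("detection frequency, San Francisco")
            axis.set_title(f"differentially detected suspects ({matrix})")
            fig.savefig(figdir / f"differential_{matrix}.png", dpi=120)
            plt.close(fig)


# ---------------------------------------------------------------------------
# Stage 4: external comparisons
# ---------------------------------------------------------------------------


def stage_compare(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.outdir)
    wristband = io.read_csv(out / "wristband.csv")
    cohort = io.read_csv(out / "cohort.csv")
    samples = io.read_csv(out / "samples.csv")
    db = io.read_chemdb(out / "chemdb.csv")
    abundance = io.harmonized_from_long(io.read_csv(out / "harmonized.csv"))
    det_long = io.read_csv(out / "detections.csv")
    detected = det_long.pivot(index="chemical", columns="sample_id", values="detected")
    detected.columns.name = None
    annotations = io.read_csv(
        out / "annotations_maternal.csv", keep_default_na=False
    )

    wearers = sorted(wristband["participant_id"].unique())
    wb_freq = ext.wristband_detection_frequency(wristband)

    msamp = samples[samples["matrix"] == "maternal"]
    pid_of = msamp.set_index("sample_id")["participant_id"]
    wearer_cols = [
        s for s in detected.columns if pid_of.get(s) in set(wearers)
    ]
    serum_freq_all = detected[wearer_cols].mean(axis=1) if wearer_cols else (
        detected.mean(axis=1) * 0.0
    )
    serum_table = pd.DataFrame(
        {
            "chemical": detected.index,
            "formula": [c.rsplit("#", 1)[0] for c in detected.index],
            "detection_frequency": serum_freq_all.to_numpy(),
        }
    )
    matches, excluded = ext.match_wristband_to_serum(wb_freq, serum_table, db)
    io.write_csv(matches, out / "crossplatform_matches.csv")
    io.write_csv(excluded, out / "crossplatform_excluded.csv")

    # participant-level abundance vs concentration over matched formulas
    rho_ab = None
    if len(matches):
        pairs_x, pairs_y = [], []
        conc = wristband.set_index(["chemical", "participant_id"])["concentration"]
        for m in matches.itertuples():
            for s in wearer_cols:
                pid = pid_of[s]
                c = conc.get((m.wristband_chemical, pid), 0.0)
                a = abundance.at[m.serum_chemical, s] if s in abundance.columns else 0.0
                if c > 0 and a > 0:
                    pairs_x.append(np.log(a))
                    pairs_y.append(np.log(c))
        if len(pairs_x) >= 3 and len(set(pairs_x)) > 1 and len(set(pairs_y)) > 1:
            rho_ab = ext.spearman_rho(pairs_x, pairs_y)

    # geographic correlations per city
    geo_rows = []
    city_of_pid = cohort.set_index("participant_id")["city"]
    for category, pct_col in (
        ("pesticide", "pesticide_pctile"),
        ("all", "pollution_burden_pctile"),
    ):
        counts = ext.count_chemicals_by_category(detected, annotations, category)
        counts.index = counts.index.map(pid_of)
        counts = counts[counts.index.notna()]
        pct = cohort.set_index("participant_id")[pct_col]
        for city in ("Fresno", "SanFrancisco"):
            pids = [p for p in counts.index if city_of_pid.get(p) == city]
            if len(pids) < 3:
                continue
            try:
                rho, p = ext.correlate_geo(counts.loc[pids], pct.loc[pids])
            except Exception:
                continue
            geo_rows.append(
                {
                    "city": city,
                    "category": category,
                    "percentile": pct_col,
                    "rho": rho,
                    "p": p,
                    "n": len(pids),
                }
            )
    geo = pd.DataFrame(geo_rows, columns=["city", "category", "percentile", "rho", "p", "n"])
    io.write_csv(geo, out / "geo_correlations.csv")

    n_wb_detected = int((wb_freq["detection_frequency"] > 0).sum())
    overlap_possible = int(wb_freq["formula"].isin(set(db.formulas)).sum())
    detected_serum_formulas = set(
        serum_table.loc[serum_freq_all.to_numpy() > 0, "formula"]
    )
    overlap_detected = int(
        wb_freq["formula"].isin(detected_serum_formulas).sum()
    )
    summary = {
        "n_wristband_chemicals_detected": n_wb_detected,
        "n_overlap_possible": overlap_possible,
        "n_overlap_detected_in_serum": overlap_detected,
        "n_crossplatform_matches": int(len(matches)),
        "serum_wristband_rho": rho_ab[0] if rho_ab else None,
        "serum_wristband_rho_p": rho_ab[1] if rho_ab else None,
        "geo_correlations": geo_rows,
    }
    io.write_json(summary, out / "compare_summary.json")
    return summary


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all four stages and write a reproducibility manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "seeds": _stage_seeds(cfg.seed),
        "version": __version__,
        "stages": {},
    }
    manifest["stages"]["generate"] = stage_generate(cfg)
    manifest["stages"]["features"] = stage_features(cfg)
    manifest["stages"]["analyze"] = stage_analyze(cfg)
    manifest["stages"]["compare"] = stage_compare(cfg)
    io.write_json(manifest, out / "manifest.json")
    return manifest
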