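"""Feature-table processing: blank filtering, formula matching, duplicate
collapsing within and across ionization modes and batches, and replicate
averaging.

Conventions (documented inclusive boundaries):

* blank rule — a study-sample abundance is kept iff it is ``ratio`` times the
  batch water-blank mean **or higher** (exactly 2x qualifies);
* detection — abundance **>= 5000** counts as detected;
* duplicate relation — same formula AND mass difference **<= 15 ppm**
  (relative to the smaller mass) AND RT difference **<= 0.5 min**; groups are
  connected components of this relation, so two features that share a match
  but do not match each other are still duplicates.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    ChemicalDatabase,
    DetectionMatrix,
    DuplicateGroup,
    HarmonizedTable,
    STUDY_MATRICES,
)

#: Relative guard so exact-boundary comparisons are not lost to rounding.
_EPS = 1e-9

FEATURE_COLUMNS = (
    "feature_id",
    "neutral_mass",
    "rt",
    "mode",
    "batch",
    "sample_id",
    "replicate",
    "abundance",
)


# ---------------------------------------------------------------------------
# Blank filtering
# ---------------------------------------------------------------------------


def filter_blank_features(
    features: pd.DataFrame, samples: pd.DataFrame, ratio: float = 2.0
) -> pd.DataFrame:
    """Zero study-sample cells below ``ratio`` x the batch water-blank mean.

    The water blank is the procedural blank: for each feature, the mean
    abundance across the water-blank replicates of its batch is the
    reference.  Study-sample cells strictly below ``ratio`` times that
    reference are set to 0; a feature whose study cells are all zero
    afterwards is dropped.  A zero blank reference filters nothing.
    Filtering is applied per cell rather than per feature — the conservative
    reading that reduces to whole-feature removal when every cell fails.
    """
    sinfo = samples.set_index("sample_id")
    feat_batches = set(features["batch"].unique())
    wb_batches = set(samples.loc[samples["matrix"] == "water_blank", "batch"])
    missing = sorted(feat_batches - wb_batches)
    if missing:
        raise ValidationError(f"batch(es) without water blank: {missing}")
    f = features.copy()
    matrix = f["sample_id"].map(sinfo["matrix"])
    is_blank = matrix == "water_blank"
    blank_mean = (
        f.loc[is_blank].groupby("feature_id")["abundance"].mean()
    )
    ref = f["feature_id"].map(blank_mean).fillna(0.0)
    is_study = matrix.isin(STUDY_MATRICES)
    fails = is_study & (ref > 0) & (f["abundance"] < ratio * ref * (1.0 - _EPS))
    f.loc[fails, "abundance"] = 0.0
    alive = f.loc[is_study].groupby("feature_id")["abundance"].max()
    dead = set(alive.index[alive <= 0])
    # features with no study cells at all carry no information either
    no_study = set(f["feature_id"]) - set(alive.index)
    drop = dead | no_study
    return f.loc[~f["feature_id"].isin(drop)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Formula matching
# ---------------------------------------------------------------------------


def match_formulas(
    features: pd.DataFrame,
    db: ChemicalDatabase,
    ppm_tol: float = 5.0,
    score_threshold: float = 70.0,
) -> pd.DataFrame:
    """Assign each feature to the database formula nearest in mass.

    A feature matches the formula minimising the absolute ppm error
    (relative to the formula mass) among those within ``ppm_tol``.  The
    match score is ``100 * (1 - |ppm|/ppm_tol)``, a mass-accuracy-only stand
    in for vendor scores that also use isotope patterns; with the defaults a
    score of 70 corresponds to |ppm| <= 1.5.  Features below the threshold
    or outside the tolerance are dropped (a normal outcome, not an error).

    Returns one row per matched feature: the feature metadata plus
    ``formula``, ``formula_mass``, ``ppm_error`` and ``score``.
    """
    if len(db) == 0:
        raise ValidationError("chemical database is empty")
    meta_cols = [c for c in features.columns if c not in ("sample_id", "replicate", "abundance")]
    meta = features[meta_cols].drop_duplicates("feature_id").reset_index(drop=True)
    out = []
    for row in meta.itertuples(index=False):
        entry, ppm = db.nearest_formula(row.neutral_mass)
        if abs(ppm) > ppm_tol * (1.0 + _EPS):
            continue
        score = 100.0 * (1.0 - abs(ppm) / ppm_tol)
        if score < score_threshold * (1.0 - _EPS):
            continue
        rec = row._asdict()
        rec.update(
            formula=entry.formula,
            formula_mass=entry.monoisotopic_mass,
            ppm_error=ppm,
            score=score,
        )
        out.append(rec)
    cols = meta_cols + ["formula", "formula_mass", "ppm_error", "score"]
    matched = pd.DataFrame(out, columns=cols)
    matched.attrs["n_unmatched"] = len(meta) - len(matched)
    return matched


# ---------------------------------------------------------------------------
# Replicates and detections
# ---------------------------------------------------------------------------


def average_replicates(features: pd.DataFrame) -> pd.DataFrame:
    """Average the two technical replicates per (feature, sample) cell.

    A cell observed (abundance > 0) in only one of the two replicates is
    treated as not extracted and set to 0.  More than two replicates is a
    schema violation.
    """
    reps = set(features["replicate"].unique())
    if not reps <= {1, 2}:
        raise ValidationError(f"more than two technical replicates: {sorted(reps)}")
    wide = features.pivot_table(
        index=["feature_id", "sample_id"],
        columns="replicate",
        values="abundance",
        aggfunc="first",
    )
    r1 = wide[1].fillna(0.0).to_numpy() if 1 in wide.columns else np.zeros(len(wide))
    r2 = wide[2].fillna(0.0).to_numpy() if 2 in wide.columns else np.zeros(len(wide))
    both = (r1 > 0) & (r2 > 0)
    avg = np.where(both, (r1 + r2) / 2.0, 0.0)
    out = wide.index.to_frame(index=False)
    out["abundance"] = avg
    return out


def call_detections(
    abundance: pd.DataFrame, threshold: float = 5000.0
) -> DetectionMatrix:
    """Call detections on a chemicals/features x samples abundance matrix.

    A cell is detected iff its abundance is at or above the threshold
    (inclusive).  Negative abundances are invalid.
    """
    vals = abundance.to_numpy()
    if (vals < 0).any():
        raise ValidationError("negative abundance in detection input")
    detected = abundance >= threshold
    return DetectionMatrix(detected=detected, abundance=abundance, threshold=threshold)


# ---------------------------------------------------------------------------
# Duplicate grouping and collapsing
# ---------------------------------------------------------------------------


def pairwise_match(
    mass: np.ndarray,
    rt: np.ndarray,
    ppm_tol: float = 15.0,
    rt_tol: float = 0.5,
) -> np.ndarray:
    """Boolean pairwise duplicate relation (ppm w.r.t. the smaller mass)."""
    m = np.asarray(mass, dtype=float)
    r = np.asarray(rt, dtype=float)
    dm = np.abs(m[:, None] - m[None, :])
    denom = np.minimum(m[:, None], m[None, :])
    ppm = dm / denom * 1e6
    drt = np.abs(r[:, None] - r[None, :])
    return (ppm <= ppm_tol * (1.0 + _EPS)) & (drt <= rt_tol + rt_tol * _EPS + 1e-12)


def find_duplicate_groups(
    matched: pd.DataFrame,
    ppm_tol: float = 15.0,
    rt_tol: float = 0.5,
) -> list:
    """Group features into duplicate sets (connected components).

    Comparison is restricted to features sharing a formula; the pairwise
    relation requires mass within ``ppm_tol`` ppm of the smaller mass and RT
    within ``rt_tol`` minutes, both inclusive.  Features that share a match
    without matching each other land in the same group (transitivity).
    Singleton groups are returned too.
    """
    g = nx.Graph()
    g.add_nodes_from(matched["feature_id"])
    for _, grp in matched.groupby("formula", sort=False):
        if len(grp) < 2:
            continue
        ids = grp["feature_id"].to_numpy()
        adj = pairwise_match(
            grp["neutral_mass"].to_numpy(), grp["rt"].to_numpy(), ppm_tol, rt_tol
        )
        ii, jj = np.nonzero(np.triu(adj, k=1))
        g.add_edges_from(zip(ids[ii], ids[jj]))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return [set(c) for c in comps]


def collapse_duplicates(
    groups: Iterable, stats: pd.DataFrame
) -> tuple:
    """Retain one feature per duplicate group: the highest detection frequency.

    Ties go to the smaller |ppm_error|, then the lexicographically smallest
    feature id — a deterministic rule, so the retained set is invariant to
    input order.  ``stats`` must be indexed by feature_id with columns
    ``detection_frequency`` and ``ppm_error``.

    Returns ``(retained_ids, duplicate_groups)``.
    """
    retained = []
    dgroups = []
    for members in groups:
        if not members:
            raise ValidationError("empty duplicate group")
        best = min(
            sorted(members),
            key=lambda fid: (
                -float(stats.at[fid, "detection_frequency"]),
                abs(float(stats.at[fid, "ppm_error"])),
                fid,
            ),
        )
        retained.append(best)
        dgroups.append(DuplicateGroup(members=frozenset(members), retained_id=best))
    return sorted(retained), dgroups


def merge_modes(
    tables_by_mode: Mapping[str, pd.DataFrame],
    detection_frequency: pd.Series,
    ppm_tol: float = 15.0,
    rt_tol: float = 0.5,
) -> tuple:
    """Combine positive- and negative-mode suspect tables within a batch.

    Concatenates the matched tables, then runs duplicate grouping and
    collapsing across modes.  A chemical ionising in both modes inside the
    tolerances collapses to its higher-detection-frequency feature;
    mode-exclusive chemicals pass through.

    Returns ``(merged_table, duplicate_groups)``.
    """
    parts = [t for t in tables_by_mode.values() if t is not None and len(t)]
    if not parts:
        return pd.DataFrame(columns=["feature_id"]), []
    meta = pd.concat(parts, ignore_index=True)
    groups = find_duplicate_groups(meta, ppm_tol, rt_tol)
    stats = meta.set_index("feature_id")[["ppm_error"]].copy()
    stats["detection_frequency"] = detection_frequency.reindex(stats.index).fillna(0.0)
    retained, dgroups = collapse_duplicates(groups, stats)
    merged = meta[meta["feature_id"].isin(retained)].reset_index(drop=True)
    return merged, dgroups


# ---------------------------------------------------------------------------
# Cross-batch harmonisation
# ---------------------------------------------------------------------------


def harmonize_batches(
    per_batch: Mapping[int, tuple],
    detection_frequency: pd.Series,
    ppm_tol: float = 15.0,
    rt_tol: float = 0.5,
) -> HarmonizedTable:
    """Merge per-batch deduplicated tables into one chemicals x samples table.

    The duplicate relation (same formula, <=15 ppm on experimental mass,
    <=0.5 min) is replicated across batches with connected-component
    transitivity, so a chemical chained through consecutive batches becomes
    one harmonized chemical.  If a component contains two features from the
    same batch (possible only through a cross-batch bridge), the
    higher-detection-frequency member represents that batch and a warning is
    emitted.  Batch-exclusive chemicals are kept, with 0 abundance in the
    batches that lack them.

    ``per_batch`` maps batch -> (matched_table, abundance) where abundance is
    a feature x sample (study samples of that batch) DataFrame.
    """
    metas = []
    for b, (meta, _) in sorted(per_batch.items()):
        m = meta.copy()
        m["batch"] = b
        metas.append(m)
    combined = pd.concat(metas, ignore_index=True) if metas else pd.DataFrame(
        columns=["feature_id", "formula", "neutral_mass", "rt", "batch"]
    )
    groups = find_duplicate_groups(combined, ppm_tol, rt_tol)
    by_id = combined.set_index("feature_id")
    all_samples = []
    for b, (_, ab) in sorted(per_batch.items()):
        all_samples.extend(ab.columns)
    counters: dict = {}
    records = []
    provenance = {}
    rows = {}

    def _freq(fid):
        return float(detection_frequency.get(fid, 0.0))

    # deterministic order: by formula then smallest member id
    ordered = sorted(groups, key=lambda c: (by_id.at[sorted(c)[0], "formula"], sorted(c)[0]))
    for members in ordered:
        members = sorted(members)
        formula = by_id.at[members[0], "formula"]
        counters[formula] = counters.get(formula, 0) + 1
        chem = f"{formula}#{counters[formula]}"
        per_b: dict = {}
        for fid in members:
            per_b.setdefault(int(by_id.at[fid, "batch"]), []).append(fid)
        reps = {}
        for b, fids in per_b.items():
            if len(fids) > 1:
                warnings.warn(
                    f"cross-batch component for {formula} holds {len(fids)} "
                    f"features from batch {b}; keeping highest detection frequency",
                    stacklevel=2,
                )
            reps[b] = min(fids, key=lambda f: (-_freq(f), f))
        abund = pd.Series(0.0, index=pd.Index(all_samples, name="sample_id"))
        for b, fid in reps.items():
            ab = per_batch[b][1]
            if fid in ab.index:
                abund.loc[ab.columns] = ab.loc[fid].to_numpy()
        rows[chem] = abund
        provenance[chem] = {b: list(fids) for b, fids in sorted(per_b.items())}
        records.append(
            {
                "chemical": chem,
                "formula": formula,
                "neutral_mass": float(by_id.loc[members, "neutral_mass"].mean()),
                "rt": float(by_id.loc[members, "rt"].mean()),
                "n_batches": len(per_b),
                "true_chemical": (
                    by_id.loc[members, "true_chemical"].mode().iat[0]
                    if "true_chemical" in by_id.columns and
                    by_id.loc[members, "true_chemical"].notna().any()
                    else None
                ),
            }
        )
    abundance = pd.DataFrame(rows).T
    if len(abundance):
        abundance.index.name = "chemical"
        abundance = abundance[all_samples]
    meta = pd.DataFrame(records)
    return HarmonizedTable(abundance=abundance, meta=meta, provenance=provenance)
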