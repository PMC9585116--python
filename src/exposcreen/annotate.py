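"""Isomer annotation: pick the most probable structure for a formula-level
suspect chemical.

The score for an isomer averages two terms: the *blind probability*
(1/k over the formula's k isomers) and an *evidence score* combining how
often the isomer is mentioned in PubMed and PubChem with its production
volume, each min-max scaled to [0, 1] across the whole database.  When one
formula yields several distinct suspect chemicals, isomers are assigned by
rank: most probable isomer to the chemical with the highest detection
frequency, and so on down.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .types import ChemicalDatabase, IsomerScore

_METRICS = ("pubmed_count", "pubchem_count", "production_volume")


def blind_probability(formula: str, db: ChemicalDatabase) -> float:
    """1 over the number of isomers recorded for the formula."""
    entry = db.formula(formula)
    return 1.0 / len(entry.isomers)


def evidence_table(
    db: ChemicalDatabase, weights: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Scaled evidence metrics per isomer, plus their weighted mean.

    Each metric is min-max scaled across the entire database (not within
    formula), preserving cross-formula comparability; a constant column
    scales to 0 for every isomer.  Missing values count as 0 before scaling.
    """
    w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
    if len(w) != 3 or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be three non-negative numbers, not all zero")
    df = db.to_frame().set_index("isomer")
    scaled = {}
    for m in _METRICS:
        col = pd.to_numeric(df[m], errors="coerce").fillna(0.0)
        lo, hi = col.min(), col.max()
        scaled[m] = (col - lo) / (hi - lo) if hi > lo else col * 0.0
    out = pd.DataFrame(scaled)
    out["evidence_score"] = (out[list(_METRICS)].to_numpy() * w).sum(axis=1) / w.sum()
    return out


def evidence_score(
    isomer: str, db: ChemicalDatabase, weights: Optional[Sequence[float]] = None
) -> float:
    table = evidence_table(db, weights)
    if isomer not in table.index:
        raise LookupError(f"isomer {isomer!r} not in database")
    return float(table.at[isomer, "evidence_score"])


def score_isomers(
    formula: str,
    db: ChemicalDatabase,
    weights: Optional[Sequence[float]] = None,
    _evidence: Optional[pd.DataFrame] = None,
) -> list:
    """Score and rank a formula's isomers by final score (descending).

    ``final = (blind + evidence) / 2``; ties break on isomer name so the
    ranking is a deterministic permutation of 1..k.
    """
    entry = db.formula(formula)
    ev = _evidence if _evidence is not None else evidence_table(db, weights)
    blind = 1.0 / len(entry.isomers)
    scored = []
    for iso in entry.isomers:
        e = float(ev.at[iso.name, "evidence_score"])
        scored.append((iso.name, blind, e, (blind + e) / 2.0))
    scored.sort(key=lambda t: (-t[3], t[0]))
    return [
        IsomerScore(
            name=n, blind_probability=b, evidence_score=e, final_score=f, rank=i + 1
        )
        for i, (n, b, e, f) in enumerate(scored)
    ]


def assign_isomers_by_rank(
    formula: str,
    chemical_frequencies: Mapping[str, float],
    db: ChemicalDatabase,
    weights: Optional[Sequence[float]] = None,
    _evidence: Optional[pd.DataFrame] = None,
) -> dict:
    """Pair suspect chemicals of one formula with isomers, rank to rank.

    Chemicals sorted by descending detection frequency (ties by name) are
    paired positionally with isomers sorted by score rank — a bijection onto
    the top-|chemicals| isomers.  More chemicals than isomers is an error.
    """
    scores = score_isomers(formula, db, weights, _evidence=_evidence)
    chems = sorted(chemical_frequencies, key=lambda c: (-chemical_frequencies[c], c))
    if len(chems) > len(scores):
        raise AnnotationError(
            f"formula {formula}: {len(chems)} suspect chemicals but only "
            f"{len(scores)} isomers"
        )
    return {chem: scores[i] for i, chem in enumerate(chems)}


def annotate_chemicals(
    table: pd.DataFrame,
    db: ChemicalDatabase,
    weights: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Annotate a harmonized chemical table (columns chemical, formula,
    detection_frequency) with the rank-assigned isomer and its categories."""
    ev = evidence_table(db, weights)
    rows = []
    for formula, grp in table.groupby("formula", sort=True):
        freqs = dict(zip(grp["chemical"], grp["detection_frequency"]))
        k = len(db.formula(formula).isomers)
        overflow = []
        if len(freqs) > k:
            # more surviving suspect chemicals than known isomers: annotate the
            # top-k by detection frequency, leave the remainder unassigned
            ordered = sorted(freqs, key=lambda c: (-freqs[c], c))
            overflow = ordered[k:]
            freqs = {c: freqs[c] for c in ordered[:k]}
        assignment = assign_isomers_by_rank(formula, freqs, db, _evidence=ev)
        for chem in overflow:
            rows.append(
                {
                    "chemical": chem,
                    "formula": formula,
                    "isomer": "",
                    "blind_probability": np.nan,
                    "evidence_score": np.nan,
                    "final_score": np.nan,
                    "rank": -1,
                    "categories": "",
                }
            )
        for chem, sc in assignment.items():
            iso = db.isomer(sc.name)
            rows.append(
                {
                    "chemical": chem,
                    "formula": formula,
                    "isomer": sc.name,
                    "blind_probability": sc.blind_probability,
                    "evidence_score": sc.evidence_score,
                    "final_score": sc.final_score,
                    "rank": sc.rank,
                    "categories": ";".join(sorted(iso.categories)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chemical",
            "formula",
            "isomer",
            "blind_probability",
            "evidence_score",
            "final_score",
            "rank",
            "categories",
        ],
    ).sort_values("chemical").reset_index(drop=True)
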