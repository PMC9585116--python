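"""Cross-platform and geographic comparisons.

Wristband concentrations (targeted GC screen, ng per g silicone per week)
are linked to serum suspect chemicals by shared molecular formula and
detection-frequency rank, since the two platforms share no structure-level
identifiers.  Tract-level pollution and pesticide-use percentiles are
compared with per-participant detected-chemical counts via Spearman rank
correlation.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError
from .types import CATEGORIES, ChemicalDatabase, categories_from_string


def normalize_wristband(raw_ng, silicone_g, days_worn):
    """ng per g silicone per week: ``raw / grams / (days/7)``.

    Scale-equivariant in the raw mass; denominators must be positive.
    """
    raw = np.asarray(raw_ng, dtype=float)
    g = np.asarray(silicone_g, dtype=float)
    d = np.asarray(days_worn, dtype=float)
    if (g <= 0).any() or (d <= 0).any():
        raise ValidationError("silicone mass and wear time must be positive")
    out = raw / g / (d / 7.0)
    return float(out) if out.ndim == 0 else out


def wristband_detection_frequency(wristband: pd.DataFrame) -> pd.DataFrame:
    """Per-chemical wristband detection frequency (fraction of wearers > 0).

    Zero is the reporting floor of the targeted screen, so any positive
    concentration counts as detected.
    """
    n = wristband["participant_id"].nunique()
    grp = wristband.groupby(["chemical", "formula"], sort=True)
    out = grp.agg(
        n_detected=("concentration", lambda s: int((s > 0).sum())),
        mean_concentration=("concentration", lambda s: float(s[s > 0].mean()) if (s > 0).any() else 0.0),
        categories=("categories", "first"),
        in_serum_db=("in_serum_db", "first"),
    ).reset_index()
    out["detection_frequency"] = out["n_detected"] / n
    return out


def match_wristband_to_serum(
    wristband_table: pd.DataFrame,
    serum_table: pd.DataFrame,
    serum_db: ChemicalDatabase,
) -> tuple:
    """Match wristband chemicals to serum suspects by formula and rank.

    Wristband chemicals whose formula is absent from the serum suspect
    database (GC-only analytes such as PCBs) are excluded and reported with
    a reason.  Within each shared formula, chemicals are sorted by
    descending detection frequency in each source and paired positionally
    (rank 1 with rank 1, ...); the unpaired remainder is reported unmatched.

    Returns ``(matches, excluded)`` DataFrames.
    """
    wb = wristband_table.copy()
    excluded = []
    eligible = []
    for r in wb.itertuples():
        if r.formula in serum_db:
            eligible.append(r)
        else:
            excluded.append(
                {"chemical": r.chemical, "formula": r.formula,
                 "reason": "formula not in serum database"}
            )
    serum_by_formula: dict = {}
    for r in serum_table.itertuples():
        serum_by_formula.setdefault(r.formula, []).append(
            (r.chemical, float(r.detection_frequency))
        )
    wb_by_formula: dict = {}
    for r in eligible:
        wb_by_formula.setdefault(r.formula, []).append(
            (r.chemical, float(r.detection_frequency))
        )
    matches = []
    for formula, wlist in sorted(wb_by_formula.items()):
        slist = serum_by_formula.get(formula, [])
        wlist = sorted(wlist, key=lambda t: (-t[1], t[0]))
        slist = sorted(slist, key=lambda t: (-t[1], t[0]))
        for rank, ((wc, wf), (sc, sf)) in enumerate(zip(wlist, slist), start=1):
            matches.append(
                {
                    "formula": formula,
                    "rank": rank,
                    "wristband_chemical": wc,
                    "wristband_df": wf,
                    "serum_chemical": sc,
                    "serum_df": sf,
                }
            )
        for wc, wf in wlist[len(slist):]:
            excluded.append(
                {"chemical": wc, "formula": formula,
                 "reason": "no serum suspect left at this rank"}
            )
    return (
        pd.DataFrame(matches, columns=["formula", "rank", "wristband_chemical",
                                       "wristband_df", "serum_chemical", "serum_df"]),
        pd.DataFrame(excluded, columns=["chemical", "formula", "reason"]),
    )


def spearman_rho(x, y) -> tuple:
    """Spearman rank correlation with midrank ties; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedStatisticError("Spearman correlation needs >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def count_chemicals_by_category(
    detected: pd.DataFrame,
    annotations: pd.DataFrame,
    category: str = "all",
) -> pd.Series:
    """Per-sample count of detected chemicals whose isomer carries a category.

    ``detected`` is chemicals x samples boolean; ``annotations`` maps each
    chemical to its assigned isomer's categories.  ``"all"`` counts every
    detected chemical.
    """
    valid = ("all",) + CATEGORIES
    if category not in valid:
        raise ValidationError(
            f"unknown category {category!r}; valid labels: {', '.join(valid)}"
        )
    ann = annotations.set_index("chemical")
    if category == "all":
        mask = pd.Series(True, index=detected.index)
    else:
        cats = ann["categories"].reindex(detected.index).fillna("")
        mask = cats.map(lambda s: category in categories_from_string(s))
    return detected.loc[mask.to_numpy(dtype=bool)].sum(axis=0).astype(int)


def correlate_geo(counts: pd.Series, percentiles: pd.Series) -> tuple:
    """Spearman correlation of per-participant chemical counts vs tract
    percentiles, over participants present in both series."""
    joined = pd.concat([counts, percentiles], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise UndefinedStatisticError("geographic correlation needs >= 3 participants")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise UndefinedStatisticError("percentiles are constant; correlation undefined")
    if np.all(x == x[0]):
        raise UndefinedStatisticError("counts are constant; correlation undefined")
    return spearman_rho(x, y)
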