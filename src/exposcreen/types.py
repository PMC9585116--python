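"""Core domain containers shared across pipeline stages.

The pipeline works on pandas DataFrames with fixed column schemas (documented
in :mod:`exposcreen.io`); the small dataclasses here carry structured results
and the chemical database, which needs fast mass lookup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Source categories a database isomer may carry (zero, one, or several).
CATEGORIES = (
    "pesticide",
    "cosmetic/fragrance",
    "pharmaceutical",
    "chemical-in-commerce",
    "personal-care",
    "PAH",
    "flame-retardant",
    "consumer-product",
)

CITIES = ("Fresno", "SanFrancisco")

#: Matching covariates used for the propensity model and batch-correction design.
COVARIATES = ("age_cat", "race_eth", "education", "marital")

STUDY_MATRICES = ("maternal", "cord")
BLANK_MATRICES = ("water_blank", "matrix_blank", "matrix_spike")


@dataclass(frozen=True)
class IsomerEntry:
    """One chemical structure sharing its formula with possible siblings."""

    name: str
    formula: str
    pubmed_count: int
    pubchem_count: int
    production_volume: float
    categories: frozenset = frozenset()


@dataclass(frozen=True)
class FormulaEntry:
    formula: str
    monoisotopic_mass: float
    isomers: tuple = ()


class ChemicalDatabase:
    """Suspect-screening database: unique formulas with candidate isomers.

    Provides O(log n) nearest-mass lookup for formula matching and
    per-isomer metadata for annotation scoring.
    """

    def __init__(self, formulas: Sequence[FormulaEntry]):
        self._formulas = {f.formula: f for f in formulas}
        if len(self._formulas) != len(formulas):
            raise ValidationError("duplicate formulas in database")
        names = [iso.name for f in formulas for iso in f.isomers]
        if len(set(names)) != len(names):
            raise ValidationError("isomer names are not unique within database")
        order = np.argsort([f.monoisotopic_mass for f in formulas])
        self._sorted = [formulas[i] for i in order]
        self._masses = np.array([f.monoisotopic_mass for f in self._sorted])
        self._isomer_index = {
            iso.name: iso for f in formulas for iso in f.isomers
        }

    def __len__(self) -> int:
        return len(self._formulas)

    def __contains__(self, formula: str) -> bool:
        return formula in self._formulas

    @property
    def formulas(self) -> Mapping[str, FormulaEntry]:
        return self._formulas

    @property
    def masses(self) -> np.ndarray:
        """Monoisotopic masses sorted ascending (parallel to sorted entries)."""
        return self._masses

    def entry_by_mass_rank(self, i: int) -> FormulaEntry:
        return self._sorted[i]

    def formula(self, formula: str) -> FormulaEntry:
        try:
            return self._formulas[formula]
        except KeyError:
            raise LookupError(f"formula {formula!r} not in database") from None

    def isomer(self, name: str) -> IsomerEntry:
        try:
            return self._isomer_index[name]
        except KeyError:
            raise LookupError(f"isomer {name!r} not in database") from None

    def nearest_formula(self, mass: float) -> tuple:
        """Return (FormulaEntry, ppm_error) of the formula nearest in mass."""
        i = int(np.searchsorted(self._masses, mass))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(self._masses):
                entry = self._sorted[j]
                ppm = (mass - entry.monoisotopic_mass) / entry.monoisotopic_mass * 1e6
                if best is None or abs(ppm) < abs(best[1]):
                    best = (entry, ppm)
        return best

    # -- (de)serialisation: one CSV row per isomer --------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self._sorted:
            for iso in f.isomers:
                rows.append(
                    {
                        "formula": f.formula,
                        "monoisotopic_mass": f.monoisotopic_mass,
                        "isomer": iso.name,
                        "pubmed_count": iso.pubmed_count,
                        "pubchem_count": iso.pubchem_count,
                        "production_volume": iso.production_volume,
                        "categories": ";".join(sorted(iso.categories)),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChemicalDatabase":
        entries = []
        for (formula, mass), grp in df.groupby(
            ["formula", "monoisotopic_mass"], sort=False
        ):
            isomers = tuple(
                IsomerEntry(
                    name=r.isomer,
                    formula=formula,
                    pubmed_count=int(r.pubmed_count),
                    pubchem_count=int(r.pubchem_count),
                    production_volume=float(r.production_volume),
                    categories=frozenset(
                        c for c in str(r.categories).split(";") if c and c != "nan"
                    ),
                )
                for r in grp.itertuples()
            )
            entries.append(FormulaEntry(formula, float(mass), isomers))
        return cls(entries)


@dataclass
class GroundTruth:
    """Generator-side truth used to validate recovery downstream.

    presence_prob maps chemical name -> city -> probability that the chemical
    is present (detectable) in a participant from that city.  batch_shift is
    an additive log-abundance offset per instrument batch.
    pesticide_coupling shifts the detection log-odds of pesticide-annotated
    chemicals by ``coupling * (pesticide_pctile - 50) / 50``.
    """

    presence_prob: dict
    differential_chemicals: set
    batch_shift: dict
    pesticide_coupling: float = 0.0
    pesticide_chemicals: set = field(default_factory=set)
    chemical_formula: dict = field(default_factory=dict)

    def __post_init__(self):
        for chem, by_city in self.presence_prob.items():
            for city, p in by_city.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"presence probability out of [0,1] for {chem}/{city}"
                    )

    def to_json(self) -> str:
        return json.dumps(
            {
                "presence_prob": self.presence_prob,
                "differential_chemicals": sorted(self.differential_chemicals),
                "batch_shift": {str(k): v for k, v in self.batch_shift.items()},
                "pesticide_coupling": self.pesticide_coupling,
                "pesticide_chemicals": sorted(self.pesticide_chemicals),
                "chemical_formula": self.chemical_formula,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            presence_prob=d["presence_prob"],
            differential_chemicals=set(d["differential_chemicals"]),
            batch_shift={int(k): v for k, v in d["batch_shift"].items()},
            pesticide_coupling=d["pesticide_coupling"],
            pesticide_chemicals=set(d["pesticide_chemicals"]),
            chemical_formula=d.get("chemical_formula", {}),
        )


@dataclass(frozen=True)
class DuplicateGroup:
    """Connected component of the pairwise mass/RT match relation."""

    members: frozenset
    retained_id: str

    def __post_init__(self):
        if self.retained_id not in self.members:
            raise ValidationError("retained feature must belong to the group")


@dataclass
class DetectionMatrix:
    """Boolean chemical x sample detection calls plus the abundances behind them."""

    detected: pd.DataFrame
    abundance: pd.DataFrame
    threshold: float

    @property
    def frequency(self) -> pd.Series:
        """Detection frequency per chemical across all samples in the matrix."""
        return self.detected.mean(axis=1)


@dataclass
class HarmonizedTable:
    """Chemicals x samples table after mode merging and cross-batch harmonisation.

    ``abundance`` is replicate-averaged, blank-filtered abundance (0 = not
    observed); ``meta`` has one row per harmonized chemical (formula,
    representative mass/RT); ``provenance`` maps chemical -> batch ->
    contributing feature ids.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    provenance: dict

    def __post_init__(self):
        if (self.abundance.values < 0).any():
            raise ValidationError("harmonized abundances must be non-negative")


@dataclass
class IsomerScore:
    name: str
    blind_probability: float
    evidence_score: float
    final_score: float
    rank: int


@dataclass
class PropensityModel:
    """Logistic model of Pr(city == Fresno | covariates)."""

    coef: pd.Series
    scores: pd.Series  # index: participant_id, values in (0, 1)
    covariates: tuple

    def __post_init__(self):
        s = self.scores
        if ((s <= 0) | (s >= 1)).any():
            raise ValidationError("propensity scores must lie strictly in (0,1)")


@dataclass
class MatchedCohort:
    """1:1 matched pairs (Fresno participant, San Francisco participant)."""

    pairs: list
    matrix: str = "maternal"

    def __post_init__(self):
        flat = [p for pair in self.pairs for p in pair]
        if len(set(flat)) != len(flat):
            raise ValidationError("matching must be without replacement")

    @property
    def fresno_ids(self) -> list:
        return [a for a, _ in self.pairs]

    @property
    def sf_ids(self) -> list:
        return [b for _, b in self.pairs]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["fresno_id", "sf_id"])


def categories_from_string(s: str) -> frozenset:
    return frozenset(c for c in str(s).split(";") if c and c != "nan")
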