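"""Synthetic-data generators emulating a two-city LC-QTOF biomonitoring study.

Everything the downstream pipeline consumes is produced here with known
ground truth: a suspect database of formulas and isomers, a two-city cohort
with demographic confounding, per-batch/per-mode feature tables with
technical replicates, water/matrix blanks, injected duplicate features and
batch effects, and silicone-wristband concentration profiles.

The generators are deterministic given their seed (``numpy`` Generator
streams spawned from a single ``SeedSequence``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .types import (
    CATEGORIES,
    CITIES,
    COVARIATES,
    ChemicalDatabase,
    FormulaEntry,
    GroundTruth,
    IsomerEntry,
)

# ---------------------------------------------------------------------------
# Chemical database
# ---------------------------------------------------------------------------

_CATEGORY_WEIGHTS = {
    "pesticide": 0.16,
    "cosmetic/fragrance": 0.18,
    "pharmaceutical": 0.14,
    "chemical-in-commerce": 0.30,
    "personal-care": 0.18,
    "PAH": 0.06,
    "flame-retardant": 0.06,
    "consumer-product": 0.18,
}


def _random_formula(rng: np.random.Generator, used: set) -> str:
    """Draw a unique Hill-notation-like formula string."""
    for _ in range(1000):
        c = int(rng.integers(6, 40))
        h = int(rng.integers(4, 2 * c + 3))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(0, 9))
        s = int(rng.integers(0, 3))
        parts = [f"C{c}", f"H{h}"]
        if n:
            parts.append(f"N{n}")
        if o:
            parts.append(f"O{o}")
        if s:
            parts.append(f"S{s}")
        formula = "".join(parts)
        if formula not in used:
            used.add(formula)
            return formula
    raise ConfigError("could not draw a unique formula; database too large")


def generate_chemical_db(
    n_formulas: int, max_isomers: int, seed: int
) -> ChemicalDatabase:
    """Generate a suspect database of unique formulas with isomer candidates.

    Monoisotopic masses are uniform on the instrument scan range
    [100, 1000] Da.  Literature mention counts and production volumes are
    drawn from heavy-tailed log-normal distributions so that evidence scores
    discriminate between isomers.
    """
    if n_formulas < 1 or max_isomers < 1:
        raise ValueError("n_formulas and max_isomers must be >= 1")
    rng = np.random.default_rng(seed)
    used: set = set()
    entries = []
    masses = rng.uniform(100.0, 1000.0, size=n_formulas)
    for i in range(n_formulas):
        formula = _random_formula(rng, used)
        k = 1 + int(rng.binomial(max_isomers - 1, 0.35)) if max_isomers > 1 else 1
        isomers = []
        for j in range(k):
            cats = [
                c
                for c in CATEGORIES
                if rng.random() < _CATEGORY_WEIGHTS[c] * 0.9
            ]
            isomers.append(
                IsomerEntry(
                    name=f"{formula}-{j + 1}",
                    formula=formula,
                    pubmed_count=int(rng.lognormal(2.0, 2.0)),
                    pubchem_count=int(rng.lognormal(2.5, 2.0)),
                    production_volume=float(rng.lognormal(5.0, 3.0)),
                    categories=frozenset(cats),
                )
            )
        entries.append(FormulaEntry(formula, float(masses[i]), tuple(isomers)))
    return ChemicalDatabase(entries)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CovariateConfig:
    """Per-city categorical covariate distributions and tract percentile shapes.

    ``city_probs[covariate][city]`` is the probability vector over that
    covariate's levels.  Percentile shapes are Beta(a, b) parameters scaled
    to [0, 100].
    """

    levels: dict
    city_probs: dict
    pesticide_beta: dict
    pollution_beta: dict

    @classmethod
    def default(cls) -> "CovariateConfig":
        # Fresno skews younger, more Latina, lower educational attainment,
        # less often married; Fresno tracts carry far higher agricultural
        # pesticide-use percentiles.
        levels = {
            "age_cat": ("<30", "30-34", ">=35"),
            "race_eth": ("Latina", "White", "Black", "Asian/PI", "Other"),
            "education": ("<HS", "HS", "some-college", "bachelor+"),
            "marital": ("married", "not-married"),
        }
        city_probs = {
            "age_cat": {
                "Fresno": (0.66, 0.30, 0.04),
                "SanFrancisco": (0.35, 0.40, 0.25),
            },
            "race_eth": {
                "Fresno": (0.55, 0.20, 0.10, 0.08, 0.07),
                "SanFrancisco": (0.25, 0.35, 0.08, 0.22, 0.10),
            },
            "education": {
                "Fresno": (0.20, 0.35, 0.30, 0.15),
                "SanFrancisco": (0.05, 0.12, 0.23, 0.60),
            },
            "marital": {
                "Fresno": (0.45, 0.55),
                "SanFrancisco": (0.75, 0.25),
            },
        }
        return cls(
            levels=levels,
            city_probs=city_probs,
            pesticide_beta={"Fresno": (4.0, 1.6), "SanFrancisco": (1.2, 8.0)},
            pollution_beta={"Fresno": (5.0, 2.0), "SanFrancisco": (3.0, 3.0)},
        )

    @classmethod
    def null(cls) -> "CovariateConfig":
        """Identical distributions in both cities (covariates exchangeable)."""
        cfg = cls.default()
        probs = {
            cov: {city: cfg.city_probs[cov]["Fresno"] for city in CITIES}
            for cov in cfg.levels
        }
        return cls(
            levels=cfg.levels,
            city_probs=probs,
            pesticide_beta={c: (2.0, 2.0) for c in CITIES},
            pollution_beta={c: (2.0, 2.0) for c in CITIES},
        )

    def validate(self) -> None:
        for cov, lv in self.levels.items():
            if len(lv) == 0:
                raise ConfigError(f"covariate {cov!r} has no levels")
            for city in CITIES:
                p = self.city_probs[cov][city]
                if len(p) != len(lv):
                    raise ConfigError(
                        f"probability vector length mismatch for {cov}/{city}"
                    )
                if abs(sum(p) - 1.0) > 1e-8:
                    raise ConfigError(f"probabilities for {cov}/{city} must sum to 1")


def generate_cohort(
    n_per_city: int,
    covariate_config: Optional[CovariateConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the two-city cohort with confounded covariates.

    Returns a DataFrame with one row per participant: id, city, the four
    matching covariates, and CalEnviroScreen-style tract percentiles.
    """
    if n_per_city < 1:
        raise ValueError("n_per_city must be >= 1")
    cfg = covariate_config or CovariateConfig.default()
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for city, prefix in (("Fresno", "F"), ("SanFrancisco", "S")):
        for i in range(n_per_city):
            row = {"participant_id": f"{prefix}-{i:04d}", "city": city}
            for cov, lv in cfg.levels.items():
                row[cov] = rng.choice(lv, p=cfg.city_probs[cov][city])
            a, b = cfg.pesticide_beta[city]
            row["pesticide_pctile"] = 100.0 * rng.beta(a, b)
            a, b = cfg.pollution_beta[city]
            row["pollution_burden_pctile"] = 100.0 * rng.beta(a, b)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground truth and participant-level presence
# ---------------------------------------------------------------------------


@dataclass
class EffectsConfig:
    """Effect structure injected into the synthetic study.

    Differential chemicals are detectable with probability ``df_high`` in
    Fresno and ``df_low`` in San Francisco (a fraction reversed); null
    chemicals share one probability drawn uniformly from ``null_df_range``.
    """

    n_chemicals: int = 120
    #: probability that the truly present chemical is its formula's
    #: highest-evidence isomer (well-documented, high-production chemicals
    #: are the ones people are actually exposed to)
    top_isomer_prob: float = 0.8
    differential_fraction: float = 0.2
    df_high: float = 0.9
    df_low: float = 0.3
    reverse_fraction: float = 0.1
    null_df_range: tuple = (0.2, 0.8)
    batch_shift: dict = field(default_factory=lambda: {1: 0.0, 2: 0.5, 3: -0.5})
    pesticide_coupling: float = 1.5


def make_ground_truth(
    db: ChemicalDatabase,
    effects: Optional[EffectsConfig] = None,
    seed: int = 0,
) -> GroundTruth:
    """Select the assayable chemical panel and its per-city effect structure.

    One isomer per formula is sampled (so injected chemicals map 1:1 to
    formula groups), a fraction is made differentially detectable, and
    pesticide-annotated chemicals carry the tract-percentile coupling.
    """
    from .annotate import evidence_table

    eff = effects or EffectsConfig()
    rng = np.random.default_rng(seed)
    n = min(eff.n_chemicals, len(db))
    formula_idx = rng.choice(len(db), size=n, replace=False)
    evidence = evidence_table(db)["evidence_score"]
    chems = []
    for i in formula_idx:
        entry = db.entry_by_mass_rank(int(i))
        if rng.random() < eff.top_isomer_prob:
            iso = max(entry.isomers, key=lambda x: (evidence[x.name], x.name))
        else:
            iso = entry.isomers[int(rng.integers(len(entry.isomers)))]
        chems.append(iso)
    n_diff = int(round(eff.differential_fraction * n))
    diff_names = {c.name for c in chems[:n_diff]}
    presence = {}
    for c in chems:
        if c.name in diff_names:
            hi, lo = eff.df_high, eff.df_low
            if rng.random() < eff.reverse_fraction:
                hi, lo = lo, hi
            presence[c.name] = {"Fresno": hi, "SanFrancisco": lo}
        else:
            p = float(rng.uniform(*eff.null_df_range))
            presence[c.name] = {"Fresno": p, "SanFrancisco": p}
    pesticides = {c.name for c in chems if "pesticide" in c.categories}
    return GroundTruth(
        presence_prob=presence,
        differential_chemicals=diff_names,
        batch_shift=dict(eff.batch_shift),
        pesticide_coupling=eff.pesticide_coupling,
        pesticide_chemicals=pesticides,
        chemical_formula={c.name: c.formula for c in chems},
    )


def simulate_detection_matrix(
    truth: GroundTruth, cohort: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Draw participant-level presence (chemicals x participants, boolean).

    Presence is Bernoulli with the chemical's city probability; for
    pesticide-annotated chemicals the log-odds are shifted by
    ``coupling * (pesticide_pctile - 50) / 50``.
    """
    rng = np.random.default_rng(seed)
    chems = sorted(truth.presence_prob)
    pids = cohort["participant_id"].to_numpy()
    city = cohort["city"].to_numpy()
    pest = cohort["pesticide_pctile"].to_numpy()
    out = np.zeros((len(chems), len(pids)), dtype=bool)
    for i, chem in enumerate(chems):
        p = np.array([truth.presence_prob[chem][c] for c in city])
        if chem in truth.pesticide_chemicals and truth.pesticide_coupling != 0.0:
            p = np.clip(p, 1e-9, 1 - 1e-9)
            logit = np.log(p / (1 - p))
            logit = logit + truth.pesticide_coupling * (pest - 50.0) / 50.0
            p = 1.0 / (1.0 + np.exp(-logit))
        out[i] = rng.random(len(pids)) < p
    return pd.DataFrame(out, index=chems, columns=pids)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureGenConfig:
    """Noise and nuisance structure of the simulated feature extraction.

    Mass error is Gaussian (SD ``mass_ppm_sd`` ppm) truncated at
    ``mass_ppm_max`` ppm, matching sub-5-ppm instrument accuracy.  RT jitter
    is small within batch and larger between batches so cross-batch matching
    is exercised but mostly succeeds inside the 0.5-min window.
    """

    mass_ppm_sd: float = 0.8
    mass_ppm_max: float = 5.0
    rt_within_sd: float = 0.1
    rt_between_sd: float = 0.2
    dual_mode_fraction: float = 0.2
    duplicate_fraction: float = 0.1
    blank_fail_fraction: float = 0.1
    singleton_fraction: float = 0.02
    replicate_log_sd: float = 0.05
    log_abundance_mean_range: tuple = (math.log(12000.0), math.log(80000.0))
    log_abundance_sd: float = 0.5
    secondary_mode_scale: float = 0.7
    duplicate_scale: float = 0.5
    duplicate_presence: float = 0.7
    cord_fraction: float = 0.85
    mother_cord_corr: float = 0.7
    n_spike_chemicals: int = 5


DEFAULT_BATCH_PLAN = {"SanFrancisco": (1, 2), "Fresno": (3,)}


def _truncnorm_ppm(rng, sd, bound):
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return x


def generate_feature_tables(
    db: ChemicalDatabase,
    cohort: pd.DataFrame,
    batch_plan: Optional[Mapping[str, Sequence[int]]] = None,
    truth: Optional[GroundTruth] = None,
    seed: int = 0,
    config: Optional[FeatureGenConfig] = None,
) -> tuple:
    """Simulate per-batch, per-mode extracted feature tables with replicates.

    Returns ``(features, samples)``:

    * ``features`` — long format, one row per (feature, sample, replicate):
      feature_id, neutral_mass, rt, mode, batch, sample_id, replicate,
      abundance, true_chemical.
    * ``samples`` — sample_id, participant_id (null for blanks), matrix,
      batch; every batch contains one water blank, one matrix blank and one
      matrix spike.
    """
    cfg = config or FeatureGenConfig()
    plan = {c: tuple(b) for c, b in (batch_plan or DEFAULT_BATCH_PLAN).items()}
    for city in cohort["city"].unique():
        if city not in plan or len(plan[city]) == 0:
            raise ConfigError(f"batch plan missing city {city!r}")
    ss = np.random.SeedSequence(seed)
    s_truth, s_assign, s_presence, s_feat = ss.spawn(4)
    if truth is None:
        truth = make_ground_truth(db, seed=s_truth.generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(s_assign)

    # --- samples -----------------------------------------------------------
    sample_rows = []
    participant_batch = {}
    for city, grp in cohort.groupby("city", sort=True):
        batches = plan[city]
        pids = grp["participant_id"].tolist()
        order = rng.permutation(len(pids))
        for rank, idx in enumerate(order):
            participant_batch[pids[idx]] = batches[rank % len(batches)]
    has_cord = {
        pid: bool(rng.random() < cfg.cord_fraction) for pid in participant_batch
    }
    for pid in cohort["participant_id"]:
        b = participant_batch[pid]
        sample_rows.append((f"{pid}-M", pid, "maternal", b))
        if has_cord[pid]:
            sample_rows.append((f"{pid}-C", pid, "cord", b))
    all_batches = sorted({b for bs in plan.values() for b in bs})
    for b in all_batches:
        sample_rows.append((f"B{b}-WB", None, "water_blank", b))
        sample_rows.append((f"B{b}-MB", None, "matrix_blank", b))
        sample_rows.append((f"B{b}-SP", None, "matrix_spike", b))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "participant_id", "matrix", "batch"]
    )

    # --- participant-level presence ---------------------------------------
    presence = simulate_detection_matrix(
        truth, cohort, seed=s_presence.generate_state(1)[0] % 2**31
    )
    chems = list(presence.index)
    pid_col = cohort.set_index("participant_id")
    frng = np.random.default_rng(s_feat)

    spike_chems = set(chems[: cfg.n_spike_chemicals])
    blank_fail = {c for c in chems if frng.random() < cfg.blank_fail_fraction}

    study = samples[samples["matrix"].isin(("maternal", "cord"))]
    by_batch_study = {
        b: grp for b, grp in study.groupby("batch")
    }

    feat_meta = []  # feature_id, mass, rt, mode, batch, true_chemical
    rows_fid, rows_sid, rows_rep, rows_ab = [], [], [], []
    counter = 0

    def emit_feature(chem, formula_mass, rt_cb, mode, batch, scale, present_mask,
                     log_mu, z_part, mass_ppm=None, rt_exact=None):
        nonlocal counter
        fid = f"FT{counter:06d}"
        counter += 1
        ppm = mass_ppm if mass_ppm is not None else _truncnorm_ppm(
            frng, cfg.mass_ppm_sd, cfg.mass_ppm_max
        )
        mass = formula_mass * (1.0 + ppm * 1e-6)
        if rt_exact is not None:
            rt = max(0.0, rt_exact)
        else:
            rt = max(0.0, rt_cb + frng.normal(0.0, cfg.rt_within_sd))
        feat_meta.append((fid, mass, rt, mode, batch, chem))
        grp = by_batch_study.get(batch)
        sample_ids, abunds = [], []
        if grp is not None:
            for srow in grp.itertuples():
                pid = srow.participant_id
                if present_mask.get(pid, False):
                    z = z_part[pid]
                    r = cfg.mother_cord_corr
                    e = frng.normal()
                    la = (
                        log_mu
                        + truth.batch_shift.get(batch, 0.0)
                        + cfg.log_abundance_sd
                        * (math.sqrt(max(r, 0.0)) * z + math.sqrt(max(1 - r, 0.0)) * e)
                        + math.log(scale)
                    )
                    a = math.exp(la)
                else:
                    a = 0.0
                sample_ids.append(srow.sample_id)
                abunds.append(a)
        # blanks
        wb = f"B{batch}-WB"
        mb = f"B{batch}-MB"
        sp = f"B{batch}-SP"
        typical = math.exp(log_mu + truth.batch_shift.get(batch, 0.0)) * scale
        blank_ab = 0.8 * typical if chem in blank_fail else 0.0
        sample_ids += [wb, mb, sp]
        abunds += [
            blank_ab,
            0.0,
            3.0 * typical if chem in spike_chems else 0.0,
        ]
        for sid, a in zip(sample_ids, abunds):
            for rep in (1, 2):
                if a > 0:
                    ab = a * math.exp(frng.normal(0.0, cfg.replicate_log_sd))
                else:
                    ab = 0.0
                rows_fid.append(fid)
                rows_sid.append(sid)
                rows_rep.append(rep)
                rows_ab.append(ab)
        return fid, rt

    for chem in chems:
        formula = truth.chemical_formula[chem]
        fmass = db.formula(formula).monoisotopic_mass
        log_mu = frng.uniform(*cfg.log_abundance_mean_range)
        rt_c = frng.uniform(0.5, 18.5)
        primary = "positive" if frng.random() < 0.5 else "negative"
        dual = frng.random() < cfg.dual_mode_fraction
        z_part = {pid: frng.normal() for pid in cohort["participant_id"]}
        pres = presence.loc[chem]
        for batch in all_batches:
            grp = by_batch_study.get(batch)
            if grp is None:
                continue
            batch_pids = sorted(set(grp["participant_id"]))
            mask = {pid: bool(pres[pid]) for pid in batch_pids}
            if not any(mask.values()):
                continue
            rt_cb = rt_c + frng.normal(0.0, cfg.rt_between_sd)
            modes = [primary] + (
                ["negative" if primary == "positive" else "positive"] if dual else []
            )
            for k, mode in enumerate(modes):
                scale = 1.0 if k == 0 else cfg.secondary_mode_scale
                _, parent_rt = emit_feature(
                    chem, fmass, rt_cb, mode, batch, scale, mask, log_mu, z_part
                )
                if frng.random() < cfg.duplicate_fraction:
                    # split duplicate: nearby mass/RT, thinner presence
                    sub = {
                        pid: ok and frng.random() < cfg.duplicate_presence
                        for pid, ok in mask.items()
                    }
                    emit_feature(
                        chem,
                        fmass,
                        rt_cb,
                        mode,
                        batch,
                        scale * cfg.duplicate_scale,
                        sub,
                        log_mu,
                        z_part,
                        mass_ppm=_truncnorm_ppm(
                            frng, cfg.mass_ppm_sd, cfg.mass_ppm_max
                        ),
                        rt_exact=parent_rt + float(frng.uniform(-0.35, 0.35)),
                    )

    features = pd.DataFrame(
        {
            "feature_id": rows_fid,
            "sample_id": rows_sid,
            "replicate": rows_rep,
            "abundance": rows_ab,
        }
    )
    meta = pd.DataFrame(
        feat_meta,
        columns=["feature_id", "neutral_mass", "rt", "mode", "batch", "true_chemical"],
    )
    features = features.merge(meta, on="feature_id")
    # singleton extractions: knock out replicate 2 of a small fraction of cells
    if cfg.singleton_fraction > 0:
        pos = (features["abundance"] > 0) & (features["replicate"] == 2)
        idx = features.index[pos]
        knock = frng.random(len(idx)) < cfg.singleton_fraction
        features.loc[idx[knock], "abundance"] = 0.0
    features = features[
        [
            "feature_id",
            "neutral_mass",
            "rt",
            "mode",
            "batch",
            "sample_id",
            "replicate",
            "abundance",
            "true_chemical",
        ]
    ].reset_index(drop=True)
    return features, samples


# ---------------------------------------------------------------------------
# Wristbands
# ---------------------------------------------------------------------------


@dataclass
class WristbandConfig:
    n_screen: int = 120
    overlap_fraction: float = 0.7
    #: fraction of screen chemicals present in the cohort's environment at
    #: all; the remainder is never detected (a targeted screen is sparse)
    present_fraction: float = 0.55
    detect_prob_range: tuple = (0.05, 0.9)
    wear_days_mean: float = 35.0
    wear_days_sd: float = 5.0
    silicone_g_mean: float = 4.5
    silicone_g_sd: float = 0.3
    log_ng_mean: float = 5.0
    log_ng_sd: float = 1.5


def generate_wristband_data(
    db: ChemicalDatabase,
    participants: Sequence[str],
    seed: int = 0,
    config: Optional[WristbandConfig] = None,
) -> pd.DataFrame:
    """Simulate the targeted silicone-wristband screen for a participant subset.

    A configurable fraction of screen chemicals shares formulas with the
    serum suspect database; the remainder emulates GC-only analytes (PCB/PBDE
    style) absent from the LC screen.  Concentrations are normalised to
    ng per g silicone per week worn.
    """
    participants = list(participants)
    if not participants:
        raise ValueError("participant subset must be non-empty")
    cfg = config or WristbandConfig()
    rng = np.random.default_rng(seed)
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_screen))
    n_overlap = min(n_overlap, len(db))
    idx = rng.choice(len(db), size=n_overlap, replace=False)
    screen = []
    for i in idx:
        entry = db.entry_by_mass_rank(int(i))
        iso = entry.isomers[int(rng.integers(len(entry.isomers)))]
        screen.append((iso.name, iso.formula, ";".join(sorted(iso.categories)), True))
    db_formulas = set(db.formulas)
    for j in range(cfg.n_screen - n_overlap):
        cl = int(rng.integers(1, 10))
        formula = f"C12H{10 - min(cl, 9)}Cl{cl}x{j}"  # synthetic, guaranteed non-LC
        assert formula not in db_formulas
        screen.append((f"PCB-like-{j:03d}", formula, "chemical-in-commerce", False))
    wear = np.clip(
        rng.normal(cfg.wear_days_mean, cfg.wear_days_sd, len(participants)), 7.0, None
    )
    sil = np.clip(
        rng.normal(cfg.silicone_g_mean, cfg.silicone_g_sd, len(participants)),
        1.0,
        None,
    )
    rows = []
    for name, formula, cats, in_db in screen:
        if rng.random() < cfg.present_fraction:
            p = rng.uniform(*cfg.detect_prob_range)
        else:
            p = 0.0
        for k, pid in enumerate(participants):
            detected = rng.random() < p
            raw = float(rng.lognormal(cfg.log_ng_mean, cfg.log_ng_sd)) if detected else 0.0
            conc = raw / sil[k] / (wear[k] / 7.0)
            rows.append(
                {
                    "participant_id": pid,
                    "chemical": name,
                    "formula": formula,
                    "categories": cats,
                    "raw_ng": raw,
                    "silicone_g": sil[k],
                    "days_worn": wear[k],
                    "concentration": conc,
                    "in_serum_db": in_db,
                }
            )
    return pd.DataFrame(rows)
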