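import numpy as np
import pandas as pd
import pytest

from exposcreen.synth import (
    CovariateConfig,
    EffectsConfig,
    FeatureGenConfig,
    generate_chemical_db,
    generate_cohort,
    generate_feature_tables,
    make_ground_truth,
)
from exposcreen.types import ChemicalDatabase, FormulaEntry, IsomerEntry


def _iso(name, formula, pm=0, pc=0, pv=0.0, cats=()):
    return IsomerEntry(
        name=name,
        formula=formula,
        pubmed_count=pm,
        pubchem_count=pc,
        production_volume=pv,
        categories=frozenset(cats),
    )


@pytest.fixture(scope="session")
def tiny_db():
    """Hand-built database with known masses and evidence metrics."""
    return ChemicalDatabase(
        [
            FormulaEntry(
                "C10H10O2",
                300.0,
                (
                    _iso("alpha", "C10H10O2", 100, 1000, 500.0, ("pesticide",)),
                    _iso("beta", "C10H10O2", 10, 100, 50.0, ("cosmetic/fragrance",)),
                    _iso("gamma", "C10H10O2", 0, 0, 0.0),
                    _iso("delta", "C10H10O2", 50, 500, 250.0, ("pesticide", "PAH")),
                ),
            ),
            FormulaEntry(
                "C12H10O3",
                400.0,
                (_iso("solo", "C12H10O3", 40, 40, 40.0, ("pharmaceutical",)),),
            ),
            FormulaEntry(
                "C5H5N5",
                500.0,
                (
                    _iso("tie-a", "C5H5N5", 20, 20, 20.0),
                    _iso("tie-b", "C5H5N5", 20, 20, 20.0),
                ),
            ),
        ]
    )


@pytest.fixture(scope="session")
def gen_db():
    return generate_chemical_db(100, 4, seed=7)


@pytest.fixture(scope="session")
def cohort150():
    return generate_cohort(75, seed=3)


@pytest.fixture(scope="session")
def small_study():
    """Modest end-to-end synthetic study shared by integration tests."""
    db = generate_chemical_db(80, 4, seed=11)
    cohort = generate_cohort(20, seed=11)
    effects = EffectsConfig(n_chemicals=30, batch_shift={1: 0.0, 2: 0.6, 3: -0.6})
    truth = make_ground_truth(db, effects, seed=11)
    features, samples = generate_feature_tables(
        db, cohort, truth=truth, seed=11, config=FeatureGenConfig()
    )
    return {
        "db": db,
        "cohort": cohort,
        "truth": truth,
        "features": features,
        "samples": samples,
    }


def make_feature_rows(specs, batch=1, mode="positive", samples=("S1", "S2")):
    """Long-format feature rows from (feature_id, mass, rt, {sample: abundance})."""
    rows = []
    for fid, mass, rt, ab in specs:
        for sid in samples:
            for rep in (1, 2):
                rows.append(
                    {
                        "feature_id": fid,
                        "neutral_mass": mass,
                        "rt": rt,
                        "mode": mode,
                        "batch": batch,
                        "sample_id": sid,
                        "replicate": rep,
                        "abundance": float(ab.get(sid, 0.0)),
                    }
                )
    return pd.DataFrame(rows)
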