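"""CSV/JSON readers and writers for the pipeline's on-disk interfaces.

All CSVs are RFC-4180 UTF-8 with a header row; floats are written with a
fixed ``%.10g`` format so reruns with identical inputs are byte-identical.
Schemas (long formats):

* ``features.csv`` — feature_id, neutral_mass, rt, mode, batch, sample_id,
  replicate, abundance, true_chemical (ground-truth column, absent for real
  data)
* ``samples.csv`` — sample_id, participant_id, matrix, batch
* ``cohort.csv`` — participant_id, city, age_cat, race_eth, education,
  marital, pesticide_pctile, pollution_burden_pctile
* ``chemdb.csv`` — one row per isomer (see ChemicalDatabase.to_frame)
* ``wristband.csv`` — participant_id, chemical, formula, categories, raw_ng,
  silicone_g, days_worn, concentration, in_serum_db
* ``harmonized.csv`` — chemical, sample_id, abundance
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import ChemicalDatabase, GroundTruth

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, **kw)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_chemdb(db: ChemicalDatabase, path) -> None:
    write_csv(db.to_frame(), path)


def read_chemdb(path) -> ChemicalDatabase:
    return ChemicalDatabase.from_frame(pd.read_csv(path, keep_default_na=False))


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def harmonized_to_long(abundance: pd.DataFrame) -> pd.DataFrame:
    long = abundance.reset_index().melt(
        id_vars="chemical", var_name="sample_id", value_name="abundance"
    )
    return long.sort_values(["chemical", "sample_id"]).reset_index(drop=True)


def harmonized_from_long(long: pd.DataFrame) -> pd.DataFrame:
    wide = long.pivot(index="chemical", columns="sample_id", values="abundance")
    wide.columns.name = None
    return wide
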