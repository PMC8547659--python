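"""CSV schemas and round-trip readers/writers for all pipeline tables.

All tables travel as UTF-8 CSV with a header row and '.' decimal
separator. Column names are part of the contract; floats are written with
17 significant digits so write->read round-trips are lossless.
"""

from __future__ import annotations

import pathlib
from typing import Dict, Mapping, Optional

import pandas as pd

from .reformulation import TargetSet

SCHEMAS: Dict[str, list] = {
    "strata": [
        "stratum_id", "sex", "age_lo", "age_hi", "age_mid",
        "mean_sbp", "htn_prev", "htn_prev_se", "population",
    ],
    "products": [
        "product_id", "company_id", "company_type", "category_id", "sodium_mg_per_100g",
    ],
    "sales": ["product_id", "kg_per_year"],
    "recalls": ["person_id", "stratum_id", "survey_weight", "food_id", "grams_per_day"],
    "composition": ["food_id", "category_id", "sodium_mg_per_100g"],
    "burden": ["metric", "cause_id", "stratum_id", "events", "ui_low", "ui_high"],
}

_FLOAT_FORMAT = "%.17g"


def write_table(df: pd.DataFrame, path, name: Optional[str] = None) -> None:
    """Write one table, checking its schema if ``name`` is a known table."""
    if name is not None:
        expected = SCHEMAS[name]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} missing columns: {missing}")
        df = df[expected]
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_table(path, name: Optional[str] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if name is not None:
        expected = SCHEMAS[name]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} missing columns: {missing}")
        df = df[expected]
    return df


def write_tables(tables: Mapping[str, pd.DataFrame], outdir) -> None:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_table(df, out / f"{name}.csv", name if name in SCHEMAS else None)


def read_tables(indir, names=None) -> Dict[str, pd.DataFrame]:
    indir = pathlib.Path(indir)
    names = names if names is not None else list(SCHEMAS)
    return {name: read_table(indir / f"{name}.csv", name if name in SCHEMAS else None)
            for name in names}


def write_target_set(targets: TargetSet, path) -> None:
    pd.DataFrame(
        {
            "category_id": list(targets.targets),
            "max_sodium_mg_per_100g": list(targets.targets.values()),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_target_set(path, name: str) -> TargetSet:
    df = pd.read_csv(path)
    return TargetSet(
        name=name,
        targets=dict(zip(df["category_id"], df["max_sodium_mg_per_100g"])),
    )
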