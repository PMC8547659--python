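"""Loaders for the reference data shipped with the package.

Three inputs of the risk model are data, not code: the cause list with its
mortality/morbidity inclusion flags, the age-specific relative-risk tables
(per 10 mm Hg SBP for blood-pressure-mediated causes; per 1 g/d sodium for
stomach cancer), and the sodium->SBP meta-regression coefficients. They are
versioned under ``sodium_cra/data/`` and can be replaced by user-supplied
files with the same schemas.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd
import yaml

from .cra import SBPEffectModel

_DATA = files("sodium_cra") / "data"


def load_causes(path=None) -> pd.DataFrame:
    """Cause registry: id, label, group, pathway, inclusion flags.

    ``include_in_mortality`` / ``include_in_morbidity`` implement the rule
    that inflammatory heart diseases (endocarditis, rheumatic heart disease)
    count toward averted deaths but not toward averted incidence or DALYs,
    because they arise independently of blood pressure while their fatality
    is still blood-pressure sensitive.
    """
    src = path if path is not None else (_DATA / "causes.csv")
    df = pd.read_csv(src)
    for col in ("include_in_mortality", "include_in_morbidity"):
        df[col] = df[col].astype(bool)
    return df


def load_rr_table(path=None) -> pd.DataFrame:
    """Relative-risk table by cause and age band.

    Columns ``rr, ci_low, ci_high`` are on the RR scale; ``ln_rr`` and its
    standard error (from the 95% CI width) are derived here. For
    blood-pressure-mediated causes the RR is per 10 mm Hg SBP; for stomach
    cancer it is per 1 g/d sodium.
    """
    src = path if path is not None else (_DATA / "rr_tables.csv")
    df = pd.read_csv(src)
    if (df["ci_low"] > df["rr"]).any() or (df["rr"] > df["ci_high"]).any():
        raise ValueError("RR central values must lie within their CIs")
    df["ln_rr"] = np.log(df["rr"])
    df["ln_rr_se"] = (np.log(df["ci_high"]) - np.log(df["ci_low"])) / (2 * 1.959964)
    return df


def load_sbp_model(path=None) -> SBPEffectModel:
    """Sodium->SBP meta-regression coefficients as an :class:`SBPEffectModel`."""
    src = path if path is not None else (_DATA / "sbp_effect.yaml")
    if hasattr(src, "read_text"):
        raw = yaml.safe_load(src.read_text())
    else:
        with open(src) as fh:
            raw = yaml.safe_load(fh)
    return SBPEffectModel(
        main=float(raw["main_effect_mmhg_per_100mmol"]),
        age_interaction=float(raw["age_interaction_mmhg_per_year"]),
        hypertension_interaction=float(raw["hypertension_interaction_mmhg"]),
        reference_age=float(raw["reference_age_years"]),
        main_se=float(raw.get("main_effect_se", 0.0)),
        age_interaction_se=float(raw.get("age_interaction_se", 0.0)),
        hypertension_interaction_se=float(raw.get("hypertension_interaction_se", 0.0)),
    )
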