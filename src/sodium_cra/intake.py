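"""Pre-reformulation sodium intake estimation from 24-hour recall data.

The exposure model needs, for each of the 24 age-sex strata, the mean
sodium intake (mg/d) contributed by every targeted food category plus an
untargeted remainder (scratch cooking, restaurant and takeaway food, and
any category without a reformulation target). Recall records give grams
eaten per day per food; a composition lookup gives each food's sodium
density and category. Survey weights are applied as sampling weights
throughout.

Because single 24-hour recalls systematically underestimate sodium, all
category means are rescaled so that each sex's total matches a chosen
share (85% in the primary model) of the urinary-excretion-based intake
estimate for that sex; the scaling is uniform across categories, so every
category keeps its share of the total within a sex.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

#: Category id carrying all foods outside any reformulation target's scope.
UNTARGETED = "remainder"


def person_category_sodium(recalls: pd.DataFrame, composition: pd.DataFrame):
    """Person-level sodium (mg/d) by food category.

    Returns ``(persons, matrix)``: a per-person frame (stratum, survey
    weight) indexed by person_id, and a person x category matrix of sodium
    intakes with zeros for categories a person did not eat. Unmappable
    food ids are a hard error listing the offenders.
    """
    comp = composition[["food_id", "category_id", "sodium_mg_per_100g"]]
    df = recalls.merge(comp, on="food_id", how="left", validate="m:1")
    if df["category_id"].isna().any():
        offenders = sorted(df.loc[df["category_id"].isna(), "food_id"].unique())
        raise KeyError(f"recall foods missing from composition table: {offenders}")
    df["sodium_mg"] = df["grams_per_day"] * df["sodium_mg_per_100g"] / 100.0
    persons = (
        recalls[["person_id", "stratum_id", "survey_weight"]]
        .drop_duplicates("person_id")
        .set_index("person_id")
    )
    matrix = (
        df.pivot_table(
            index="person_id", columns="category_id", values="sodium_mg", aggfunc="sum"
        )
        .reindex(persons.index)
        .fillna(0.0)
    )
    return persons, matrix


def _weighted_mean_se(y: np.ndarray, w: np.ndarray):
    """Survey-weighted mean with ratio-estimator standard error."""
    wsum = w.sum()
    mean = (w * y).sum() / wsum
    se = np.sqrt((w**2 * (y - mean) ** 2).sum()) / wsum
    return mean, se


def category_intake(
    recalls: pd.DataFrame,
    composition: pd.DataFrame,
    strata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Survey-weighted mean sodium (mg/d) per category per stratum.

    Output columns: stratum_id, category_id, mean_mg, se_mg, weight (the
    stratum's total survey weight, repeated per row). When ``strata`` is
    given, every stratum must be represented in the recalls with positive
    total weight.
    """
    persons, matrix = person_category_sodium(recalls, composition)
    rows = []
    for stratum_id, grp in persons.groupby("stratum_id", sort=True):
        w = grp["survey_weight"].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"zero total survey weight in stratum {stratum_id}")
        sub = matrix.loc[grp.index]
        for cat in matrix.columns:
            mean, se = _weighted_mean_se(sub[cat].to_numpy(dtype=float), w)
            rows.append(
                {
                    "stratum_id": stratum_id,
                    "category_id": cat,
                    "mean_mg": mean,
                    "se_mg": se,
                    "weight": w.sum(),
                }
            )
    out = pd.DataFrame(rows)
    if strata is not None:
        missing = set(strata["stratum_id"]) - set(out["stratum_id"])
        if missing:
            raise ValueError(f"strata without recall persons: {sorted(missing)}")
    return out


def adjust_underreporting(
    cat_intakes: pd.DataFrame,
    strata: pd.DataFrame,
    urinary_mean_by_sex: Mapping[str, float],
    nondiscretionary_share: float = 0.85,
):
    """Rescale recall-based intakes to urinary-excretion-based totals.

    For each sex s the factor f_s = share * urinary_s / recall_total_s is
    applied uniformly to every category mean and SE, where recall_total_s
    is the weight-averaged per-person total over that sex's strata. After
    adjustment each sex's total equals share * urinary_s exactly.

    Returns ``(adjusted, factors)`` with factors the per-sex scaling dict.
    """
    if not 0 < nondiscretionary_share <= 1:
        raise ValueError("nondiscretionary share must be in (0, 1]")
    sex_of = strata.set_index("stratum_id")["sex"]
    df = cat_intakes.copy()
    df["sex"] = df["stratum_id"].map(sex_of)
    if df["sex"].isna().any():
        bad = sorted(df.loc[df["sex"].isna(), "stratum_id"].unique())
        raise KeyError(f"strata missing from strata table: {bad}")

    totals = df.groupby(["sex", "stratum_id"], sort=True).agg(
        total_mg=("mean_mg", "sum"), weight=("weight", "first")
    )
    factors = {}
    for sex, grp in totals.groupby(level="sex"):
        recall_total = np.average(grp["total_mg"], weights=grp["weight"])
        if recall_total <= 0:
            raise ValueError(f"recall-based total for sex {sex!r} is not positive")
        factors[sex] = nondiscretionary_share * float(urinary_mean_by_sex[sex]) / recall_total

    scale = df["sex"].map(factors)
    adjusted = cat_intakes.copy()
    adjusted["mean_mg"] = df["mean_mg"] * scale
    adjusted["se_mg"] = df["se_mg"] * scale
    return adjusted, factors


def total_intake(cat_intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum total sodium intake (mg/d), untargeted remainder included.

    SEs are combined across categories assuming independence (root sum of
    squares) — a documented simplification; category intakes from a shared
    recall are not truly independent.
    """
    def _agg(g):
        return pd.Series(
            {
                "mean_mg": g["mean_mg"].sum(),
                "se_mg": float(np.sqrt((g["se_mg"] ** 2).sum())),
                "weight": g["weight"].iloc[0],
            }
        )

    return (
        cat_intakes.groupby("stratum_id", sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )


def population_mean(totals: pd.DataFrame, column: str = "mean_mg") -> float:
    """Survey-weight-averaged grand mean across strata (for reporting)."""
    return float(np.average(totals[column], weights=totals["weight"]))
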