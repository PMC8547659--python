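"""Sales-weighted reformulation modelling at the product level.

A reformulation program is a set of maximum sodium densities (mg/100 g) per
food category. Full compliance is simulated by clamping every covered
product's sodium density to its category target; products already at or
below the target are untouched. The effect of a program on a category is
summarized by the proportional reduction of its *sales-weighted* mean
sodium density, r_c = 1 - post/pre, where each product is weighted by its
annual kilograms sold. Company-specific effects clamp only that company's
products, leaving all sales weights fixed (no substitution between
products is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TargetSet:
    """A named reformulation scenario: category -> maximum sodium (mg/100 g)."""

    name: str
    targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cat, level in self.targets.items():
            if not np.isfinite(level) or level <= 0:
                raise ValueError(f"target for {cat!r} must be > 0, got {level}")

    @property
    def coverage(self) -> frozenset:
        return frozenset(self.targets)

    def covers(self, category: str) -> bool:
        return category in self.targets


def _merged(products: pd.DataFrame, sales: pd.DataFrame) -> pd.DataFrame:
    df = products.merge(sales, on="product_id", how="left", validate="1:1")
    if df["kg_per_year"].isna().any():
        missing = df.loc[df["kg_per_year"].isna(), "product_id"].tolist()
        raise ValueError(f"products without sales records: {missing}")
    return df


def sales_weighted_mean(products, sales, category: Optional[str] = None):
    """Sales-weighted mean sodium density, per category or for one category.

    Returns a float when ``category`` is given, otherwise a Series indexed
    by category. A category with zero total sales volume is an error: its
    weighted mean is undefined.
    """
    df = _merged(products, sales)
    if category is not None:
        df = df[df["category_id"] == category]
        if df.empty:
            raise ValueError(f"no products in category {category!r}")
    grouped = df.groupby("category_id", sort=True)
    kg = grouped["kg_per_year"].sum()
    if (kg <= 0).any():
        bad = kg.index[kg <= 0].tolist()
        raise ValueError(f"zero total sales in categories: {bad}")
    wmean = grouped.apply(
        lambda g: np.average(g["sodium_mg_per_100g"], weights=g["kg_per_year"]),
        include_groups=False,
    )
    if category is not None:
        return float(wmean.loc[category])
    return wmean.rename("sales_weighted_mg_per_100g")


def apply_targets(products, targets: TargetSet, company: Optional[str] = None):
    """Simulate full compliance: clamp covered products to their target.

    With ``company`` set, only that company's products are reformulated
    (the single-company counterfactual used for attribution).
    """
    out = products.copy()
    capped = out["category_id"].map(
        lambda c: targets.targets.get(c, np.inf)
    ).astype(float)
    mask = np.isfinite(capped)
    if company is not None:
        mask &= out["company_id"] == company
    out["sodium_mg_per_100g"] = np.where(
        mask, np.minimum(out["sodium_mg_per_100g"], capped), out["sodium_mg_per_100g"]
    )
    return out


def proportional_reduction(pre, post):
    """r = 1 - post/pre for sales-weighted means (elementwise on arrays/Series)."""
    pre_arr = np.asarray(pre, dtype=float)
    if np.any(pre_arr <= 0):
        raise ValueError("pre-reformulation mean must be > 0")
    return 1.0 - np.asarray(post, dtype=float) / pre_arr


def reformulation_effects(
    products, sales, targets: TargetSet, company: Optional[str] = None
) -> pd.DataFrame:
    """Per-category pre/post sales-weighted means and proportional reductions.

    Covered categories only; uncovered categories have r_c = 0 by definition
    and are omitted. Sales weights are identical pre and post.
    """
    covered = sorted(
        set(targets.coverage) & set(products["category_id"].unique())
    )
    pre = sales_weighted_mean(products, sales)
    post_products = apply_targets(products, targets, company=company)
    post = sales_weighted_mean(post_products, sales)
    eff = pd.DataFrame(
        {
            "category_id": covered,
            "pre_mg_per_100g": pre.loc[covered].to_numpy(),
            "post_mg_per_100g": post.loc[covered].to_numpy(),
        }
    )
    eff["reduction"] = proportional_reduction(
        eff["pre_mg_per_100g"], eff["post_mg_per_100g"]
    )
    return eff


def weighted_quantile(values, weights, q: float) -> float:
    """Left-continuous weighted quantile: smallest value whose cumulative
    weight share is >= q. No interpolation, so at least a fraction q of the
    total weight lies at or below the returned value."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty values")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    idx = np.searchsorted(cum, q, side="left")
    return float(v[order][min(idx, v.size - 1)])


def derive_percentile_targets(
    products,
    sales,
    q: float = 0.25,
    categories: Optional[Sequence[str]] = None,
    name: str = "optimistic_p25",
) -> TargetSet:
    """Targets at the sales-weighted q-th percentile sodium density.

    The default q = 0.25 builds the "optimistic" scenario: in every covered
    category, at least 25% of the sales volume already meets the target, so
    the level is demonstrably attainable in the current supply.
    """
    df = _merged(products, sales)
    if categories is not None:
        df = df[df["category_id"].isin(set(categories))]
    targets = {}
    for cat, g in df.groupby("category_id", sort=True):
        targets[cat] = weighted_quantile(
            g["sodium_mg_per_100g"], g["kg_per_year"], q
        )
    if not targets:
        raise ValueError("no categories to derive targets for")
    return TargetSet(name=name, targets=targets)


def scenario_intake_change(cat_intakes: pd.DataFrame, effects: pd.DataFrame):
    """Per-stratum sodium intake reduction implied by category reductions.

    delta_as = sum_c intake_as,c * r_c over the covered categories. Returns
    ``(per_stratum, per_stratum_category)``: total mg/d reduction per
    stratum, and the category-resolved matrix used for attribution.
    """
    known = set(cat_intakes["category_id"].unique())
    missing = [c for c in effects["category_id"] if c not in known]
    if missing:
        raise KeyError(f"effects reference categories absent from intakes: {missing}")
    merged = cat_intakes.merge(
        effects[["category_id", "reduction"]], on="category_id", how="inner"
    )
    merged["delta_mg"] = merged["mean_mg"] * merged["reduction"]
    per_sc = merged[["stratum_id", "category_id", "delta_mg"]].copy()
    strata_ids = cat_intakes["stratum_id"].drop_duplicates()
    per_stratum = (
        per_sc.groupby("stratum_id")["delta_mg"].sum()
        .reindex(strata_ids, fill_value=0.0)
        .rename("delta_mg")
        .reset_index()
    )
    return per_stratum, per_sc


def compliance_stats(products, sales, targets: TargetSet) -> pd.DataFrame:
    """Fraction of products and of sales volume already at/below target."""
    df = _merged(products, sales)
    rows = []
    for cat in sorted(set(targets.coverage) & set(df["category_id"].unique())):
        g = df[df["category_id"] == cat]
        ok = g["sodium_mg_per_100g"] <= targets.targets[cat]
        rows.append(
            {
                "category_id": cat,
                "frac_products": float(ok.mean()),
                "frac_sales": float(g.loc[ok, "kg_per_year"].sum() / g["kg_per_year"].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["category_id", "frac_products", "frac_sales"])
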