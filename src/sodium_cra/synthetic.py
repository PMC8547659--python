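"""Synthetic generators for every input table of the pipeline.

The real inputs of a national sodium-reformulation assessment — 24-hour
recall surveys, branded food composition data, household purchase panels,
and burden-of-disease tables — are proprietary. This module generates
statistically analogous stand-ins with known ground truth so the whole
pipeline is exercisable and testable offline:

* 24 age-sex strata (12 five-year bands from age 25, open-ended top band,
  both sexes) with mean SBP, hypertension prevalence, and population;
* a branded product supply with lognormal (right-skewed) sodium densities
  per category, a Zipf-like concentration of sales across companies so a
  handful of retailers/manufacturers dominate, and annual kg sold;
* person x food recall records with survey weights, linked to a
  product-level composition lookup plus untargeted "remainder" foods
  (scratch cooking, takeaway) that no program reformulates;
* burden tables (deaths, incidence, DALYs) per cause and stratum with
  multiplicative 95% uncertainty intervals, skewed toward old age.

Every generator is byte-deterministic given the config seed; independent
substreams per table keep outputs stable when tables are generated in any
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .intake import UNTARGETED
from .reformulation import TargetSet, derive_percentile_targets
from .resources import load_causes

DEFAULT_AGE_EDGES: Tuple[int, ...] = (25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80)

#: Substream labels -> fixed spawn keys, so generators are order-independent.
_STREAMS = {"strata": 0, "products": 1, "recalls": 2, "burden": 3, "composition": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class CategorySpec:
    """Per-category parameters: lognormal sodium density (mg/100 g) and
    lognormal per-food daily intake (g/d), plus whether the category is in
    the narrower program's scope (`au_covered`) or only in the broader one."""

    name: str
    sodium_log_mean: float
    sodium_log_sd: float
    intake_log_mean: float
    intake_log_sd: float
    au_covered: bool = True


def _cat(name, median_na, sd_na, median_g, sd_g, au=True) -> CategorySpec:
    return CategorySpec(name, math.log(median_na), sd_na, math.log(median_g), sd_g, au)


def default_categories() -> Tuple[CategorySpec, ...]:
    """Twelve packaged-food categories: seven covered by the narrow (AU-style)
    program, five additional covered only by the broad (UK-style) program."""
    return (
        _cat("bread", 430.0, 0.25, 100.0, 0.5),
        _cat("processed_meat", 1050.0, 0.40, 50.0, 0.6),
        _cat("sausages", 760.0, 0.30, 60.0, 0.6),
        _cat("cheese", 650.0, 0.45, 30.0, 0.6),
        _cat("savoury_biscuits", 700.0, 0.35, 25.0, 0.6),
        _cat("breakfast_cereal", 400.0, 0.50, 40.0, 0.5),
        _cat("crumbed_proteins", 450.0, 0.30, 70.0, 0.5),
        _cat("ready_meals", 350.0, 0.35, 150.0, 0.5, au=False),
        _cat("baked_beans", 300.0, 0.30, 90.0, 0.5, au=False),
        _cat("canned_vegetables", 250.0, 0.40, 70.0, 0.5, au=False),
        _cat("table_sauces", 900.0, 0.50, 20.0, 0.6, au=False),
        _cat("butter_spreads", 600.0, 0.30, 15.0, 0.5, au=False),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all synthetic generators.

    Defaults describe the study conditions the pipeline is meant to
    emulate: urinary-excretion-based intakes near 4,000 (men) and 2,900
    (women) mg/d, right-skewed intakes and sodium densities, and a sales
    concentration under which roughly five companies hold over half the
    market.
    """

    seed: int = 0
    n_persons: int = 600
    n_products_per_category: int = 30
    n_companies: int = 25
    n_retailers: int = 3
    company_concentration: float = 1.0
    age_band_edges: Tuple[int, ...] = DEFAULT_AGE_EDGES
    categories: Tuple[CategorySpec, ...] = field(default_factory=default_categories)
    n_untargeted_foods: int = 15
    untargeted_sodium_log_mean: float = math.log(250.0)
    untargeted_sodium_log_sd: float = 0.5
    untargeted_intake_log_mean: float = math.log(400.0)
    untargeted_intake_log_sd: float = 0.4
    urinary_sodium_mean: Mapping[str, float] = field(
        default_factory=lambda: {"M": 4000.0, "F": 2900.0}
    )
    mean_foods_per_person: float = 7.0
    mean_untargeted_foods_per_person: float = 2.0
    burden_scale: float = 1.0
    burden_total_deaths: float = 57000.0
    burden_ui_log_sd: float = 0.12
    prevalence_concentration: float = 60.0

    def validate(self) -> "SynthConfig":
        positive = {
            "n_persons": self.n_persons,
            "n_products_per_category": self.n_products_per_category,
            "n_companies": self.n_companies,
            "company_concentration": self.company_concentration,
            "burden_scale": self.burden_scale,
            "burden_total_deaths": self.burden_total_deaths,
            "prevalence_concentration": self.prevalence_concentration,
            "mean_foods_per_person": self.mean_foods_per_person,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_retailers > self.n_companies:
            raise ValueError("n_retailers cannot exceed n_companies")
        if len(self.age_band_edges) < 2:
            raise ValueError("need at least two age band edges")
        for sex, mean in self.urinary_sodium_mean.items():
            if mean <= 0:
                raise ValueError(f"urinary sodium mean for {sex} must be > 0")
        return self


def age_bands(config: SynthConfig):
    """[(lo, hi_inclusive)] bands; the last band is open-ended (hi = 200)."""
    edges = list(config.age_band_edges)
    bands = [(edges[i], edges[i + 1] - 1) for i in range(len(edges) - 1)]
    bands.append((edges[-1], 200))
    return bands


def _age_mid(lo: int, hi: int) -> float:
    return lo + 5.0 if hi >= 200 else (lo + hi + 1) / 2.0


def generate_strata(config: SynthConfig) -> pd.DataFrame:
    """One row per age-sex stratum: SBP, hypertension prevalence, population.

    Prevalence is drawn from a Beta family whose mean rises with age
    (logistic in age midpoint), so all values lie in [0, 1] by support.
    Population follows a declining pyramid in age.
    """
    config.validate()
    rng = _rng(config.seed, "strata")
    rows = []
    for sex in ("F", "M"):
        for lo, hi in age_bands(config):
            mid = _age_mid(lo, hi)
            prev_mean = 0.06 + 0.80 / (1.0 + math.exp(-(mid - 62.0) / 11.0))
            prev_mean = min(prev_mean, 0.90)
            kappa = config.prevalence_concentration
            prev = float(rng.beta(prev_mean * kappa, (1.0 - prev_mean) * kappa))
            prev_se = math.sqrt(prev_mean * (1 - prev_mean) / (kappa + 1.0))
            sbp = 112.0 + 0.45 * (mid - 25.0) + (2.0 if sex == "M" else 0.0)
            sbp += float(rng.normal(0.0, 2.0))
            population = 1.0e6 * math.exp(-0.025 * (mid - 25.0))
            population *= float(rng.lognormal(0.0, 0.05))
            if population <= 0:
                raise ValueError("non-positive population weight generated")
            rows.append(
                {
                    "stratum_id": f"{sex}:{lo}-{'plus' if hi >= 200 else hi}",
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "age_mid": mid,
                    "mean_sbp": sbp,
                    "htn_prev": prev,
                    "htn_prev_se": prev_se,
                    "population": population,
                }
            )
    return pd.DataFrame(rows)


def _company_weights(config: SynthConfig) -> np.ndarray:
    ranks = np.arange(1, config.n_companies + 1, dtype=float)
    w = ranks ** (-config.company_concentration)
    return w / w.sum()


def generate_products_and_sales(config: SynthConfig):
    """Branded product supply and annual sales volumes.

    Products carry a company (retailer or manufacturer), category, and
    lognormal sodium density; products are assigned to companies with
    Zipf-like probabilities, so at the default exponent the leading
    handful of companies holds the majority of products and therefore of
    kilograms sold.
    """
    config.validate()
    rng = _rng(config.seed, "products")
    weights = _company_weights(config)
    company_ids = [f"C{i + 1:02d}" for i in range(config.n_companies)]
    company_type = [
        "retailer" if i < config.n_retailers else "manufacturer"
        for i in range(config.n_companies)
    ]
    prod_rows, sales_rows = [], []
    for cat in config.categories:
        for j in range(config.n_products_per_category):
            ci = int(rng.choice(config.n_companies, p=weights))
            density = float(rng.lognormal(cat.sodium_log_mean, cat.sodium_log_sd))
            pid = f"P:{cat.name}:{j:03d}"
            prod_rows.append(
                {
                    "product_id": pid,
                    "company_id": company_ids[ci],
                    "company_type": company_type[ci],
                    "category_id": cat.name,
                    "sodium_mg_per_100g": density,
                }
            )
            kg = float(rng.lognormal(math.log(2.0e5), 0.7))
            sales_rows.append({"product_id": pid, "kg_per_year": kg})
    products = pd.DataFrame(prod_rows)
    sales = pd.DataFrame(sales_rows)
    totals = products.merge(sales, on="product_id").groupby("category_id")["kg_per_year"].sum()
    if (totals <= 0).any():
        raise ValueError("zero total sales generated in some category")
    return products, sales


def composition_table(config: SynthConfig, products: pd.DataFrame) -> pd.DataFrame:
    """Food -> (category, sodium density) lookup.

    Product-level: every branded product is a food, so reformulation acts
    per product. Untargeted foods pool everything outside program scope
    under the ``remainder`` category.
    """
    rng = _rng(config.seed, "composition")
    comp = products[["product_id", "category_id", "sodium_mg_per_100g"]].rename(
        columns={"product_id": "food_id"}
    )
    untargeted = pd.DataFrame(
        {
            "food_id": [f"U:{i:03d}" for i in range(config.n_untargeted_foods)],
            "category_id": UNTARGETED,
            "sodium_mg_per_100g": rng.lognormal(
                config.untargeted_sodium_log_mean,
                config.untargeted_sodium_log_sd,
                size=config.n_untargeted_foods,
            ),
        }
    )
    return pd.concat([comp, untargeted], ignore_index=True)


def _apportion(population: np.ndarray, n: int, minimum: int = 3) -> np.ndarray:
    """Deterministic largest-remainder apportionment with a floor, so every
    stratum receives survey persons regardless of seed."""
    n_strata = population.size
    floor_total = minimum * n_strata
    if n < floor_total:
        raise ValueError(f"n_persons must be >= {floor_total} for {n_strata} strata")
    quota = (n - floor_total) * population / population.sum()
    counts = np.floor(quota).astype(int) + minimum
    remainder = n - counts.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_recalls(config: SynthConfig, products: pd.DataFrame) -> pd.DataFrame:
    """Person x food recall records (g/d) with survey weights.

    Persons are apportioned across the 24 strata proportionally to
    population (with a floor), eat a Poisson number of branded foods plus
    untargeted remainder foods with lognormal daily amounts (men scaled
    up 30%), and carry lognormal survey weights. A person drawing zero
    foods is retained with a single zero-gram row so they still
    contribute zero intake to the weighted means.
    """
    config.validate()
    rng = _rng(config.seed, "recalls")
    strata = generate_strata(config)
    comp = composition_table(config, products)
    cat_spec = {c.name: c for c in config.categories}
    prod_ids = products["product_id"].to_numpy()
    prod_cats = products["category_id"].to_numpy()
    unt_ids = comp.loc[comp["category_id"] == UNTARGETED, "food_id"].to_numpy()

    counts = _apportion(strata["population"].to_numpy(), config.n_persons)
    rows = []
    person = 0
    for (_, stratum), n_here in zip(strata.iterrows(), counts):
        for _ in range(n_here):
            pid = f"person{person:05d}"
            person += 1
            weight = float(rng.lognormal(0.0, 0.3))
            sex_mult = 1.3 if stratum["sex"] == "M" else 1.0
            k = int(rng.poisson(config.mean_foods_per_person))
            ku = int(rng.poisson(config.mean_untargeted_foods_per_person))
            foods = []
            if k > 0:
                chosen = rng.choice(prod_ids.size, size=min(k, prod_ids.size), replace=False)
                for idx in chosen:
                    spec = cat_spec[prod_cats[idx]]
                    grams = float(rng.lognormal(spec.intake_log_mean, spec.intake_log_sd))
                    foods.append((prod_ids[idx], grams * sex_mult))
            if ku > 0 and unt_ids.size:
                chosen = rng.choice(unt_ids.size, size=min(ku, unt_ids.size), replace=False)
                for idx in chosen:
                    grams = float(
                        rng.lognormal(
                            config.untargeted_intake_log_mean,
                            config.untargeted_intake_log_sd,
                        )
                    ) / max(ku, 1)
                    foods.append((unt_ids[idx], grams * sex_mult))
            if not foods:
                foods.append((unt_ids[0] if unt_ids.size else prod_ids[0], 0.0))
            for food_id, grams in foods:
                rows.append(
                    {
                        "person_id": pid,
                        "stratum_id": stratum["stratum_id"],
                        "survey_weight": weight,
                        "food_id": food_id,
                        "grams_per_day": grams,
                    }
                )
    return pd.DataFrame(rows)


#: Baseline share of total deaths by cause; incidence and DALYs are scaled
#: multiples per cause (nonfatal burden is relatively larger for CKD).
_CAUSE_DEATH_SHARE = {
    "ischemic_heart_disease": 0.30,
    "ischemic_stroke": 0.09,
    "hemorrhagic_stroke": 0.05,
    "aortic_aneurysm": 0.02,
    "endocarditis": 0.01,
    "hypertensive_heart_disease": 0.03,
    "rheumatic_heart_disease": 0.005,
    "other_cvd": 0.10,
    "ckd": 0.08,
    "stomach_cancer": 0.02,
}
_INCIDENCE_MULT = {"ckd": 15.0, "stomach_cancer": 2.0}
_DALY_MULT = {"ckd": 14.0, "stomach_cancer": 19.0}


def generate_burden(config: SynthConfig) -> pd.DataFrame:
    """Deaths, incidence, and DALYs per cause x stratum with 95% UIs.

    Event counts rise exponentially with age (so averted burden accrues
    mostly to the oldest strata), are higher in men, and carry
    multiplicative uncertainty: ui_low = events / f, ui_high = events * f
    with f = exp(1.96 * burden_ui_log_sd). Doubling ``burden_scale``
    doubles every count exactly.
    """
    config.validate()
    rng = _rng(config.seed, "burden")
    strata = generate_strata(config)
    causes = load_causes()
    f = math.exp(1.959964 * config.burden_ui_log_sd)

    mids = strata["age_mid"].to_numpy()
    pops = strata["population"].to_numpy()
    sex_mult = np.where(strata["sex"].to_numpy() == "M", 1.25, 1.0)
    age_curve = np.exp(0.085 * (mids - 25.0))
    stratum_share = pops * age_curve * sex_mult
    stratum_share = stratum_share / stratum_share.sum()

    rows = []
    for _, cause in causes.iterrows():
        cid = cause["cause_id"]
        base_deaths = config.burden_total_deaths * _CAUSE_DEATH_SHARE[cid]
        for metric in ("deaths", "incidence", "dalys"):
            if metric == "deaths":
                level = base_deaths
            elif metric == "incidence":
                level = base_deaths * _INCIDENCE_MULT.get(cid, 4.3)
            else:
                level = base_deaths * _DALY_MULT.get(cid, 13.0)
            noise = rng.lognormal(0.0, 0.15, size=len(strata))
            events = config.burden_scale * level * stratum_share * noise
            for stratum_id, ev in zip(strata["stratum_id"], events):
                low, high = ev / f, ev * f
                if low > high:
                    raise ValueError("inverted uncertainty interval generated")
                rows.append(
                    {
                        "metric": metric,
                        "cause_id": cid,
                        "stratum_id": stratum_id,
                        "events": ev,
                        "ui_low": low,
                        "ui_high": high,
                    }
                )
    return pd.DataFrame(rows)


def make_target_sets(config: SynthConfig, products, sales) -> dict:
    """The three study scenarios on the synthetic supply.

    * ``au_hfp`` — lenient maxima (sales-weighted 60th percentile) over the
      narrow covered-category set; a substantial share of products already
      complies, mirroring criticism that real targets are unambitious.
    * ``uk_2017`` — stricter maxima (40th percentile) over every category.
    * ``optimistic_p25`` — sales-weighted 25th percentile over every
      category.

    Quantile monotonicity in q makes the three element-wise nested, which
    yields the expected ordering of health impacts.
    """
    au_cats = [c.name for c in config.categories if c.au_covered]
    all_cats = [c.name for c in config.categories]
    au = derive_percentile_targets(products, sales, q=0.60, categories=au_cats, name="au_hfp")
    uk = derive_percentile_targets(products, sales, q=0.40, categories=all_cats, name="uk_2017")
    opt = derive_percentile_targets(
        products, sales, q=0.25, categories=all_cats, name="optimistic_p25"
    )
    return {"au_hfp": au, "uk_2017": uk, "optimistic_p25": opt}


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference values recomputed directly from raw tables."""

    category_reductions: pd.DataFrame  # scenario, category_id, reduction
    stratum_delta_mg: pd.DataFrame  # scenario, stratum_id, delta_mg


def ground_truth(
    config: SynthConfig,
    strata: pd.DataFrame,
    products: pd.DataFrame,
    sales: pd.DataFrame,
    recalls: pd.DataFrame,
    composition: pd.DataFrame,
    target_sets: Mapping[str, TargetSet],
    nondiscretionary_share: float = 0.85,
) -> GroundTruth:
    """Recompute per-category reductions and per-stratum intake reductions
    in one dense pass, independent of the modular pipeline code path.

    Used as the oracle for end-to-end self-consistency: the staged
    pipeline must recover these values on the same tables.
    """
    df = products.merge(sales, on="product_id")
    red_rows = []
    for scen, ts in target_sets.items():
        for cat, g in df.groupby("category_id"):
            if cat not in ts.targets:
                continue
            kg = g["kg_per_year"].to_numpy()
            d = g["sodium_mg_per_100g"].to_numpy()
            clamped = np.minimum(d, ts.targets[cat])
            r = 1.0 - (clamped * kg).sum() / (d * kg).sum()
            red_rows.append({"scenario": scen, "category_id": cat, "reduction": r})
    reductions = pd.DataFrame(red_rows)

    rec = recalls.merge(
        composition[["food_id", "category_id", "sodium_mg_per_100g"]], on="food_id"
    )
    rec["sodium_mg"] = rec["grams_per_day"] * rec["sodium_mg_per_100g"] / 100.0
    persons = rec.groupby(
        ["person_id", "stratum_id", "survey_weight"], as_index=False
    )["sodium_mg"].sum()
    sex_of = strata.set_index("stratum_id")["sex"]
    persons["sex"] = persons["stratum_id"].map(sex_of)
    factors = {}
    for sex, g in persons.groupby("sex"):
        recall_total = np.average(g["sodium_mg"], weights=g["survey_weight"])
        factors[sex] = (
            nondiscretionary_share * config.urinary_sodium_mean[sex] / recall_total
        )

    person_meta = persons.set_index("person_id")
    per_cat = rec.groupby(["person_id", "category_id"], as_index=False)["sodium_mg"].sum()
    per_cat["stratum_id"] = per_cat["person_id"].map(person_meta["stratum_id"])
    per_cat["survey_weight"] = per_cat["person_id"].map(person_meta["survey_weight"])
    all_persons = person_meta[["stratum_id", "survey_weight"]]
    delta_rows = []
    for scen, ts in target_sets.items():
        rmap = reductions[reductions["scenario"] == scen].set_index("category_id")["reduction"]
        for stratum_id, sgrp in all_persons.groupby("stratum_id"):
            w_all = sgrp["survey_weight"]
            delta = 0.0
            cat_here = per_cat[per_cat["stratum_id"] == stratum_id]
            for cat, r in rmap.items():
                sub = cat_here[cat_here["category_id"] == cat].set_index("person_id")
                y = sub["sodium_mg"].reindex(sgrp.index).fillna(0.0)
                mean_cat = np.average(y, weights=w_all)
                delta += mean_cat * factors[sex_of[stratum_id]] * r
            delta_rows.append(
                {"scenario": scen, "stratum_id": stratum_id, "delta_mg": delta}
            )
    return GroundTruth(
        category_reductions=reductions,
        stratum_delta_mg=pd.DataFrame(delta_rows),
    )
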