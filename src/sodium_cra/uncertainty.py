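"""Monte Carlo propagation of input uncertainty.

Each simulation draw perturbs seven independent parameter blocks:

(a) pre-reformulation mean intake per stratum and the per-category
    reformulation effect, (b) hypertension prevalence per stratum,
(c) the main/age/hypertension SBP meta-regression coefficients,
(d, e) the log relative risks per cause and age (blood-pressure-mediated
    causes and stomach cancer share one array), (f) the TMREL, and
(g) baseline event counts per metric, cause, and stratum.

Families follow standard comparative-risk-assessment practice: normal for
means and coefficients (SE-parameterized), moment-matched beta for
prevalences, normal on the log scale for relative risks and event counts
(sigma from 95% interval widths), and zero-truncated normal for the
TMREL. Draws use counter-style substreams keyed by (seed, draw index,
block), so results are independent of execution order and the first n
draws of a longer run reproduce a shorter run exactly.

Outputs are summarized by the 50th percentile (central estimate) and the
2.5th-97.5th percentiles (95% uncertainty interval), with linear
interpolation between order statistics. Aggregates are summarized from
per-draw sums, so the median of a sum need not equal the sum of medians.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict

import numpy as np
from scipy import stats

_BLOCKS = {"intake": 0, "prevalence": 1, "sbp": 2, "ln_rr": 3, "tmrel": 4, "events": 5}


def _stream(seed: int, index: int, block: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(index, _BLOCKS[block]))
    )


@dataclass(frozen=True)
class DrawSpec:
    """Central values and dispersions for every uncertain input.

    Shapes: stratum arrays (S,), category arrays (C,), relative-risk
    arrays (K causes, S strata), event arrays (3 metrics, K, S).
    """

    x_pre_mean: np.ndarray
    x_pre_se: np.ndarray
    reduction_mean: np.ndarray
    reduction_sd: np.ndarray
    prev_mean: np.ndarray
    prev_sd: np.ndarray
    sbp_mean: np.ndarray  # (main, age_interaction, hypertension_interaction)
    sbp_se: np.ndarray
    ln_rr_mean: np.ndarray
    ln_rr_se: np.ndarray
    tmrel_mean_g: float
    tmrel_sd_g: float
    events_mean: np.ndarray
    events_sigma: np.ndarray

    def validate(self) -> "DrawSpec":
        if np.any(self.prev_mean < 0) or np.any(self.prev_mean > 1):
            raise ValueError("prevalence means must be in [0, 1]")
        interior = (self.prev_mean > 0) & (self.prev_mean < 1)
        var = np.asarray(self.prev_sd, dtype=float) ** 2
        if np.any(var[interior] >= (self.prev_mean * (1 - self.prev_mean))[interior]):
            raise ValueError("prevalence SD too large for a beta family")
        if self.tmrel_mean_g <= 0:
            raise ValueError("TMREL mean must be > 0")
        if self.tmrel_sd_g < 0:
            raise ValueError("TMREL SD must be >= 0")
        if np.any(self.events_mean <= 0):
            raise ValueError("baseline event counts must be > 0")
        for name in ("x_pre_se", "reduction_sd", "prev_sd", "sbp_se", "ln_rr_se", "events_sigma"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        return self

    def scaled(self, factor: float) -> "DrawSpec":
        """Copy with every dispersion multiplied by ``factor``."""
        return replace(
            self,
            x_pre_se=self.x_pre_se * factor,
            reduction_sd=self.reduction_sd * factor,
            prev_sd=self.prev_sd * factor,
            sbp_se=self.sbp_se * factor,
            ln_rr_se=self.ln_rr_se * factor,
            tmrel_sd_g=self.tmrel_sd_g * factor,
            events_sigma=self.events_sigma * factor,
        )

    def zeroed(self) -> "DrawSpec":
        """Copy with all dispersions set to zero (degenerate draws)."""
        return self.scaled(0.0)


@dataclass(frozen=True)
class ParameterDraw:
    """One realized parameter set."""

    x_pre: np.ndarray
    reduction: np.ndarray
    prev: np.ndarray
    sbp_main: float
    sbp_age: float
    sbp_hyp: float
    ln_rr: np.ndarray
    tmrel_g: float
    events: np.ndarray


def _beta_draw(rng, mean, sd):
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = mean.copy()
    active = (sd > 0) & (mean > 0) & (mean < 1)
    if np.any(active):
        m, v = mean[active], sd[active] ** 2
        nu = m * (1 - m) / v - 1.0
        out[active] = rng.beta(m * nu, (1 - m) * nu)
    return out


def draw_parameters(spec: DrawSpec, seed: int, index: int) -> ParameterDraw:
    """Deterministic draw for a given (seed, draw index)."""
    spec.validate()
    rng = _stream(seed, index, "intake")
    x_pre = np.maximum(rng.normal(spec.x_pre_mean, spec.x_pre_se), 0.0)
    reduction = np.clip(rng.normal(spec.reduction_mean, spec.reduction_sd), 0.0, 1.0)

    prev = _beta_draw(_stream(seed, index, "prevalence"), spec.prev_mean, spec.prev_sd)

    rng = _stream(seed, index, "sbp")
    sbp = rng.normal(spec.sbp_mean, spec.sbp_se)

    ln_rr = _stream(seed, index, "ln_rr").normal(spec.ln_rr_mean, spec.ln_rr_se)

    if spec.tmrel_sd_g > 0:
        a = (0.0 - spec.tmrel_mean_g) / spec.tmrel_sd_g
        tmrel = float(
            stats.truncnorm.rvs(
                a,
                np.inf,
                loc=spec.tmrel_mean_g,
                scale=spec.tmrel_sd_g,
                random_state=_stream(seed, index, "tmrel"),
            )
        )
    else:
        tmrel = spec.tmrel_mean_g

    z = _stream(seed, index, "events").standard_normal(spec.events_mean.shape)
    events = spec.events_mean * np.exp(spec.events_sigma * z)

    return ParameterDraw(
        x_pre=x_pre,
        reduction=reduction,
        prev=prev,
        sbp_main=float(sbp[0]),
        sbp_age=float(sbp[1]),
        sbp_hyp=float(sbp[2]),
        ln_rr=ln_rr,
        tmrel_g=tmrel,
        events=events,
    )


def central_parameters(spec: DrawSpec) -> ParameterDraw:
    """The parameter set with every input at its central value."""
    return ParameterDraw(
        x_pre=np.asarray(spec.x_pre_mean, dtype=float).copy(),
        reduction=np.asarray(spec.reduction_mean, dtype=float).copy(),
        prev=np.asarray(spec.prev_mean, dtype=float).copy(),
        sbp_main=float(spec.sbp_mean[0]),
        sbp_age=float(spec.sbp_mean[1]),
        sbp_hyp=float(spec.sbp_mean[2]),
        ln_rr=np.asarray(spec.ln_rr_mean, dtype=float).copy(),
        tmrel_g=float(spec.tmrel_mean_g),
        events=np.asarray(spec.events_mean, dtype=float).copy(),
    )


def run_draws(
    pipeline: Callable[[ParameterDraw], Dict[str, np.ndarray]],
    spec: DrawSpec,
    n: int = 1000,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Run ``pipeline`` on n parameter draws and stack outputs per key.

    The pipeline must be a pure function of the parameter set. A failing
    draw aborts the run with the draw index attached — draws are never
    silently skipped.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    spec.validate()
    collected: Dict[str, list] = {}
    for i in range(n):
        params = draw_parameters(spec, seed, i)
        try:
            out = pipeline(params)
        except Exception as exc:  # pragma: no cover - surfaced, not swallowed
            raise RuntimeError(f"pipeline failed on draw {i}") from exc
        for key, value in out.items():
            collected.setdefault(key, []).append(np.asarray(value, dtype=float))
    return {key: np.stack(vals, axis=0) for key, vals in collected.items()}


def summarize(draws: Dict[str, np.ndarray]) -> Dict[str, Dict[str, np.ndarray]]:
    """Central (median) and 95% UI (2.5/97.5 percentiles) per quantity.

    Percentiles use linear interpolation between order statistics; with a
    single draw the interval collapses onto the value.
    """
    if not draws:
        raise ValueError("no draws to summarize")
    out = {}
    for key, arr in draws.items():
        if arr.shape[0] < 1:
            raise ValueError(f"empty draw array for {key!r}")
        lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0, method="linear")
        out[key] = {"central": med, "lo": lo, "hi": hi}
    return out
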