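"""Probabilistic sensitivity analysis.

Method-of-moments beta/gamma fitting, seeded Monte Carlo propagation of the
four arm-level quantities, cost-effectiveness-plane classification, the
cost-effective proportion under the quadrant rule, and acceptability curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import AnalysisConfig, CurrencySpec, Threshold, round2, threshold_in_usd

__all__ = [
    "DistributionSpec",
    "PSADraw",
    "PSAResult",
    "InfeasibleMomentsError",
    "fit_beta_moments",
    "fit_gamma_moments",
    "sample",
    "classify_ce_plane",
    "run_psa",
    "compute_ceac",
    "specs_from_config",
    "CATEGORIES",
    "CE_CATEGORIES",
]

#: Cost-effectiveness-plane categories, in reporting order.
CATEGORIES = ("dominant", "ne_below", "ne_above", "sw", "dominated", "boundary")
#: Categories counted cost-effective under the quadrant rule (boundary draws
#: are decided individually by the net-benefit sign, see :func:`run_psa`).
CE_CATEGORIES = ("dominant", "ne_below")


class InfeasibleMomentsError(ValueError):
    """The requested (mean, se) pair is outside the family's feasible region."""


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution fitted to a target mean and standard error.

    ``shape1``/``shape2`` are (alpha, beta) for the beta family and
    (shape k, scale theta) for the gamma family.  A zero ``se`` yields a
    degenerate point mass at the mean (``degenerate`` flag set; shapes NaN).
    """

    family: str
    mean: float
    se: float
    shape1: float
    shape2: float

    @property
    def degenerate(self) -> bool:
        return self.se == 0.0


def fit_beta_moments(mean: float, se: float) -> DistributionSpec:
    """Fit a beta distribution by the method of moments.

    With nu = mean*(1-mean)/se^2 - 1, the shapes are alpha = mean*nu and
    beta = (1-mean)*nu; the fitted distribution's analytic mean and sd equal
    the inputs.  Requires se^2 < mean*(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean!r}")
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se!r}")
    if se == 0.0:
        return DistributionSpec("beta", mean, 0.0, float("nan"), float("nan"))
    if se * se >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta moments infeasible: se^2 = {se * se:.6g} >= "
            f"mean*(1-mean) = {mean * (1.0 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return DistributionSpec("beta", mean, se, mean * nu, (1.0 - mean) * nu)


def fit_gamma_moments(mean: float, se: float) -> DistributionSpec:
    """Fit a gamma distribution by the method of moments.

    Shape k = mean^2/se^2 and scale theta = se^2/mean.  A zero ``se`` is
    allowed and produces a flagged point-mass spec whose draws all equal the
    mean.
    """
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean!r}")
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se!r}")
    if se == 0.0:
        return DistributionSpec("gamma", mean, 0.0, float("nan"), float("nan"))
    return DistributionSpec("gamma", mean, se, (mean / se) ** 2, se * se / mean)


def sample(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw from a fitted spec; degenerate specs return the mean exactly."""
    if spec.degenerate:
        return spec.mean if size is None else np.full(size, spec.mean)
    if spec.family == "beta":
        return rng.beta(spec.shape1, spec.shape2, size=size)
    if spec.family == "gamma":
        return rng.gamma(spec.shape1, spec.shape2, size=size)
    raise ValueError(f"unknown family {spec.family!r}")


def classify_ce_plane(delta_cost: float, delta_effect: float, lambda_usd: float) -> str:
    """Classify one (dC, dE) pair on the cost-effectiveness plane.

    dominant: cheaper and more effective; dominated: costlier and less
    effective; ne_below / ne_above: costlier and more effective with the ratio
    at-or-below / above the threshold (inclusive comparison at the threshold);
    sw: cheaper and less effective.  Exact zeros on either axis go to the
    separate ``boundary`` category.
    """
    if lambda_usd <= 0:
        raise ValueError(f"lambda_usd must be > 0, got {lambda_usd!r}")
    if delta_cost == 0.0 or delta_effect == 0.0:
        return "boundary"
    if delta_cost < 0.0:
        return "dominant" if delta_effect > 0.0 else "sw"
    if delta_effect < 0.0:
        return "dominated"
    return "ne_below" if delta_cost / delta_effect <= lambda_usd else "ne_above"


@dataclass(frozen=True)
class PSADraw:
    """One Monte Carlo realization of the four arm quantities."""

    cost_int: float
    cost_con: float
    eff_int: float
    eff_con: float
    delta_cost: float
    delta_effect: float
    category: str


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo PSA output: retained draws, category counts, decision proportion."""

    n_draws: int
    seed: int | None
    lambda_usd: float
    counts: dict[str, int]
    proportion_ce: float
    draws: tuple[PSADraw, ...] = ()

    @classmethod
    def from_counts(cls, counts: dict[str, int], seed: int | None = None,
                    lambda_usd: float = float("nan")) -> "PSAResult":
        """Build a result from pre-tabulated category counts (no draws retained).

        The cost-effective proportion is (dominant + ne_below) / n under the
        quadrant rule; boundary draws, if tabulated, are not counted.
        """
        full = {c: int(counts.get(c, 0)) for c in CATEGORIES}
        extra = set(counts) - set(CATEGORIES)
        if extra:
            raise ValueError(f"unknown categories {sorted(extra)}")
        n = sum(full.values())
        if n < 1:
            raise ValueError("counts must sum to a positive number of draws")
        prop = sum(full[c] for c in CE_CATEGORIES) / n
        return cls(n_draws=n, seed=seed, lambda_usd=lambda_usd,
                   counts=full, proportion_ce=prop)

    def to_dataframe(self) -> pd.DataFrame:
        """Draw table with one row per draw (audit/export format)."""
        return pd.DataFrame(
            [(i, d.cost_int, d.cost_con, d.eff_int, d.eff_con,
              d.delta_cost, d.delta_effect, d.category)
             for i, d in enumerate(self.draws)],
            columns=["draw", "cost_int", "cost_con", "eff_int", "eff_con",
                     "delta_cost", "delta_effect", "category"],
        )

    def summary(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "lambda_usd": self.lambda_usd,
            "counts": {c: self.counts.get(c, 0) for c in CATEGORIES},
            "proportion_ce": self.proportion_ce,
            "percent_ce": round2(100.0 * self.proportion_ce),
        }

    def to_json(self) -> str:
        """Deterministic serialization (summary plus full-precision draws)."""
        payload = self.summary()
        payload["draws"] = [
            [repr(d.cost_int), repr(d.cost_con), repr(d.eff_int), repr(d.eff_con),
             repr(d.delta_cost), repr(d.delta_effect), d.category]
            for d in self.draws
        ]
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def run_psa(
    cost_int: DistributionSpec,
    cost_con: DistributionSpec,
    eff_int: DistributionSpec,
    eff_con: DistributionSpec,
    thr: Threshold,
    fx: CurrencySpec,
    n_draws: int = 1000,
    seed: int | None = None,
) -> PSAResult:
    """Seeded Monte Carlo PSA over the four arm quantities.

    Draws are taken independently; per draw the generator stream is consumed
    in the fixed order (cost_int, cost_con, eff_int, eff_con) so exported
    tables can be re-derived from the seed.  Boundary draws (an exact zero
    delta) count as cost-effective iff lambda*dE - dC >= 0.
    """
    for name, spec in (("cost_int", cost_int), ("cost_con", cost_con),
                       ("eff_int", eff_int), ("eff_con", eff_con)):
        if spec is None:
            raise ValueError(f"missing distribution spec for {name}")
    if seed is None:
        raise ValueError("run_psa requires an explicit seed")
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws!r}")

    lam = threshold_in_usd(thr, fx)
    rng = np.random.default_rng(seed)

    draws: list[PSADraw] = []
    counts = dict.fromkeys(CATEGORIES, 0)
    n_ce = 0
    for _ in range(n_draws):
        ci = float(sample(cost_int, rng))
        cc = float(sample(cost_con, rng))
        ei = float(sample(eff_int, rng))
        ec = float(sample(eff_con, rng))
        dc, de = ci - cc, ei - ec
        cat = classify_ce_plane(dc, de, lam)
        counts[cat] += 1
        if cat in CE_CATEGORIES or (cat == "boundary" and lam * de - dc >= 0):
            n_ce += 1
        draws.append(PSADraw(ci, cc, ei, ec, dc, de, cat))

    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        lambda_usd=lam,
        counts=counts,
        proportion_ce=n_ce / n_draws,
        draws=tuple(draws),
    )


def compute_ceac(
    result: PSAResult,
    lambda_grid,
    rule: str = "nmb",
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a grid of thresholds (USD).

    rule='nmb': acceptance at lambda is the fraction of draws with
    lambda*dE - dC > 0.  rule='paper_quadrant': the quadrant rule used by
    :func:`run_psa` (dominant + ne_below, boundary by net-benefit sign),
    which excludes cheaper-and-less-effective draws regardless of lambda.
    """
    grid = [float(l) for l in lambda_grid]
    if not grid:
        raise ValueError("lambda_grid must be non-empty")
    if any(l <= 0 for l in grid):
        raise ValueError("lambda_grid values must be > 0")
    if rule not in ("nmb", "paper_quadrant"):
        raise ValueError(f"unknown rule {rule!r}")
    if not result.draws:
        raise ValueError("CEAC requires a result with retained draws")

    dc = np.array([d.delta_cost for d in result.draws])
    de = np.array([d.delta_effect for d in result.draws])
    n = len(dc)

    curve = []
    for lam in grid:
        if rule == "nmb":
            acc = int(np.count_nonzero(lam * de - dc > 0)) / n
        else:
            ce = ((dc < 0) & (de > 0))                      # dominant
            ce |= (dc > 0) & (de > 0) & (dc / np.where(de == 0, np.nan, de) <= lam)
            ce |= ((dc == 0) | (de == 0)) & (lam * de - dc >= 0)   # boundary
            acc = int(np.count_nonzero(ce)) / n
        curve.append((lam, acc))
    return curve


def specs_from_config(cfg: AnalysisConfig) -> dict[str, DistributionSpec]:
    """Fit the four sampling specs from an analysis config.

    Costs get gamma fits, effects get beta fits (QALYs over a sub-year horizon
    lie in (0, 1)).  Standard errors come from the arm fields when present,
    otherwise from the ``psa.se_rule`` fraction of the mean.
    """
    def se_for(mean: float, given: float | None) -> float:
        return given if given is not None else cfg.psa.se_rule * mean

    return {
        "cost_int": fit_gamma_moments(
            cfg.intervention.mean_cost, se_for(cfg.intervention.mean_cost,
                                               cfg.intervention.cost_se)),
        "cost_con": fit_gamma_moments(
            cfg.comparator.mean_cost, se_for(cfg.comparator.mean_cost,
                                             cfg.comparator.cost_se)),
        "eff_int": fit_beta_moments(
            cfg.intervention.mean_effect, se_for(cfg.intervention.mean_effect,
                                                 cfg.intervention.effect_se)),
        "eff_con": fit_beta_moments(
            cfg.comparator.mean_effect, se_for(cfg.comparator.mean_effect,
                                               cfg.comparator.effect_se)),
    }
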