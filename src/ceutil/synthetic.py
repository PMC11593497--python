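"""Synthetic two-arm trial data with the statistical structure the analysis assumes.

Per-patient costs are gamma-distributed and per-patient utilities are
beta-distributed, fitted by the method of moments, so every pipeline stage can
be exercised and parameter recovery verified without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import CostItem, StrategyArm
from .psa import fit_beta_moments, fit_gamma_moments, sample

__all__ = [
    "PatientRecord",
    "ArmEstimate",
    "EstimationError",
    "generate_trial",
    "estimate_arm_params",
    "generate_cost_table",
    "ARMS",
]

ARMS = ("INT", "CON")


class EstimationError(ValueError):
    """An arm has too few records to estimate a standard error."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    arm: str
    cost: float
    utility: float
    horizon_weeks: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.cost < 0:
            raise ValueError(f"cost must be >= 0, got {self.cost!r}")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"utility must be in [0, 1], got {self.utility!r}")
        if self.horizon_weeks < 1:
            raise ValueError(f"horizon_weeks must be >= 1, got {self.horizon_weeks!r}")


@dataclass(frozen=True)
class ArmEstimate:
    """Sample means and standard errors of cost and QALY for one arm."""

    arm: str
    n: int
    mean_cost: float
    se_cost: float
    mean_effect: float
    se_effect: float

    def to_strategy_arm(self) -> StrategyArm:
        return StrategyArm(name=self.arm, mean_cost=self.mean_cost,
                           mean_effect=self.mean_effect,
                           cost_se=self.se_cost, effect_se=self.se_effect)


def generate_trial(
    n_int: int,
    n_con: int,
    cost_means: tuple[float, float],
    cost_ses: tuple[float, float],
    utility_means: tuple[float, float],
    utility_ses: tuple[float, float],
    horizon_weeks: int = 12,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Draw per-patient records for a two-arm trial.

    Moment pairs are (INT, CON) ordered.  Costs are drawn from
    method-of-moments gamma fits, utilities from beta fits; infeasible beta
    moments raise the same error as the fitting routine.  Reproducible under
    ``seed``.
    """
    if n_int < 0 or n_con < 0 or n_int + n_con < 1:
        raise ValueError("need at least one patient across the two arms")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for arm, n, c_mean, c_se, u_mean, u_se in (
        ("INT", n_int, cost_means[0], cost_ses[0], utility_means[0], utility_ses[0]),
        ("CON", n_con, cost_means[1], cost_ses[1], utility_means[1], utility_ses[1]),
    ):
        if n == 0:
            continue
        cost_spec = fit_gamma_moments(c_mean, c_se)
        util_spec = fit_beta_moments(u_mean, u_se)
        costs = sample(cost_spec, rng, size=n)
        utils = sample(util_spec, rng, size=n)
        for i in range(n):
            records.append(PatientRecord(
                patient_id=f"{arm}-{i + 1:03d}",
                arm=arm,
                cost=float(costs[i]),
                utility=float(utils[i]),
                horizon_weeks=horizon_weeks,
            ))
    return records


def estimate_arm_params(records: list[PatientRecord],
                        weeks_per_year: float = 52.0) -> tuple[ArmEstimate, ArmEstimate]:
    """Per-arm sample means and standard errors of cost and QALY.

    Per-patient QALY is utility * horizon_weeks / weeks_per_year; the
    standard error is the sample standard deviation (ddof=1) over sqrt(n).
    Returns (INT, CON); an arm with fewer than two records raises
    :class:`EstimationError`.
    """
    out = []
    for arm in ARMS:
        sub = [r for r in records if r.arm == arm]
        if len(sub) < 2:
            raise EstimationError(
                f"arm {arm!r} has {len(sub)} record(s); need >= 2 for se estimation")
        costs = np.array([r.cost for r in sub])
        qalys = np.array([r.utility * r.horizon_weeks / weeks_per_year for r in sub])
        n = len(sub)
        out.append(ArmEstimate(
            arm=arm,
            n=n,
            mean_cost=float(costs.mean()),
            se_cost=float(costs.std(ddof=1) / math.sqrt(n)),
            mean_effect=float(qalys.mean()),
            se_effect=float(qalys.std(ddof=1) / math.sqrt(n)),
        ))
    return out[0], out[1]


# fixture: the six resource lines of the packaged cost table (USD line totals,
# already corrected/converted)
_COST_TEMPLATE = (
    ("Structure", "IMT device", "1 unit", 1200.0, "Market price"),
    ("Structure", "Treadmill", "1 unit", 1150.0, "Market price"),
    ("Structure", "Resistance exercise station", "2 units", 1132.0, "Market price"),
    ("Structure", "Oxygen supplier device", "2 units", 960.0, "Market price"),
    ("Rehabilitation team salaries",
     "Physicians, physical therapists, nurses, and administrative employment",
     "Per month", 2347.0, "Health Secretary of Distrito Federal"),
    ("Supplies", "Cleaners, nose catheter, individual protective equipment",
     "200 units", 1345.0, "SIGTAP"),
)


def generate_cost_table(seed: int | None = None) -> list[CostItem]:
    """Emit the six-line resource cost table.

    Without a seed the exact fixture values are returned; with a seed each
    monetary value is jittered (log-normal, ~20% sd) while the schema — labels,
    unit descriptions, sources — is unchanged.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    items = []
    for cost_type, label, units_label, value, source in _COST_TEMPLATE:
        if rng is not None:
            value = float(np.round(value * rng.lognormal(0.0, 0.2), 2))
        items.append(CostItem(
            resource_label=label,
            n_units=1,
            unit_cost=value,
            currency="USD",
            source=source,
            period=units_label if "month" in units_label.lower() else None,
            units_label=units_label,
            cost_type=cost_type,
            corrected=True,
        ))
    return items
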