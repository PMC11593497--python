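"""Base-case cost-utility computation.

QALY accrual, incremental cost and effect, the incremental cost-effectiveness
ratio (ICER) with dominance status, and incremental net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    CurrencySpec,
    StrategyArm,
    Threshold,
    TimeHorizon,
    UtilityParam,
    threshold_in_usd,
)

__all__ = [
    "ICERResult",
    "NMBResult",
    "compute_qaly",
    "compute_icer",
    "compute_inmb",
    "STATUS_DOMINANT",
    "STATUS_DOMINATED",
    "STATUS_TRADEOFF_NE",
    "STATUS_TRADEOFF_SW",
    "STATUS_INDIFFERENT",
]

STATUS_DOMINANT = "dominant"
STATUS_DOMINATED = "dominated"
STATUS_TRADEOFF_NE = "trade-off-NE"
STATUS_TRADEOFF_SW = "trade-off-SW"
STATUS_INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of an intervention against its comparator.

    ``icer`` is None exactly when ``delta_effect == 0`` (the ratio is
    undefined); ``icer_defined`` mirrors that as an explicit flag.  When the
    status is dominant or dominated the ratio is suppressed in reports — the
    status alone carries the decision.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None

    @property
    def report_icer(self) -> float | None:
        """The ratio as it should appear in reports (suppressed under dominance)."""
        if self.status in (STATUS_DOMINANT, STATUS_DOMINATED):
            return None
        return self.icer


@dataclass(frozen=True)
class NMBResult:
    """Incremental net monetary benefit at a willingness-to-pay value (USD/QALY)."""

    lambda_usd: float
    inmb: float


def compute_qaly(u: UtilityParam, h: TimeHorizon) -> float:
    """Quality-adjusted life years accrued at utility ``u`` over horizon ``h``.

    >>> compute_qaly(UtilityParam("full", 1.0), TimeHorizon(weeks=52))
    1.0
    """
    return u.utility * h.years


def compute_icer(int_arm: StrategyArm, con_arm: StrategyArm) -> ICERResult:
    """Incremental cost, incremental effect, ICER and dominance status.

    Dominance is strict: dominant means cheaper *and* more effective,
    dominated means costlier *and* less effective.  Equal-cost or
    equal-effect comparisons fall into the trade-off statuses by the sign of
    the non-zero delta; identical arms are indifferent.
    """
    delta_cost = int_arm.mean_cost - con_arm.mean_cost
    delta_effect = int_arm.mean_effect - con_arm.mean_effect

    if delta_cost == 0 and delta_effect == 0:
        return ICERResult(0.0, 0.0, None, STATUS_INDIFFERENT)

    if delta_effect == 0:
        # undefined ratio; the cost sign alone determines the trade-off label
        status = STATUS_TRADEOFF_NE if delta_cost > 0 else STATUS_TRADEOFF_SW
        return ICERResult(delta_cost, 0.0, None, status)

    icer = delta_cost / delta_effect
    if delta_cost < 0 and delta_effect > 0:
        status = STATUS_DOMINANT
    elif delta_cost > 0 and delta_effect < 0:
        status = STATUS_DOMINATED
    elif delta_effect > 0:
        status = STATUS_TRADEOFF_NE
    else:
        status = STATUS_TRADEOFF_SW
    return ICERResult(delta_cost, delta_effect, icer, status)


def compute_inmb(result: ICERResult, thr: Threshold, fx: CurrencySpec) -> NMBResult:
    """Incremental net monetary benefit: lambda * dE - dC, with lambda in USD."""
    lam = threshold_in_usd(thr, fx)
    return NMBResult(lambda_usd=lam, inmb=lam * result.delta_effect - result.delta_cost)
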