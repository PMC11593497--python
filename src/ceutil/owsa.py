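"""One-way (univariate) deterministic sensitivity analysis with tornado ordering."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .deterministic import compute_icer, compute_inmb
from .parameters import AnalysisConfig, CurrencySpec, StrategyArm, Threshold

__all__ = ["ParamBound", "TornadoRow", "make_bounds", "run_owsa", "PARAM_NAMES"]

#: Scalar parameters that can be varied one at a time.
PARAM_NAMES = (
    "int.mean_cost",
    "con.mean_cost",
    "int.mean_effect",
    "con.mean_effect",
)

BOUND_SOURCES = ("CI", "pct15", "custom")


@dataclass(frozen=True)
class ParamBound:
    """Low/high re-evaluation interval for one scalar parameter."""

    param_name: str
    low: float
    high: float
    bound_source: str

    def __post_init__(self) -> None:
        if self.bound_source not in BOUND_SOURCES:
            raise ValueError(f"bound_source must be one of {BOUND_SOURCES}, "
                             f"got {self.bound_source!r}")
        if self.low > self.high:
            raise ValueError(f"low must be <= high, got ({self.low!r}, {self.high!r})")


@dataclass(frozen=True)
class TornadoRow:
    """Outcome of re-evaluating the model at one parameter's bounds."""

    param_name: str
    outcome_at_low: float
    outcome_at_high: float
    range: float
    outcome: str
    sign_flip: bool = False  # the ICER changed sign or lost definition inside the bound


def make_bounds(base_value: float, source: str, ci: tuple[float, float] | None = None,
                param_name: str = "", variation: float = 0.15) -> ParamBound:
    """Build a bound interval around a base value.

    'pct15' (or any ``variation`` fraction) gives (1-v, 1+v) times base;
    'CI' takes the supplied pair; 'custom' passes the pair through.
    """
    if source == "pct15":
        lo, hi = base_value * (1.0 - variation), base_value * (1.0 + variation)
        if lo > hi:  # negative base flips the endpoints
            lo, hi = hi, lo
        return ParamBound(param_name, lo, hi, "pct15")
    if source in ("CI", "custom"):
        if ci is None:
            raise ValueError(f"source {source!r} requires an explicit (low, high) pair")
        return ParamBound(param_name, ci[0], ci[1], source)
    raise ValueError(f"unknown bound source {source!r}")


def _set_param(int_arm: StrategyArm, con_arm: StrategyArm, name: str,
               value: float) -> tuple[StrategyArm, StrategyArm]:
    if name == "int.mean_cost":
        return replace(int_arm, mean_cost=value), con_arm
    if name == "con.mean_cost":
        return int_arm, replace(con_arm, mean_cost=value)
    if name == "int.mean_effect":
        return replace(int_arm, mean_effect=value), con_arm
    if name == "con.mean_effect":
        return int_arm, replace(con_arm, mean_effect=value)
    raise ValueError(f"unknown parameter {name!r}; valid names: {', '.join(PARAM_NAMES)}")


def _evaluate(int_arm: StrategyArm, con_arm: StrategyArm, outcome: str,
              thr: Threshold, fx: CurrencySpec) -> tuple[float, bool]:
    """Outcome value plus a flag marking an undefined/sign-ambiguous ICER."""
    res = compute_icer(int_arm, con_arm)
    if outcome == "iNMB":
        return compute_inmb(res, thr, fx).inmb, False
    if res.icer is None:
        return float("nan"), True
    return res.icer, False


def run_owsa(config: AnalysisConfig, bounds: list[ParamBound],
             outcome: str = "ICER") -> list[TornadoRow]:
    """Re-evaluate the base case at each parameter's bounds, one at a time.

    Returns rows sorted by descending range (ties keep input order).  For the
    ICER outcome, a row is flagged ``sign_flip`` when the incremental cost or
    incremental effect changes sign between the two endpoints (or the ratio is
    undefined at either); the net-benefit outcome is the stable alternative in
    that case.
    """
    if outcome not in ("ICER", "iNMB"):
        raise ValueError(f"outcome must be 'ICER' or 'iNMB', got {outcome!r}")

    rows: list[TornadoRow] = []
    for b in bounds:
        if b.param_name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {b.param_name!r}; "
                             f"valid names: {', '.join(PARAM_NAMES)}")
        endpoints = []
        flip = False
        deltas = []
        for value in (b.low, b.high):
            ia, ca = _set_param(config.intervention, config.comparator,
                                b.param_name, value)
            val, undef = _evaluate(ia, ca, outcome, config.threshold, config.currency)
            res = compute_icer(ia, ca)
            deltas.append((res.delta_cost, res.delta_effect))
            flip = flip or undef
            endpoints.append(val)
        if outcome == "ICER":
            (dc_lo, de_lo), (dc_hi, de_hi) = deltas
            if dc_lo * dc_hi < 0 or de_lo * de_hi < 0:
                flip = True
        lo_val, hi_val = endpoints
        rng = abs(hi_val - lo_val)
        rows.append(TornadoRow(b.param_name, lo_val, hi_val, rng, outcome, flip))

    # stable sort keeps input order on ties
    rows.sort(key=lambda r: -r.range)
    return rows
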