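"""Study parameter types, currency arithmetic and configuration ingestion.

All monetary quantities are carried as floats at full precision internally;
rounding to two decimals (half-up) happens only in the reporting layer via
:func:`round2`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "CostItem",
    "CurrencySpec",
    "CostCorrection",
    "UtilityParam",
    "TimeHorizon",
    "Threshold",
    "StrategyArm",
    "PSASettings",
    "OWSASettings",
    "SimulateSettings",
    "AnalysisConfig",
    "ConfigError",
    "DoubleCorrectionError",
    "brl_to_usd",
    "usd_to_brl",
    "apply_cost_correction",
    "total_cost",
    "load_config",
    "read_cost_table",
    "write_cost_table",
    "round2",
    "threshold_in_usd",
]

SUPPORTED_CURRENCIES = ("BRL", "USD")

#: Column headers of the cost-table CSV interchange format.
COST_TABLE_COLUMNS = (
    "Type of Cost",
    "Type of Resources",
    "Units",
    "Monetary Values (USD)",
    "Sources of Information",
)


class ConfigError(ValueError):
    """Raised when a configuration fails validation.

    ``errors`` lists every offending field, not just the first one found.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


class DoubleCorrectionError(ValueError):
    """Raised when a cost correction would be applied to an already-corrected item."""


def round2(x: float) -> float:
    """Round to two decimals with half-up tie-breaking (presentation rule)."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CostItem:
    """One resource line of a cost table.

    ``unit_cost`` is the cost of one unit; the line total is
    ``unit_cost * n_units``.  ``corrected`` is a provenance flag: True means
    the administrative-price correction has already been applied (or does not
    apply), so re-applying it is a detectable error.
    """

    resource_label: str
    n_units: int
    unit_cost: float
    currency: str = "USD"
    source: str = ""
    period: str | None = None
    units_label: str | None = None
    cost_type: str | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        _require(int(self.n_units) == self.n_units and self.n_units >= 1,
                 f"n_units must be a positive integer, got {self.n_units!r}")
        _require(self.unit_cost >= 0, f"unit_cost must be >= 0, got {self.unit_cost!r}")
        _require(self.currency in SUPPORTED_CURRENCIES,
                 f"currency must be one of {SUPPORTED_CURRENCIES}, got {self.currency!r}")

    @property
    def line_total(self) -> float:
        return self.unit_cost * self.n_units


@dataclass(frozen=True)
class CurrencySpec:
    """Exchange rate between the two supported currencies."""

    brl_per_usd: float = 5.10

    def __post_init__(self) -> None:
        _require(self.brl_per_usd > 0, f"brl_per_usd must be > 0, got {self.brl_per_usd!r}")


@dataclass(frozen=True)
class CostCorrection:
    """Multiplicative correction for administrative procedure prices.

    Applied to items whose ``source`` is in ``applies_to`` (default the
    national procedure table, which under-reports true spending).
    """

    factor: float = 2.8
    applies_to: frozenset[str] = frozenset({"SIGTAP"})

    def __post_init__(self) -> None:
        _require(self.factor > 0, f"factor must be > 0, got {self.factor!r}")
        object.__setattr__(self, "applies_to", frozenset(self.applies_to))


@dataclass(frozen=True)
class UtilityParam:
    """Health-state preference weight and its decrement from baseline."""

    label: str
    utility: float
    disutility: float = 0.0
    setting: str = "ward"

    def __post_init__(self) -> None:
        _require(0.0 <= self.utility <= 1.0,
                 f"utility must be in [0, 1], got {self.utility!r}")
        _require(-1.0 <= self.disutility <= 0.0,
                 f"disutility must be in [-1, 0], got {self.disutility!r}")
        _require(self.setting in ("ward", "ICU"),
                 f"setting must be 'ward' or 'ICU', got {self.setting!r}")


@dataclass(frozen=True)
class TimeHorizon:
    """Analytic time horizon in weeks; ``weeks_per_year`` converts to years."""

    weeks: int = 12
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        _require(int(self.weeks) == self.weeks and self.weeks >= 1,
                 f"weeks must be a positive integer, got {self.weeks!r}")
        _require(self.weeks_per_year > 0,
                 f"weeks_per_year must be > 0, got {self.weeks_per_year!r}")

    @property
    def years(self) -> float:
        return self.weeks / self.weeks_per_year


@dataclass(frozen=True)
class Threshold:
    """Willingness-to-pay threshold per QALY."""

    value: float = 40_000.0
    currency: str = "BRL"
    per_unit: str = "QALY"

    def __post_init__(self) -> None:
        _require(self.value > 0, f"threshold value must be > 0, got {self.value!r}")
        _require(self.currency in SUPPORTED_CURRENCIES,
                 f"currency must be one of {SUPPORTED_CURRENCIES}, got {self.currency!r}")


@dataclass(frozen=True)
class StrategyArm:
    """A comparator arm summarized by mean cost (USD) and mean effect (QALY)."""

    name: str
    mean_cost: float
    mean_effect: float
    cost_se: float | None = None
    effect_se: float | None = None

    def __post_init__(self) -> None:
        _require(self.mean_cost >= 0, f"mean_cost must be >= 0, got {self.mean_cost!r}")
        _require(self.mean_effect >= 0, f"mean_effect must be >= 0, got {self.mean_effect!r}")
        if self.cost_se is not None:
            _require(self.cost_se >= 0, f"cost_se must be >= 0, got {self.cost_se!r}")
        if self.effect_se is not None:
            _require(self.effect_se >= 0, f"effect_se must be >= 0, got {self.effect_se!r}")


@dataclass(frozen=True)
class PSASettings:
    n_draws: int = 1000
    seed: int | None = None
    se_rule: float = 0.15  # default dispersion: se = fraction * mean

    def __post_init__(self) -> None:
        _require(self.n_draws >= 1, f"n_draws must be >= 1, got {self.n_draws!r}")
        _require(self.se_rule >= 0, f"se_rule must be >= 0, got {self.se_rule!r}")


@dataclass(frozen=True)
class OWSASettings:
    variation: float = 0.15
    #: explicit {param_name: [low, high]} bounds; overrides ``variation``
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(0 <= self.variation, f"variation must be >= 0, got {self.variation!r}")


@dataclass(frozen=True)
class SimulateSettings:
    """Arm sizes and moments for synthetic patient-level generation."""

    n_int: int = 25
    n_con: int = 27
    utility_mean_int: float = 0.724
    utility_mean_con: float = 0.693
    utility_se_int: float | None = None   # default: se_fraction * mean
    utility_se_con: float | None = None
    se_fraction: float = 0.15

    def __post_init__(self) -> None:
        _require(self.n_int >= 0 and self.n_con >= 0, "arm sizes must be >= 0")
        _require(self.n_int + self.n_con >= 1, "at least one patient required")


@dataclass(frozen=True)
class AnalysisConfig:
    """The full validated parameter set for one analysis."""

    intervention: StrategyArm
    comparator: StrategyArm
    cost_items: tuple[CostItem, ...] = ()
    utilities: tuple[UtilityParam, ...] = ()
    horizon: TimeHorizon = TimeHorizon()
    currency: CurrencySpec = CurrencySpec()
    correction: CostCorrection = CostCorrection()
    threshold: Threshold = Threshold()
    psa: PSASettings = PSASettings()
    owsa: OWSASettings = OWSASettings()
    simulate: SimulateSettings = SimulateSettings()


# ---------------------------------------------------------------------------
# currency / correction arithmetic
# ---------------------------------------------------------------------------

def brl_to_usd(amount: float, spec: CurrencySpec) -> float:
    """Convert a BRL amount to USD at ``spec.brl_per_usd``."""
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount!r}")
    return amount / spec.brl_per_usd


def usd_to_brl(amount: float, spec: CurrencySpec) -> float:
    """Exact inverse of :func:`brl_to_usd`."""
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount!r}")
    return amount * spec.brl_per_usd


def threshold_in_usd(thr: Threshold, fx: CurrencySpec) -> float:
    """Threshold value expressed in USD (costs are carried in USD)."""
    if thr.currency == "USD":
        return thr.value
    return brl_to_usd(thr.value, fx)


def apply_cost_correction(item: CostItem, corr: CostCorrection) -> CostItem:
    """Multiply ``unit_cost`` by the correction factor if the item's source is eligible.

    Items already flagged ``corrected`` raise :class:`DoubleCorrectionError` so
    the pipeline cannot silently apply the factor twice.  Non-eligible items
    pass through unchanged.
    """
    if item.source not in corr.applies_to:
        return item
    if item.corrected:
        raise DoubleCorrectionError(
            f"cost item {item.resource_label!r} is already corrected; "
            f"applying the factor again would scale it by {corr.factor}^2"
        )
    return replace(item, unit_cost=item.unit_cost * corr.factor, corrected=True)


def total_cost(items: list[CostItem], spec: CurrencySpec, corr: CostCorrection) -> float:
    """Sum of corrected line totals over all items, in USD.

    The correction is applied exactly once (items flagged ``corrected`` are
    taken as-is); BRL amounts are converted at ``spec``.
    """
    if not items:
        raise ValueError("total_cost requires a non-empty item list")
    total = 0.0
    for item in items:
        if not item.corrected and item.source in corr.applies_to:
            item = apply_cost_correction(item, corr)
        line = item.line_total
        if item.currency == "BRL":
            line = brl_to_usd(line, spec)
        total += line
    return total


# ---------------------------------------------------------------------------
# config ingestion
# ---------------------------------------------------------------------------

_ROLE_INTERVENTION = ("intervention", "int")
_ROLE_COMPARATOR = ("comparator", "control", "con")


def _build(cls, raw: dict[str, Any], where: str, errors: list[str]):
    """Construct a dataclass from a raw mapping, collecting per-field errors."""
    if not isinstance(raw, dict):
        errors.append(f"{where}: expected a mapping, got {type(raw).__name__}")
        return None
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known - {"role"}
    if unknown:
        errors.append(f"{where}: unknown field(s) {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    if cls is OWSASettings and "bounds" in kwargs:
        kwargs["bounds"] = {k: tuple(v) for k, v in kwargs["bounds"].items()}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{where}: {exc}")
        return None


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML/JSON analysis configuration.

    Every type invariant is checked; all violations are collected and raised
    together as a single :class:`ConfigError` naming the offending fields.
    Omitted sections fall back to their documented defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])

    errors: list[str] = []

    strategies = raw.get("strategies")
    intervention = comparator = None
    if not isinstance(strategies, list) or len(strategies) < 2:
        errors.append("strategies: exactly two strategy arms are required "
                      "(intervention and comparator)")
    else:
        arms: list[tuple[str | None, StrategyArm | None]] = []
        for i, entry in enumerate(strategies[:2]):
            role = None
            if isinstance(entry, dict):
                role = str(entry.get("role", "")).lower() or None
            arm = _build(StrategyArm, entry, f"strategies[{i}]", errors)
            arms.append((role, arm))
        roles = [r for r, _ in arms]
        if roles[0] in _ROLE_COMPARATOR or roles[1] in _ROLE_INTERVENTION:
            arms.reverse()
        intervention, comparator = arms[0][1], arms[1][1]

    cost_items = []
    for i, entry in enumerate(raw.get("cost_items", []) or []):
        item = _build(CostItem, entry, f"cost_items[{i}]", errors)
        if item is not None:
            cost_items.append(item)

    cost_csv = raw.get("cost_items_csv")
    if cost_csv:
        csv_path = Path(cost_csv)
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        try:
            cost_items.extend(read_cost_table(csv_path))
        except (OSError, ValueError) as exc:
            errors.append(f"cost_items_csv: {exc}")

    utilities = []
    for i, entry in enumerate(raw.get("utilities", []) or []):
        u = _build(UtilityParam, entry, f"utilities[{i}]", errors)
        if u is not None:
            utilities.append(u)

    horizon = _build(TimeHorizon, raw.get("horizon", {}), "horizon", errors)
    currency = _build(CurrencySpec, raw.get("currency", {}), "currency", errors)
    correction = _build(CostCorrection, raw.get("correction", {}), "correction", errors)
    threshold = _build(Threshold, raw.get("threshold", {}), "threshold", errors)
    psa = _build(PSASettings, raw.get("psa", {}), "psa", errors)
    owsa = _build(OWSASettings, raw.get("owsa", {}), "owsa", errors)
    simulate = _build(SimulateSettings, raw.get("simulate", {}), "simulate", errors)

    known_top = {"strategies", "cost_items", "cost_items_csv", "utilities", "horizon",
                 "currency", "correction", "threshold", "psa", "owsa", "simulate"}
    unknown_top = set(raw) - known_top
    if unknown_top:
        errors.append(f"unknown top-level section(s): {sorted(unknown_top)}")

    if errors:
        raise ConfigError(errors)

    return AnalysisConfig(
        intervention=intervention,
        comparator=comparator,
        cost_items=tuple(cost_items),
        utilities=tuple(utilities),
        horizon=horizon,
        currency=currency,
        correction=correction,
        threshold=threshold,
        psa=psa,
        owsa=owsa,
        simulate=simulate,
    )


# ---------------------------------------------------------------------------
# cost-table CSV interchange
# ---------------------------------------------------------------------------

def read_cost_table(path: str | Path) -> list[CostItem]:
    """Read cost items from a CSV whose headers follow :data:`COST_TABLE_COLUMNS`.

    The monetary column holds the USD line total for the printed quantity, so
    each row maps to one item with ``n_units=1`` and the printed quantity kept
    as descriptive text in ``units_label``.  Values are flagged ``corrected``:
    the table format carries final, already-converted totals.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        got = tuple(reader.fieldnames or ())
        if got != COST_TABLE_COLUMNS:
            raise ValueError(
                f"unexpected cost-table headers {got!r}; expected {COST_TABLE_COLUMNS!r}"
            )
        items = []
        for row in reader:
            items.append(CostItem(
                resource_label=row["Type of Resources"],
                n_units=1,
                unit_cost=float(row["Monetary Values (USD)"]),
                currency="USD",
                source=row["Sources of Information"],
                period=row["Units"] if "month" in row["Units"].lower() else None,
                units_label=row["Units"],
                cost_type=row["Type of Cost"],
                corrected=True,
            ))
    return items


def write_cost_table(items: list[CostItem], path: str | Path) -> None:
    """Write cost items in the CSV interchange format read by :func:`read_cost_table`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COST_TABLE_COLUMNS)
        for item in items:
            writer.writerow([
                item.cost_type or "",
                item.resource_label,
                item.units_label or str(item.n_units),
                repr(item.line_total) if item.line_total != int(item.line_total)
                else str(int(item.line_total)),
                item.source,
            ])
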