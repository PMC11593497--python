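"""ceutil: trial-based cost-utility analysis.

Deterministic incremental cost-effectiveness (ICER, dominance, net monetary
benefit), one-way sensitivity analysis with tornado ordering, seeded
Monte Carlo probabilistic sensitivity analysis with beta/gamma
method-of-moments fitting and CE-plane classification, acceptability curves,
and a synthetic two-arm trial generator.
"""

from importlib import resources

__version__ = "0.1.0"

from .deterministic import ICERResult, NMBResult, compute_icer, compute_inmb, compute_qaly
from .owsa import ParamBound, TornadoRow, make_bounds, run_owsa
from .parameters import (
    AnalysisConfig,
    ConfigError,
    CostCorrection,
    CostItem,
    CurrencySpec,
    StrategyArm,
    Threshold,
    TimeHorizon,
    UtilityParam,
    apply_cost_correction,
    brl_to_usd,
    load_config,
    read_cost_table,
    round2,
    total_cost,
    usd_to_brl,
)
from .psa import (
    DistributionSpec,
    PSADraw,
    PSAResult,
    classify_ce_plane,
    compute_ceac,
    fit_beta_moments,
    fit_gamma_moments,
    run_psa,
)
from .synthetic import (
    ArmEstimate,
    PatientRecord,
    estimate_arm_params,
    generate_cost_table,
    generate_trial,
)

__all__ = [
    "__version__",
    "AnalysisConfig", "ConfigError", "CostCorrection", "CostItem", "CurrencySpec",
    "StrategyArm", "Threshold", "TimeHorizon", "UtilityParam",
    "apply_cost_correction", "brl_to_usd", "usd_to_brl", "total_cost",
    "load_config", "read_cost_table", "round2",
    "ICERResult", "NMBResult", "compute_icer", "compute_inmb", "compute_qaly",
    "ParamBound", "TornadoRow", "make_bounds", "run_owsa",
    "DistributionSpec", "PSADraw", "PSAResult", "classify_ce_plane",
    "compute_ceac", "fit_beta_moments", "fit_gamma_moments", "run_psa",
    "ArmEstimate", "PatientRecord", "estimate_arm_params",
    "generate_cost_table", "generate_trial",
    "base_case_config_path", "cost_table_path",
]


def base_case_config_path() -> str:
    """Path to the packaged base-case configuration fixture."""
    return str(resources.files("ceutil").joinpath("data", "base_case.yaml"))


def cost_table_path() -> str:
    """Path to the packaged resource-cost table fixture (CSV)."""
    return str(resources.files("ceutil").joinpath("data", "resource_costs.csv"))
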