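"""medlongsim: mediated longitudinal data — latent growth SEMs vs linear
mixed models, with a Monte-Carlo study harness.

The package simulates cohorts in which a binary baseline exposure affects
six repeated continuous outcomes both directly and through a continuous
baseline mediator, fits the mediated latent growth curve SEM and random
intercept/slope linear mixed models (with and without the mediator) by
maximum likelihood, and evaluates total-effect bias, coverage and power
across sample sizes, effect sizes and non-normal error regimes.
"""

from .parameters import (
    SEMParameters,
    EffectTarget,
    EFFECT_SIZES,
    latent_moments,
    implied_outcome_moments,
    total_effect,
    effect_size,
    calibrate_effects,
)
from .distributions import (
    ErrorSpec,
    FLEISHMAN_PRESETS,
    LOGNORMAL_LOG_VARIANCE,
    fleishman_coefficients,
    lognormal_log_variance,
    mattson_intermediate_corr,
    draw_errors,
)
from .datasets import TrialDataset, simulate_dataset, write_dataset, read_dataset
from .inference import delta_total_effect, wald_summary, FitStats, rmsea
from .lmm import GrowthCurveLMM, LMMResults
from .sem import MediatedGrowthSEM, SEMResults, fit_sem
from .study import (
    ScenarioConfig,
    MetricsRow,
    evaluate_scenario,
    mc_ci_width,
    reproduce_table,
)


def fit_lmm(ds, include_mediator: bool = False, include_interaction: bool = False):
    """Fit a random intercept/slope LMM (LMM1 with mediator, LMM2 without)."""
    return GrowthCurveLMM(ds, include_mediator, include_interaction).fit()


__version__ = "0.1.0"

__all__ = [
    "SEMParameters", "EffectTarget", "EFFECT_SIZES",
    "latent_moments", "implied_outcome_moments", "total_effect",
    "effect_size", "calibrate_effects",
    "ErrorSpec", "FLEISHMAN_PRESETS", "LOGNORMAL_LOG_VARIANCE",
    "fleishman_coefficients", "lognormal_log_variance",
    "mattson_intermediate_corr", "draw_errors",
    "TrialDataset", "simulate_dataset", "write_dataset", "read_dataset",
    "delta_total_effect", "wald_summary", "FitStats",
    "GrowthCurveLMM", "LMMResults",
    "MediatedGrowthSEM", "SEMResults", "fit_sem", "fit_lmm",
    "ScenarioConfig", "MetricsRow", "evaluate_scenario",
    "mc_ci_width", "reproduce_table",
]
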