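"""Monte-Carlo evaluation of bias, coverage and power across scenarios.

One scenario fixes a sample size, a standardized effect target, an error
regime and a set of models; :func:`evaluate_scenario` simulates replicate
cohorts, fits each model, and summarizes the total-effect estimates:

* relative bias (%) = 100 * (mean estimate - truth) / truth
* coverage (%) = share of nominal 95% Wald CIs containing the truth
* power (%) = share of two-sided Wald tests rejecting zero at alpha

Replicates that fail to converge are excluded from the metrics and counted.
:func:`reproduce_table` runs the canonical scenario grids (sample-size
sweep, effect-size-by-split grid, error-regime sweep).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import simulate_dataset
from .distributions import ErrorSpec
from .lmm import GrowthCurveLMM
from .parameters import (
    EFFECT_SIZES,
    EffectTarget,
    SEMParameters,
    calibrate_effects,
    total_effect,
)
from .sem import MediatedGrowthSEM

__all__ = ["ScenarioConfig", "MetricsRow", "evaluate_scenario",
           "mc_ci_width", "reproduce_table"]

logger = logging.getLogger(__name__)

MODEL_TAGS = ("SEM", "LMM1", "LMM2")


@dataclass
class ScenarioConfig:
    """One cell of the simulation study."""

    n_subjects: int
    target: EffectTarget = field(
        default_factory=lambda: EffectTarget(0.5, "equal", "intercept"))
    error_spec: ErrorSpec = field(default_factory=ErrorSpec)
    models: tuple[str, ...] = MODEL_TAGS
    reps: int = 1000
    base_seed: int = 0
    alpha: float = 0.05
    params_base: SEMParameters = field(default_factory=SEMParameters)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.models) - set(MODEL_TAGS)
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}")

    @property
    def component(self) -> str:
        return self.target.component


@dataclass
class MetricsRow:
    """Performance of one model in one scenario (one table row)."""

    model_tag: str
    bias_pct: float
    coverage_pct: float
    power_pct: float
    n_converged: int
    reps: int
    mean_se: float
    mean_estimate: float
    sd_estimate: float
    truth: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mc_ci_width(p: float, reps: int) -> float:
    """Width (percentage points) of a 95% CI around a proportion estimated
    from ``reps`` Monte-Carlo replicates: 200 * 1.96 * sqrt(p(1-p)/reps)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    z = norm.ppf(0.975)
    return float(100.0 * 2.0 * z * np.sqrt(p * (1.0 - p) / reps))


def _fit_one(tag: str, ds, component: str, alpha: float):
    """Return (estimate, se, converged) of the total-effect estimand."""
    interaction = component == "slope"
    if tag == "SEM":
        res = MediatedGrowthSEM(ds).fit()
        if not res.converged:
            return np.nan, np.nan, False
        est, se = res.total_effect(component)
        return est, se, True
    lmm = GrowthCurveLMM(ds, include_mediator=(tag == "LMM1"),
                         include_interaction=interaction)
    res = lmm.fit()
    if not res.converged:
        return np.nan, np.nan, False
    return res.total_effect_estimate, res.total_effect_se, True


def evaluate_scenario(cfg: ScenarioConfig) -> list[MetricsRow]:
    """Run the replicates of one scenario and summarize each model."""
    params = calibrate_effects(cfg.target, cfg.params_base)
    truth = total_effect(params, cfg.component)
    zcrit = norm.ppf(1.0 - cfg.alpha / 2.0)

    est = {m: [] for m in cfg.models}
    se = {m: [] for m in cfg.models}
    for i in range(cfg.reps):
        seed = int((cfg.base_seed + i) % 2**31)
        ds = simulate_dataset(params, cfg.n_subjects, cfg.error_spec, seed)
        for tag in cfg.models:
            e, s, ok = _fit_one(tag, ds, cfg.component, cfg.alpha)
            if ok and np.isfinite(e) and np.isfinite(s) and s > 0:
                est[tag].append(e)
                se[tag].append(s)
            else:
                logger.info("replicate %d: %s did not converge", i, tag)

    rows = []
    for tag in cfg.models:
        e = np.asarray(est[tag])
        s = np.asarray(se[tag])
        if e.size == 0:
            raise RuntimeError(
                f"all {cfg.reps} replicates failed to converge for {tag} "
                f"(n={cfg.n_subjects}, effect={cfg.target})"
            )
        covered = np.abs(e - truth) <= zcrit * s
        rejected = np.abs(e / s) > zcrit
        rows.append(MetricsRow(
            model_tag=tag,
            bias_pct=float(100.0 * (e.mean() - truth) / truth),
            coverage_pct=float(100.0 * covered.mean()),
            power_pct=float(100.0 * rejected.mean()),
            n_converged=int(e.size),
            reps=cfg.reps,
            mean_se=float(s.mean()),
            mean_estimate=float(e.mean()),
            sd_estimate=float(e.std(ddof=1)) if e.size > 1 else 0.0,
            truth=float(truth),
        ))
    return rows


# ---------------------------------------------------------------------------
# Canonical scenario grids
# ---------------------------------------------------------------------------

T1_SAMPLE_SIZES = (25, 50, 100, 200, 250, 500)
T2_GRID = [(es, split) for es in ("large", "medium", "medium_small", "small")
           for split in ("equal", "direct", "indirect")]
T3_REGIMES = [
    ("uniform", "measurement_only"),
    ("uniform", "measurement_and_structural"),
    ("lognormal", "measurement_only"),
    ("lognormal", "measurement_and_structural"),
    ("contaminated", "measurement_only"),
    ("contaminated", "measurement_and_structural"),
    ("fleishman1", "measurement_and_structural"),
    ("fleishman2", "measurement_and_structural"),
]


def reproduce_table(
    table_id: str,
    reps: int = 1000,
    base_seed: int = 0,
    out_path=None,
    params_base: SEMParameters | None = None,
) -> pd.DataFrame:
    """Rebuild one of the canonical result tables as a DataFrame.

    T1: sample-size sweep (medium effect, equal split, all three models).
    T2: effect size x split grid at n=250 (SEM and LMM2).
    T3: error-regime sweep at n=250, medium-small equal split.
    An effect-size cell whose split geometry cannot reach the target with
    the base parameters is reported with NaN metrics and a note.
    """
    params_base = params_base or SEMParameters()
    records: list[dict] = []

    def run(cfg: ScenarioConfig, keys: dict) -> None:
        try:
            rows = evaluate_scenario(cfg)
        except ValueError as exc:  # infeasible calibration
            warnings.warn(f"scenario {keys} skipped: {exc}", RuntimeWarning,
                          stacklevel=2)
            records.append({**keys, "model_tag": None, "note": str(exc)})
            return
        for row in rows:
            records.append({**keys, **row.to_dict(), "base_seed": cfg.base_seed,
                            "note": ""})

    if table_id == "T1":
        for j, n in enumerate(T1_SAMPLE_SIZES):
            cfg = ScenarioConfig(
                n_subjects=n, reps=reps, base_seed=base_seed + j * reps,
                params_base=params_base,
                target=EffectTarget(EFFECT_SIZES["medium"], "equal"),
            )
            run(cfg, {"n_subjects": n})
    elif table_id == "T2":
        for j, (es, split) in enumerate(T2_GRID):
            cfg = ScenarioConfig(
                n_subjects=250, reps=reps, base_seed=base_seed + j * reps,
                params_base=params_base, models=("SEM", "LMM2"),
                target=EffectTarget(EFFECT_SIZES[es], split),
            )
            run(cfg, {"effect_size": es, "split": split})
    elif table_id == "T3":
        for j, (family, level) in enumerate(T3_REGIMES):
            cfg = ScenarioConfig(
                n_subjects=250, reps=reps, base_seed=base_seed + j * reps,
                params_base=params_base, models=("SEM", "LMM2"),
                target=EffectTarget(EFFECT_SIZES["medium_small"], "equal"),
                error_spec=ErrorSpec(family=family, level=level),
            )
            run(cfg, {"family": family, "level": level})
    else:
        raise ValueError(f"unknown table id {table_id!r}")

    df = pd.DataFrame.from_records(records)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
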