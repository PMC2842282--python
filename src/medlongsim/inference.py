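"""Delta-method total-effect inference, Wald summaries and fit indices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

__all__ = ["delta_total_effect", "wald_summary", "WaldSummary", "FitStats",
           "rmsea"]


def rmsea(chi_square: float, df: int, n_subjects: int) -> float:
    """Root mean square error of approximation:
    sqrt(max(chi2 - df, 0) / (df * (N - 1)))."""
    if df <= 0 or n_subjects < 2:
        raise ValueError("need df > 0 and at least 2 subjects")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n_subjects - 1))))


def delta_total_effect(
    estimates: dict[str, float],
    vcov: np.ndarray,
    names: list[str],
    component: str = "intercept",
) -> tuple[float, float]:
    """Point estimate and delta-method SE of the exposure's total effect.

    Total effect = direct + mediated*exposure->mediator, i.e.
    gamma13 + b13*gamma33 (intercept) or gamma23 + b23*gamma33 (slope);
    the gradient is (1, gamma33, b) so se = sqrt(g' V g).
    """
    if component == "intercept":
        keys = ("gamma13", "b13", "gamma33")
    elif component == "slope":
        keys = ("gamma23", "b23", "gamma33")
    else:
        raise ValueError(f"unknown component {component!r}")
    missing = [k for k in keys if k not in names]
    if missing:
        raise ValueError(f"vcov does not cover coefficients {missing}")
    g_dir, b, g_med = (estimates[k] for k in keys)
    est = g_dir + b * g_med
    idx = [names.index(k) for k in keys]
    V = np.asarray(vcov)[np.ix_(idx, idx)]
    grad = np.array([1.0, g_med, b])
    se = float(np.sqrt(grad @ V @ grad))
    return float(est), se


class WaldSummary(NamedTuple):
    ci_low: float
    ci_high: float
    z: float
    p: float
    reject: bool


def wald_summary(
    estimate: float, se: float, level: float = 0.95, null: float = 0.0
) -> WaldSummary:
    """Two-sided normal-theory CI and test of ``estimate`` against ``null``."""
    if se <= 0:
        raise ValueError("se must be positive")
    zcrit = norm.ppf(0.5 * (1.0 + level))
    z = (estimate - null) / se
    p = 2.0 * norm.sf(abs(z))
    return WaldSummary(
        ci_low=estimate - zcrit * se,
        ci_high=estimate + zcrit * se,
        z=z,
        p=p,
        reject=bool(p < 1.0 - level),
    )


@dataclass
class FitStats:
    """Goodness-of-fit battery.

    For the SEM: chi-square against a saturated reference (free mean
    coefficients on (1, z1, z2) for each of the 7 outcomes, unstructured
    7x7 covariance), RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1))) and SRMR
    (root mean square of moment residuals standardized by saturated SDs).
    LMMs report only the likelihood-based indices.
    """

    aic: float
    bic: float
    neg2loglik: float
    chi_square: float | None = None
    df: int | None = None
    rmsea: float | None = None
    srmr: float | None = None

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square, "df": self.df,
            "rmsea": self.rmsea, "srmr": self.srmr,
            "aic": self.aic, "bic": self.bic,
            "neg2loglik": self.neg2loglik,
        }
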