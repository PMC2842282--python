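"""Non-normal residual error generators.

Six regimes for the residual errors of the measurement and/or structural
model, each standardized to mean zero and (except the contaminated normal,
deliberately) the target variance:

* ``normal`` — multivariate normal with the target covariance.
* ``uniform`` — Uniform(-sqrt(3), sqrt(3)), unit variance, scaled.
* ``lognormal`` — centered lognormal with log-scale variance 0.4812, the
  root of (e^s - 1) e^s = 1, so the centered variate has unit variance.
* ``contaminated`` — scale mixture: standard normal w.p. 0.6, normal with
  SD 10 w.p. 0.4.  Its variance (40.4 per unit of target variance) is NOT
  rescaled; the regime exists to stress estimators with gross outliers.
* ``fleishman1`` / ``fleishman2`` — Fleishman power-method transforms of a
  standard normal hitting preset (skewness, excess kurtosis) targets, with
  the intermediate ("Mattson") correlation adjusted so cross-correlations
  of the transformed streams match the target covariance.

Correlated non-Gaussian streams use a Gaussian-copula intermediate
correlation: exact polynomial root for Fleishman marginals, exact closed
forms for uniform (rho = 2 sin(pi r / 6)) and lognormal marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.optimize import brentq, root

__all__ = [
    "ErrorSpec",
    "LOGNORMAL_LOG_VARIANCE",
    "lognormal_log_variance",
    "fleishman_coefficients",
    "mattson_intermediate_corr",
    "draw_errors",
    "FLEISHMAN_PRESETS",
]

Family = Literal["normal", "uniform", "lognormal", "contaminated",
                 "fleishman1", "fleishman2"]
Level = Literal["measurement_only", "measurement_and_structural"]

# Preset (skewness, excess kurtosis) targets for the two Fleishman regimes:
# one pair for the measurement errors, three pairs for the structural
# residual streams (latent intercept, slope, mediator).  Regime 1's
# structural kurtoses are infeasible as stated (excess kurtosis -3 is below
# the universal minimum of -2, and the Fleishman family is narrower still);
# the solver clamps them to the feasible boundary with a warning.
FLEISHMAN_PRESETS: dict[str, dict[str, list[tuple[float, float]]]] = {
    "fleishman1": {
        "measurement": [(0.75, 0.0)],
        "structural": [(0.53, -1.5), (0.5, -1.9), (0.75, -3.0)],
    },
    "fleishman2": {
        "measurement": [(1.75, 3.75)],
        "structural": [(1.2, 0.4), (1.4, 0.5), (1.8, 0.8)],
    },
}


def lognormal_log_variance() -> float:
    """Log-scale variance s with (e^s - 1) e^s = 1: s = ln((1+sqrt(5))/2)."""
    return float(np.log((1.0 + np.sqrt(5.0)) / 2.0))


LOGNORMAL_LOG_VARIANCE = lognormal_log_variance()  # 0.4812...


@dataclass
class ErrorSpec:
    """Which distribution generates residual errors, and where it applies.

    ``level`` selects whether only the measurement-model errors are
    non-normal or the structural residuals as well.  The contamination
    parameters follow the gross-error mixture reading in which the
    contaminating component has SD ``contamination_scale``; set
    ``contamination_variance_is_sd_squared=False`` to read the scale as a
    variance instead.
    """

    family: Family = "normal"
    level: Level = "measurement_and_structural"
    contamination_prob: float = 0.4
    contamination_scale: float = 10.0
    contamination_variance_is_sd_squared: bool = True
    skewness: float | None = None
    excess_kurtosis: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform", "lognormal",
                               "contaminated", "fleishman1", "fleishman2"):
            raise ValueError(f"unknown error family {self.family!r}")
        if self.level not in ("measurement_only", "measurement_and_structural"):
            raise ValueError(f"unknown level {self.level!r}")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ValueError("contamination_prob must be in [0, 1]")

    @property
    def contaminant_sd(self) -> float:
        if self.contamination_variance_is_sd_squared:
            return self.contamination_scale
        return float(np.sqrt(self.contamination_scale))

    def structural_is_nonnormal(self) -> bool:
        return (self.family != "normal"
                and self.level == "measurement_and_structural")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# Fleishman power method
# ---------------------------------------------------------------------------

def _fleishman_system(bcd: np.ndarray, skew: float, ekurt: float) -> np.ndarray:
    b, c, d = bcd
    f1 = b**2 + 6*b*d + 2*c**2 + 15*d**2 - 1.0
    f2 = 2*c*(b**2 + 24*b*d + 105*d**2 + 2.0) - skew
    f3 = 24*(b*d + c**2*(1 + b**2 + 28*b*d)
             + d**2*(12 + 48*b*d + 141*c**2 + 225*d**2)) - ekurt
    return np.array([f1, f2, f3])


def _try_solve_fleishman(skew: float, ekurt: float) -> np.ndarray | None:
    starts = [
        np.array([1.0, 0.0, 0.0]),
        np.array([0.9, 0.15 * np.sign(skew) if skew else 0.0, 0.03]),
        np.array([1.1, 0.1 * np.sign(skew) if skew else 0.0, -0.05]),
        np.array([0.7, 0.3 * np.sign(skew) if skew else 0.1, 0.1]),
    ]
    for x0 in starts:
        sol = root(_fleishman_system, x0, args=(skew, ekurt),
                   method="hybr", tol=1e-14)
        if sol.success:
            res = _fleishman_system(sol.x, skew, ekurt)
            if np.max(np.abs(res)) < 1e-10 and sol.x[0] > 0:
                return sol.x
    return None


def fleishman_coefficients(
    skewness: float, excess_kurtosis: float, *, clamp: bool = False
) -> tuple[float, float, float, float]:
    """Solve for (a, b, c, d) with Y = a + bZ + cZ^2 + dZ^3, Z ~ N(0,1).

    The returned polynomial gives Y mean 0, variance 1 and the requested
    skewness and excess kurtosis (a = -c enforces the zero mean).  With
    ``clamp=True`` an infeasible kurtosis is raised to the boundary of the
    Fleishman-feasible region (a warning records the substitution);
    otherwise infeasibility raises ``ValueError``.
    """
    bcd = _try_solve_fleishman(skewness, excess_kurtosis)
    if bcd is None:
        if not clamp:
            raise ValueError(
                f"(skewness={skewness}, excess_kurtosis={excess_kurtosis}) "
                "is outside the Fleishman-feasible region"
            )
        # walk kurtosis upward to the feasible boundary
        k = excess_kurtosis
        step = 0.25
        for _ in range(200):
            k += step
            bcd = _try_solve_fleishman(skewness, k)
            if bcd is not None:
                break
        else:
            raise ValueError(
                f"no feasible kurtosis found above {excess_kurtosis} "
                f"for skewness {skewness}"
            )
        # bisect back toward the boundary for a tight clamp
        lo, hi = k - step, k
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            trial = _try_solve_fleishman(skewness, mid)
            if trial is None:
                lo = mid
            else:
                hi, bcd = mid, trial
        warnings.warn(
            f"excess kurtosis {excess_kurtosis} infeasible for skewness "
            f"{skewness}; clamped to {hi:.4f}",
            RuntimeWarning,
            stacklevel=2,
        )
    b, c, d = bcd
    return (-c, float(b), float(c), float(d))


def mattson_intermediate_corr(
    target_corr: float,
    coeffs_i: tuple[float, float, float, float],
    coeffs_j: tuple[float, float, float, float],
) -> float:
    """Intermediate normal correlation reproducing ``target_corr`` after the
    power-method transform of each margin.

    Solves r = rho(b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
              + rho^2 (2 c_i c_j) + rho^3 (6 d_i d_j)
    for the unique real rho in (-1, 1).
    """
    if not abs(target_corr) < 1.0:
        raise ValueError("|target_corr| must be < 1")
    _, bi, ci, di = coeffs_i
    _, bj, cj, dj = coeffs_j

    k1 = bi*bj + 3*bi*dj + 3*di*bj + 9*di*dj
    k2 = 2*ci*cj
    k3 = 6*di*dj

    def f(rho: float) -> float:
        return k1*rho + k2*rho**2 + k3*rho**3 - target_corr

    if target_corr == 0.0 and k2 == 0.0:
        return 0.0
    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"target correlation {target_corr} not attainable for these "
            "power-method marginals"
        )
    return float(brentq(f, lo, hi, xtol=1e-14))


# ---------------------------------------------------------------------------
# Drawing residual errors
# ---------------------------------------------------------------------------

def _cov_to_corr(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return sd, corr


def _gaussian_copula_normals(
    corr_z: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    # eigenvalue clip guards tiny negative drift from the rho inversion
    w, v = np.linalg.eigh(corr_z)
    w = np.clip(w, 0.0, None)
    root_ = v * np.sqrt(w)
    return rng.standard_normal((n, corr_z.shape[0])) @ root_.T


def draw_errors(
    spec: ErrorSpec,
    n: int,
    target_cov: np.ndarray,
    seed: int | np.random.Generator,
    *,
    stream: Literal["measurement", "structural"] = "measurement",
) -> np.ndarray:
    """Draw ``n`` residual vectors with mean 0 and covariance ``target_cov``.

    ``stream`` selects the preset parameter bundle for the Fleishman
    regimes (the measurement and structural errors use different skewness/
    kurtosis targets).  For the contaminated regime the realized variance
    is the inflated mixture value (not rescaled); structural contaminated
    streams share one per-draw contamination indicator so their
    cross-correlations survive the inflation.
    """
    target_cov = np.asarray(target_cov, dtype=float)
    if target_cov.ndim != 2 or target_cov.shape[0] != target_cov.shape[1]:
        raise ValueError("target_cov must be a square matrix")
    if np.min(np.linalg.eigvalsh(0.5 * (target_cov + target_cov.T))) < -1e-10:
        raise ValueError("target_cov must be positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = target_cov.shape[0]
    sd, corr = _cov_to_corr(target_cov)

    if spec.family == "normal":
        w, v = np.linalg.eigh(0.5 * (target_cov + target_cov.T))
        root_ = v * np.sqrt(np.clip(w, 0.0, None))
        return rng.standard_normal((n, k)) @ root_.T

    if spec.family == "uniform":
        if np.allclose(corr, np.eye(k)):
            u = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n, k))
        else:
            rho_z = 2.0 * np.sin(np.pi * corr / 6.0)
            np.fill_diagonal(rho_z, 1.0)
            z = _gaussian_copula_normals(rho_z, n, rng)
            from scipy.stats import norm
            u = (norm.cdf(z) - 0.5) * (2.0 * np.sqrt(3.0))
        return u * sd

    if spec.family == "lognormal":
        s = LOGNORMAL_LOG_VARIANCE
        center = np.exp(s / 2.0)
        if np.allclose(corr, np.eye(k)):
            z = rng.standard_normal((n, k))
        else:
            # bivariate lognormal: corr = (e^{rho s}-1)/(e^s-1)
            with np.errstate(invalid="ignore"):
                rho_z = np.log1p(corr * np.expm1(s)) / s
            np.fill_diagonal(rho_z, 1.0)
            z = _gaussian_copula_normals(rho_z, n, rng)
        u = np.exp(np.sqrt(s) * z) - center
        return u * sd

    if spec.family == "contaminated":
        z = _gaussian_copula_normals(corr, n, rng)
        if stream == "structural":
            ind = rng.random(n) < spec.contamination_prob  # shared per draw
            scale = np.where(ind, spec.contaminant_sd, 1.0)[:, None]
        else:
            ind = rng.random((n, k)) < spec.contamination_prob
            scale = np.where(ind, spec.contaminant_sd, 1.0)
        return z * scale * sd

    # Fleishman presets
    presets = FLEISHMAN_PRESETS[spec.family][stream]
    if len(presets) == 1 and k > 1:
        presets = presets * k
    if len(presets) < k:
        raise ValueError(
            f"{spec.family} has {len(presets)} {stream} presets but "
            f"{k} streams were requested"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coeffs = [fleishman_coefficients(s_, k_, clamp=True)
                  for (s_, k_) in presets[:k]]
    if np.allclose(corr, np.eye(k)):
        z = rng.standard_normal((n, k))
    else:
        rho_z = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                if corr[i, j] != 0.0:
                    rho_z[i, j] = rho_z[j, i] = mattson_intermediate_corr(
                        corr[i, j], coeffs[i], coeffs[j]
                    )
        z = _gaussian_copula_normals(rho_z, n, rng)
    out = np.empty_like(z)
    for i, (a, b, c, d) in enumerate(coeffs):
        zi = z[:, i]
        out[:, i] = a + b*zi + c*zi**2 + d*zi**3
    return out * sd
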