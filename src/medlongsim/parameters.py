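"""Parameterization of the mediated latent growth curve model.

The data-generating model is a structural equation model (SEM) with three
latent variables: a latent intercept ``U1`` and latent slope ``U2`` driving
six repeated outcomes ``Y1..Y6`` through fixed time scores, and a latent
mediator ``U3`` that is measured without error by a single indicator ``x``.
Two observed covariates enter the structural model: a continuous covariate
``z1`` (e.g. age) and a binary exposure ``z2`` (e.g. heavy alcohol use).

Structural model::

    U3 = alpha3 + gamma31*z1 + gamma33*z2                     + zeta3
    U1 = alpha1 + gamma11*z1 + gamma13*z2 + b13*U3 + zeta1
    U2 = alpha2 + gamma21*z1 + gamma23*z2 + b23*U3 + zeta2

Measurement model::

    Y_j = U1 + t_j * U2 + eps_j      (j = 1..6),   x = U3

The exposure's total effect on the latent intercept decomposes into a
direct path ``gamma13`` and an indirect path ``b13*gamma33`` through the
mediator; the slope analogue is ``gamma23 + b23*gamma33``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SEMParameters",
    "EffectTarget",
    "latent_moments",
    "implied_outcome_moments",
    "total_effect",
    "effect_size",
    "calibrate_effects",
]

Component = Literal["intercept", "slope"]
Split = Literal["equal", "direct", "indirect"]

_PSD_TOL = 1e-10


def _default_psi() -> np.ndarray:
    # psi11 = 1, psi22 = 0.25, corr(zeta1, zeta2) = 0.3, psi33 = 1
    psi = np.diag([1.0, 0.25, 1.0])
    psi[0, 1] = psi[1, 0] = 0.3 * np.sqrt(1.0 * 0.25)
    return psi


@dataclass
class SEMParameters:
    """Coefficients and variance components of the mediated growth model.

    Defaults give unit-scale variance components so that the non-normal
    error regimes (all standardized to variance one) plug in directly.
    """

    times: np.ndarray = field(default_factory=lambda: np.arange(6.0))
    b13: float = 0.0
    b23: float = 0.0
    gamma11: float = 0.2
    gamma21: float = 0.2
    gamma31: float = 0.2
    gamma13: float = 0.0
    gamma23: float = 0.0
    gamma33: float = 0.5
    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha3: float = 0.0
    psi: np.ndarray = field(default_factory=_default_psi)
    sigma2: float = 1.0
    z1_dist: str = "normal"
    z2_prev: float = 0.5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.shape != (6,):
            raise ValueError("times must have length 6")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.psi.shape != (3, 3):
            raise ValueError("psi must be 3x3")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.psi)) < -_PSD_TOL:
            raise ValueError("psi must be positive semi-definite")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if not 0.0 <= self.z2_prev <= 1.0:
            raise ValueError("z2_prev must be in [0, 1]")

    # -- structural matrices -------------------------------------------------

    @property
    def B(self) -> np.ndarray:
        """Latent-on-latent coefficients; only U3 -> (U1, U2) paths."""
        B = np.zeros((3, 3))
        B[0, 2] = self.b13
        B[1, 2] = self.b23
        return B

    @property
    def Gamma(self) -> np.ndarray:
        """Covariate coefficients, rows (U1, U2, U3), columns (z1, z2)."""
        return np.array(
            [
                [self.gamma11, self.gamma13],
                [self.gamma21, self.gamma23],
                [self.gamma31, self.gamma33],
            ]
        )

    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3])

    @property
    def Lambda(self) -> np.ndarray:
        """Loadings of (Y1..Y6, x) on (U1, U2, U3): growth scores + unit x."""
        lam = np.zeros((7, 3))
        lam[:6, 0] = 1.0
        lam[:6, 1] = self.times
        lam[6, 2] = 1.0
        return lam

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "b13", "b23",
                "gamma11", "gamma21", "gamma31",
                "gamma13", "gamma23", "gamma33",
                "alpha1", "alpha2", "alpha3",
                "sigma2", "z1_dist", "z2_prev",
            )
        }
        d["times"] = self.times.tolist()
        d["psi11"] = float(self.psi[0, 0])
        d["psi12"] = float(self.psi[0, 1])
        d["psi22"] = float(self.psi[1, 1])
        d["psi33"] = float(self.psi[2, 2])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SEMParameters":
        d = dict(d)
        psi = _default_psi()
        for (i, j), key in [((0, 0), "psi11"), ((0, 1), "psi12"),
                            ((1, 1), "psi22"), ((2, 2), "psi33")]:
            if key in d:
                psi[i, j] = psi[j, i] = float(d.pop(key))
        kwargs = {k: d[k] for k in d if k != "psi"}
        if "psi" in d:
            kwargs["psi"] = np.asarray(d["psi"], dtype=float)
        else:
            kwargs["psi"] = psi
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SEMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EffectTarget:
    """A standardized effect-size target for the exposure's total effect.

    ``split`` says how the total divides into direct and indirect paths:
    ``equal`` (half each), ``direct`` / ``indirect`` (a fraction ``w`` of
    the total, default 0.8, on the named path).
    """

    effect_size: float
    split: Split = "equal"
    component: Component = "intercept"
    w: float = 0.8

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.split not in ("equal", "direct", "indirect"):
            raise ValueError(f"unknown split {self.split!r}")
        if self.component not in ("intercept", "slope"):
            raise ValueError(f"unknown component {self.component!r}")
        if not 0.5 <= self.w <= 1.0:
            raise ValueError("w must lie in [0.5, 1]")


# Conventional standardized effect sizes; "medium_small" is a repo default
# (never quantified in the literature this study follows).
EFFECT_SIZES = {"small": 0.2, "medium_small": 0.35, "medium": 0.5, "large": 0.8}


def latent_moments(
    params: SEMParameters, z1: float, z2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of (U1, U2, U3) given covariates.

    Solves the structural model: mean = (I-B)^-1 (alpha + Gamma z),
    covariance = (I-B)^-1 Psi (I-B)^-T.  B is strictly triangular in the
    latent ordering, so (I-B) is always invertible.
    """
    z = np.array([z1, z2], dtype=float)
    inv = np.linalg.inv(np.eye(3) - params.B)
    mean = inv @ (params.alpha + params.Gamma @ z)
    cov = inv @ params.psi @ inv.T
    return mean, 0.5 * (cov + cov.T)


def implied_outcome_moments(
    params: SEMParameters, z1: float, z2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (length 7) and covariance (7x7) of (Y1..Y6, x).

    E[Y_j] = E[U1] + t_j E[U2];  Cov(Y_j, Y_k) = Var(U1)
    + (t_j+t_k) Cov(U1,U2) + t_j t_k Var(U2) + 1{j=k} sigma2.  The x row
    carries the latent-mediator moments (x = U3 exactly).
    """
    lmean, lcov = latent_moments(params, z1, z2)
    lam = params.Lambda
    mean = lam @ lmean
    cov = lam @ lcov @ lam.T
    cov[np.arange(6), np.arange(6)] += params.sigma2
    return mean, 0.5 * (cov + cov.T)


def total_effect(params: SEMParameters, component: Component = "intercept") -> float:
    """Direct plus indirect effect of the exposure on the named component."""
    if component == "intercept":
        return params.gamma13 + params.b13 * params.gamma33
    if component == "slope":
        return params.gamma23 + params.b23 * params.gamma33
    raise ValueError(f"unknown component {component!r}")


def _sd_total(params: SEMParameters, component: Component) -> float:
    """Marginal latent SD induced by the mediator path plus structural residual."""
    if component == "intercept":
        v = params.b13**2 * params.psi[2, 2] + params.psi[0, 0]
    elif component == "slope":
        v = params.b23**2 * params.psi[2, 2] + params.psi[1, 1]
    else:
        raise ValueError(f"unknown component {component!r}")
    return float(np.sqrt(v))


def effect_size(params: SEMParameters, component: Component = "intercept") -> float:
    """Standardized total effect: total effect / total latent SD (Cohen's-d-like)."""
    sd = _sd_total(params, component)
    if sd <= 0:
        raise ValueError("total latent standard deviation must be positive")
    return total_effect(params, component) / sd


def calibrate_effects(
    target: EffectTarget, params_base: SEMParameters
) -> SEMParameters:
    """Choose path coefficients so the standardized effect hits the target.

    Holds gamma33, Psi, sigma2 and the time scores fixed at their values in
    ``params_base`` and solves for the (direct, mediated) coefficients of the
    targeted component.  Because the mediated coefficient also inflates the
    total latent SD in the denominator, the total effect c solves

        target = c / sqrt((f_ind * c / gamma33)^2 * psi33 + psi_struct)

    where f_ind is the indirect fraction implied by the split.  A slope
    target additionally zeroes the exposure's intercept paths (the
    exposure-by-time setting treats the slope effect as the sole estimand).
    """
    comp = target.component
    psi33 = params_base.psi[2, 2]
    psi_struct = params_base.psi[0 if comp == "intercept" else 1,
                                 0 if comp == "intercept" else 1]
    gamma33 = params_base.gamma33

    if target.split == "equal":
        f_ind = 0.5
    elif target.split == "direct":
        f_ind = 1.0 - target.w
    else:
        f_ind = target.w

    if f_ind > 0 and gamma33 == 0:
        raise ValueError(
            "cannot place an indirect effect with gamma33 = 0 "
            f"(split={target.split!r} requires an exposure->mediator path)"
        )

    e = target.effect_size

    def resid(c: float) -> float:
        b = f_ind * c / gamma33 if f_ind > 0 else 0.0
        return c / np.sqrt(b**2 * psi33 + psi_struct) - e

    # e -> c is monotone with c/sd bounded above by gamma33*sqrt(psi_struct...)
    # bracket: resid(eps) < 0; expand upper bound until sign change.
    lo = 1e-12
    hi = max(1.0, 2 * e * np.sqrt(psi_struct))
    for _ in range(80):
        if resid(hi) > 0:
            break
        hi *= 2.0
    else:
        raise ValueError(
            f"target effect size {e} unreachable: the standardized effect is "
            f"bounded by gamma33/sqrt(psi33) = {gamma33 / np.sqrt(psi33):.4f} "
            f"times the indirect-fraction geometry for split={target.split!r}"
        )
    c = brentq(resid, lo, hi, xtol=1e-14, rtol=1e-15)
    b_med = f_ind * c / gamma33 if f_ind > 0 else 0.0
    g_dir = (1.0 - f_ind) * c

    if comp == "intercept":
        out = replace(params_base, gamma13=g_dir, b13=b_med)
    else:
        out = replace(
            params_base, gamma23=g_dir, b23=b_med, gamma13=0.0, b13=0.0
        )
    assert abs(effect_size(out, comp) - e) < 1e-8
    return out
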