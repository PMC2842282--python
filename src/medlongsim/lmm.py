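"""Linear mixed model for the repeated outcomes, fit by maximum likelihood.

The mean model is

    Y_j = beta0 + beta1*z1 + beta2*z2 + beta3*t_j [+ beta4*x] [+ beta5*z2*t_j]
          + r1 + r2*t_j + e_j

with a bivariate random intercept/slope (r1, r2) ~ N(0, G) and iid residual
e_j ~ N(0, sigma2).  With the mediator excluded (LMM2) the exposure
coefficient beta2 is a consistent estimator of the exposure's total effect;
with the mediator included (LMM1) it instead targets the direct effect.

Estimation profiles the fixed effects out of the multivariate-normal
marginal likelihood (per-subject covariance V = Z G Z' + sigma2 I shared by
all subjects, since measurement times are fixed and data are complete) and
optimizes the 4 covariance parameters on a log-Cholesky scale, so G stays
positive semi-definite without constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .datasets import TrialDataset
from .inference import FitStats, wald_summary

__all__ = ["GrowthCurveLMM", "LMMResults"]

_LOG2PI = np.log(2.0 * np.pi)


def _theta_to_cov(theta: np.ndarray) -> tuple[np.ndarray, float]:
    """(l11, l21, l22, ls) log-Cholesky -> (G, sigma2)."""
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T, float(np.exp(2.0 * theta[3]))


class GrowthCurveLMM:
    """Random intercept/slope model for a :class:`TrialDataset`.

    Parameters
    ----------
    data : TrialDataset
    include_mediator : bool
        Add the baseline mediator ``x`` as a covariate (LMM1).  Excluding
        it (LMM2, default) targets the exposure's total effect.
    include_interaction : bool
        Add the exposure-by-time interaction; the interaction coefficient
        is then the slope-component estimand.
    """

    def __init__(
        self,
        data: TrialDataset,
        include_mediator: bool = False,
        include_interaction: bool = False,
    ):
        self.data = data
        self.include_mediator = include_mediator
        self.include_interaction = include_interaction
        self.model_tag = "LMM1" if include_mediator else "LMM2"

        n, t = data.n_subjects, data.times
        names = ["const", "z1", "z2"]
        cols = [np.ones(n), data.z1, data.z2]
        if include_mediator:
            names.append("x")
            cols.append(data.x)
        names.append("time")
        # per-subject design: constant covariates load on 1_6, time terms on t
        # X_i = T @ D_i with T = [1 t] (6x2); D stacks those loadings.
        const_part = np.column_stack(cols)         # (n, p_const)
        slope_cols = [np.ones(n)]
        if include_interaction:
            names.append("z2:time")
            slope_cols.append(data.z2)
        slope_part = np.column_stack(slope_cols)   # (n, p_slope)
        p = const_part.shape[1] + slope_part.shape[1]
        D = np.zeros((n, 2, p))
        D[:, 0, : const_part.shape[1]] = const_part
        D[:, 1, const_part.shape[1]:] = slope_part
        self._D = D
        # fixed-effect names in D's column order
        self.param_names = names + (["z2:time"] if include_interaction else [])
        self._T = np.column_stack([np.ones(6), t])  # (6, 2)
        self._Y = data.y                            # (n, 6)
        self._n = n
        self._p = p

    # -- likelihood ----------------------------------------------------------

    def _profiled(self, theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (negloglik, beta_hat, A=sum X'V^-1 X) at covariance theta."""
        G, s2 = _theta_to_cov(theta)
        T = self._T
        V = T @ G @ T.T + s2 * np.eye(6)
        try:
            c, low = np.linalg.cholesky(V), True
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self._p), np.eye(self._p)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = np.linalg.inv(V)
        Q = T.T @ Vi @ T                           # (2,2)
        D = self._D                                # (n,2,p)
        A = np.einsum("nip,ij,njq->pq", D, Q, D)   # sum X'V^-1 X
        W = self._Y @ Vi @ T                       # (n,2) = y_i' V^-1 T
        b = np.einsum("nip,ni->p", D, W)           # sum X'V^-1 y
        beta = np.linalg.solve(A, b)
        mu2 = np.einsum("nip,p->ni", D, beta)      # (n,2): D_i beta
        # residual quadratic form: sum (y - T mu2)' V^-1 (y - T mu2)
        R = self._Y - mu2 @ T.T
        quad = float(np.einsum("ni,ij,nj->", R, Vi, R))
        nll = 0.5 * (self._n * (6 * _LOG2PI + logdet) + quad)
        return nll, beta, A

    def loglike(self, theta: np.ndarray) -> float:
        return -self._profiled(theta)[0]

    def fit(self, start: np.ndarray | None = None, maxiter: int = 500) -> "LMMResults":
        y = self._Y
        resid_guess = max(np.var(y, axis=1).mean() * 0.5, 1e-3)
        if start is None:
            start = np.array([0.0, 0.0, np.log(0.5), 0.5 * np.log(resid_guess)])
        best = None
        for x0 in (start, start + 0.3, start - 0.3):
            res = minimize(lambda th: self._profiled(th)[0], x0,
                           method="L-BFGS-B",
                           options={"maxiter": maxiter, "gtol": 1e-7,
                                    "ftol": 1e-13})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success:
                best = res if res.fun <= best.fun + 1e-10 else best
                break
        theta = best.x
        nll, beta, A = self._profiled(theta)
        G, s2 = _theta_to_cov(theta)
        vcov = np.linalg.inv(A)
        converged = bool(best.success
                         or np.max(np.abs(best.jac)) < 1e-3)
        return LMMResults(self, beta, vcov, G, s2, -nll, converged)


@dataclass
class LMMResults:
    """ML estimates for a :class:`GrowthCurveLMM`."""

    model: GrowthCurveLMM
    fe_params: np.ndarray
    vcov: np.ndarray
    G: np.ndarray
    sigma2: float
    llf: float
    converged: bool

    @property
    def model_tag(self) -> str:
        return self.model.model_tag

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def n_params(self) -> int:
        return len(self.fe_params) + 4  # + g11, g12, g22, sigma2

    @property
    def estimates(self) -> dict[str, float]:
        d = dict(zip(self.param_names, map(float, self.fe_params)))
        d.update(g11=float(self.G[0, 0]), g12=float(self.G[0, 1]),
                 g22=float(self.G[1, 1]), sigma2=self.sigma2)
        return d

    # -- total-effect inference ----------------------------------------------

    @property
    def total_effect_name(self) -> str:
        if self.model.include_interaction:
            return "z2:time"
        return "z2"

    @property
    def total_effect_estimate(self) -> float:
        return float(self.fe_params[self.param_names.index(self.total_effect_name)])

    @property
    def total_effect_se(self) -> float:
        i = self.param_names.index(self.total_effect_name)
        return float(np.sqrt(self.vcov[i, i]))

    def total_effect_wald(self, level: float = 0.95):
        return wald_summary(self.total_effect_estimate, self.total_effect_se,
                            level=level)

    def fit_statistics(self) -> FitStats:
        """Likelihood-based indices only (no saturated reference for LMMs)."""
        n = self.model.data.n_subjects
        k = self.n_params
        return FitStats(
            chi_square=None, df=None, rmsea=None, srmr=None,
            aic=-2.0 * self.llf + 2.0 * k,
            bic=-2.0 * self.llf + k * np.log(n),
            neg2loglik=-2.0 * self.llf,
        )

    def summary(self) -> str:
        lines = [
            f"Growth-curve LMM ({self.model_tag}) — ML, "
            f"{self.model.data.n_subjects} subjects, "
            f"{'converged' if self.converged else 'NOT converged'}",
            f"log-likelihood {self.llf:.3f}",
            f"{'param':>10} {'estimate':>10} {'se':>8}",
        ]
        for name, est, se in zip(self.param_names, self.fe_params, self.bse):
            lines.append(f"{name:>10} {est:10.4f} {se:8.4f}")
        lines.append(
            f"G = [[{self.G[0,0]:.4f}, {self.G[0,1]:.4f}], "
            f"[{self.G[0,1]:.4f}, {self.G[1,1]:.4f}]], "
            f"sigma2 = {self.sigma2:.4f}")
        lo, hi, z, p, rej = self.total_effect_wald()
        lines.append(
            f"exposure effect ({self.total_effect_name}): "
            f"{self.total_effect_estimate:.4f} "
            f"(SE {self.total_effect_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}], "
            f"p={p:.3g})")
        return "\n".join(lines)
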