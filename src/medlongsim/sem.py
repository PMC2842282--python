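"""Maximum-likelihood estimation of the mediated latent growth curve SEM.

The observed vector per subject is v = (Y1..Y6, x).  Conditional on the
covariates (z1, z2) the model implies

    v | z  ~  MVN( M (1, z1, z2)',  Sigma )

where the 7x3 mean-coefficient matrix M and the 7x7 covariance Sigma are
functions of the structural parameters (see :mod:`medlongsim.parameters`).
Because the exposure is binary, this case-wise conditional likelihood is
exact — no pseudo-normality assumption on the covariates is needed — and
its maximizer minimizes the distance between observed and model-implied
mean and covariance structure.

The likelihood depends on the data only through the cross-product matrices
V'V, V'W, W'W (W the n x 3 covariate design), so each evaluation is O(1)
in the sample size.  Variance components are optimized on a log /
log-Cholesky scale, which sidesteps Heywood (negative-variance) iterates;
standard errors come from the inverse observed information in the natural
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datasets import TrialDataset
from .inference import FitStats, delta_total_effect, rmsea, wald_summary
from .parameters import SEMParameters

__all__ = ["MediatedGrowthSEM", "SEMResults", "fit_sem"]

_LOG2PI = np.log(2.0 * np.pi)

FULL_PARAMS = [
    "alpha1", "alpha2", "alpha3",
    "gamma11", "gamma21", "gamma31",
    "gamma13", "gamma23", "gamma33",
    "b13", "b23",
    "psi11", "psi12", "psi22", "psi33",
    "sigma2",
]
REDUCED_PARAMS = [
    "alpha1", "alpha2",
    "gamma11", "gamma21",
    "gamma13", "gamma23",
    "psi11", "psi12", "psi22",
    "sigma2",
]
_POSITIVE = {"psi11", "psi22", "psi33", "sigma2"}


class MediatedGrowthSEM:
    """Latent intercept/slope SEM with a baseline mediator.

    Parameters
    ----------
    data : TrialDataset
    include_mediator : bool
        If False, fit the mediator-free latent growth submodel on the six
        outcomes alone (the SEM subclass equivalent to a random
        intercept/slope LMM).
    fixed : dict, optional
        Parameter names to hold at fixed values (e.g. ``{"gamma21": 0.0}``).
    """

    def __init__(
        self,
        data: TrialDataset,
        include_mediator: bool = True,
        fixed: dict[str, float] | None = None,
    ):
        self.data = data
        self.include_mediator = include_mediator
        self.model_tag = "SEM" if include_mediator else "SEM(no mediator)"
        self.fixed = dict(fixed or {})
        base = FULL_PARAMS if include_mediator else REDUCED_PARAMS
        unknown = set(self.fixed) - set(base)
        if unknown:
            raise ValueError(f"cannot fix unknown parameters {sorted(unknown)}")
        self.param_names = [p for p in base if p not in self.fixed]

        n = data.n_subjects
        V = np.column_stack([data.y, data.x]) if include_mediator else data.y
        W = np.column_stack([np.ones(n), data.z1, data.z2])
        self._k = V.shape[1]
        self._n = n
        self._Syy = V.T @ V
        self._Svw = V.T @ W
        self._Sww = W.T @ W
        self._times = data.times

    # -- parameter bookkeeping ----------------------------------------------

    def _theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        d = dict(zip(self.param_names, theta))
        d.update(self.fixed)
        return d

    def _moments(self, d: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """Mean-coefficient matrix M (k x 3) and implied covariance (k x k)."""
        t = self._times
        if self.include_mediator:
            B = np.zeros((3, 3))
            B[0, 2] = d["b13"]
            B[1, 2] = d["b23"]
            inv = np.linalg.inv(np.eye(3) - B)
            A = np.array([
                [d["alpha1"], d["gamma11"], d["gamma13"]],
                [d["alpha2"], d["gamma21"], d["gamma23"]],
                [d["alpha3"], d["gamma31"], d["gamma33"]],
            ])
            psi = np.array([
                [d["psi11"], d["psi12"], 0.0],
                [d["psi12"], d["psi22"], 0.0],
                [0.0, 0.0, d["psi33"]],
            ])
            lam = np.zeros((7, 3))
            lam[:6, 0] = 1.0
            lam[:6, 1] = t
            lam[6, 2] = 1.0
            lcov = inv @ psi @ inv.T
            M = lam @ inv @ A
            Sigma = lam @ lcov @ lam.T
            Sigma[np.arange(6), np.arange(6)] += d["sigma2"]
        else:
            A = np.array([
                [d["alpha1"], d["gamma11"], d["gamma13"]],
                [d["alpha2"], d["gamma21"], d["gamma23"]],
            ])
            psi = np.array([[d["psi11"], d["psi12"]],
                            [d["psi12"], d["psi22"]]])
            lam = np.column_stack([np.ones(6), t])
            M = lam @ A
            Sigma = lam @ psi @ lam.T + d["sigma2"] * np.eye(6)
        return M, Sigma

    # -- likelihood ----------------------------------------------------------

    def loglike(self, theta: np.ndarray) -> float:
        return -self._negll_natural(theta)

    def _negll_natural(self, theta: np.ndarray) -> float:
        d = self._theta_dict(np.asarray(theta, dtype=float))
        M, Sigma = self._moments(d)
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        C = (self._Syy - self._Svw @ M.T - M @ self._Svw.T
             + M @ self._Sww @ M.T)
        Sinv_C = np.linalg.solve(Sigma, C)
        return 0.5 * (self._n * (self._k * _LOG2PI + logdet)
                      + float(np.trace(Sinv_C)))

    # unconstrained scale: log on pure variances, log-Cholesky on the
    # (psi11, psi12, psi22) block
    def _to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        d = dict(zip(self.param_names, theta))
        out = []
        use_chol = all(p in self.param_names for p in ("psi11", "psi12", "psi22"))
        if use_chol:
            l11 = np.sqrt(max(d["psi11"], 1e-8))
            l21 = d["psi12"] / l11
            l22 = np.sqrt(max(d["psi22"] - l21**2, 1e-8))
        for name, val in zip(self.param_names, theta):
            if use_chol and name == "psi11":
                out.append(np.log(l11))
            elif use_chol and name == "psi12":
                out.append(l21)
            elif use_chol and name == "psi22":
                out.append(np.log(l22))
            elif name in _POSITIVE:
                out.append(np.log(max(val, 1e-8)))
            else:
                out.append(val)
        return np.array(out)

    def _from_unconstrained(self, u: np.ndarray) -> np.ndarray:
        d = dict(zip(self.param_names, u))
        use_chol = all(p in self.param_names for p in ("psi11", "psi12", "psi22"))
        out = []
        if use_chol:
            l11 = np.exp(d["psi11"])
            l21 = d["psi12"]
            l22 = np.exp(d["psi22"])
        for name, val in zip(self.param_names, u):
            if use_chol and name == "psi11":
                out.append(l11**2)
            elif use_chol and name == "psi12":
                out.append(l11 * l21)
            elif use_chol and name == "psi22":
                out.append(l21**2 + l22**2)
            elif name in _POSITIVE:
                out.append(np.exp(val))
            else:
                out.append(val)
        return np.array(out)

    # -- starting values -----------------------------------------------------

    def _start(self) -> np.ndarray:
        ds = self.data
        n = self._n
        W = np.column_stack([np.ones(n), ds.z1, ds.z2])
        T = np.column_stack([np.ones(6), ds.times])
        # per-subject OLS growth coefficients
        coef, *_ = np.linalg.lstsq(T, ds.y.T, rcond=None)  # (2, n)
        a_i, s_i = coef
        resid = ds.y - (T @ coef).T
        sigma2_0 = max(float(np.sum(resid**2) / (n * 4)), 1e-3)
        d: dict[str, float] = {}
        if self.include_mediator:
            cx = np.linalg.lstsq(W, ds.x, rcond=None)[0]
            d["alpha3"], d["gamma31"], d["gamma33"] = map(float, cx)
            rx = ds.x - W @ cx
            d["psi33"] = max(float(rx @ rx / n), 1e-3)
            X1 = np.column_stack([W, ds.x])
        else:
            X1 = W
        ca, *_ = np.linalg.lstsq(X1, a_i, rcond=None)
        cs, *_ = np.linalg.lstsq(X1, s_i, rcond=None)
        ra, rs = a_i - X1 @ ca, s_i - X1 @ cs
        d["alpha1"], d["gamma11"], d["gamma13"] = map(float, ca[:3])
        d["alpha2"], d["gamma21"], d["gamma23"] = map(float, cs[:3])
        if self.include_mediator:
            d["b13"], d["b23"] = float(ca[3]), float(cs[3])
        d["psi11"] = max(float(ra @ ra / n), 1e-3)
        d["psi22"] = max(float(rs @ rs / n) - sigma2_0 / 10.0, 1e-3)
        d["psi12"] = float(ra @ rs / n)
        # keep the start inside the PSD cone
        lim = 0.95 * np.sqrt(d["psi11"] * d["psi22"])
        d["psi12"] = float(np.clip(d["psi12"], -lim, lim))
        d["sigma2"] = sigma2_0
        d.update(self.fixed)
        return np.array([d[name] for name in self.param_names])

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        start: SEMParameters | np.ndarray | None = None,
        maxiter: int = 2000,
        gtol: float = 1e-6,
        compute_vcov: bool = True,
    ) -> "SEMResults":
        if start is None:
            theta0 = self._start()
        elif isinstance(start, SEMParameters):
            d = start.to_dict()
            d["psi11"], d["psi12"] = start.psi[0, 0], start.psi[0, 1]
            d["psi22"], d["psi33"] = start.psi[1, 1], start.psi[2, 2]
            theta0 = np.array([d[name] for name in self.param_names])
        else:
            theta0 = np.asarray(start, dtype=float)

        def obj(u: np.ndarray) -> float:
            return self._negll_natural(self._from_unconstrained(u))

        u0 = self._to_unconstrained(theta0)
        best = None
        rng = np.random.default_rng(0)
        for attempt in range(4):
            u_init = u0 if attempt == 0 else u0 + 0.2 * rng.standard_normal(len(u0))
            res = minimize(obj, u_init, method="L-BFGS-B",
                           options={"maxiter": maxiter, "gtol": gtol,
                                    "ftol": 1e-13})
            # finite-diff gradient noise scales with |f|; accept when the
            # gradient is at that floor even if the line search stalled
            ok = res.success or np.max(np.abs(res.jac)) < 1e-6 * max(
                1.0, abs(res.fun))
            if best is None or res.fun < best[0].fun - 1e-9:
                best = (res, ok)
            if ok:
                if res.fun <= best[0].fun + 1e-9:
                    best = (res, ok)
                break
        theta = self._from_unconstrained(best[0].x)
        converged = bool(best[1])
        llf = -self._negll_natural(theta)
        if compute_vcov:
            vcov, vcov_ok = self._observed_info_vcov(theta)
        else:
            vcov, vcov_ok = np.full((len(theta),) * 2, np.nan), True
        return SEMResults(self, theta, vcov, llf, converged and vcov_ok)

    def _observed_info_vcov(self, theta: np.ndarray) -> tuple[np.ndarray, bool]:
        """Inverse central-difference Hessian in the natural parameterization."""
        p = len(theta)
        h = 1e-4 * np.maximum(np.abs(theta), 0.1)
        H = np.empty((p, p))
        f = self._negll_natural
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            vcov = np.linalg.inv(H)
            ok = bool(np.all(np.diag(vcov) > 0))
        except np.linalg.LinAlgError:
            vcov, ok = np.linalg.pinv(H), False
        return 0.5 * (vcov + vcov.T), ok

    # -- saturated reference -------------------------------------------------

    def saturated_loglike(self) -> tuple[float, int]:
        """ML log-likelihood and parameter count of the saturated model
        (free (1, z1, z2) mean coefficients per outcome, unstructured
        covariance)."""
        k, n = self._k, self._n
        Msat = self._Svw @ np.linalg.inv(self._Sww)
        C = (self._Syy - self._Svw @ Msat.T - Msat @ self._Svw.T
             + Msat @ self._Sww @ Msat.T)
        S = C / n
        sign, logdet = np.linalg.slogdet(S)
        ll = -0.5 * n * (k * _LOG2PI + logdet + k)
        n_params = 3 * k + k * (k + 1) // 2
        return float(ll), n_params

    def saturated_moments(self) -> tuple[np.ndarray, np.ndarray]:
        Msat = self._Svw @ np.linalg.inv(self._Sww)
        C = (self._Syy - self._Svw @ Msat.T - Msat @ self._Svw.T
             + Msat @ self._Sww @ Msat.T)
        return Msat, C / self._n


@dataclass
class SEMResults:
    """ML estimates for a :class:`MediatedGrowthSEM`."""

    model: MediatedGrowthSEM
    params: np.ndarray
    vcov: np.ndarray
    llf: float
    converged: bool
    _stats: FitStats | None = field(default=None, repr=False)

    @property
    def model_tag(self) -> str:
        return self.model.model_tag

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def estimates(self) -> dict[str, float]:
        d = dict(zip(self.param_names, map(float, self.params)))
        d.update(self.model.fixed)
        return d

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.abs(np.diag(self.vcov)))

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def sigma2(self) -> float:
        return self.estimates["sigma2"]

    # -- total-effect inference ----------------------------------------------

    def total_effect(self, component: str = "intercept") -> tuple[float, float]:
        """Delta-method (estimate, se) of gamma + b*gamma33."""
        est = self.estimates
        names = self.param_names
        if "gamma33" not in est or "gamma33" not in names:
            raise ValueError("mediator paths are not free in this model")
        return delta_total_effect(est, self.vcov, names, component)

    @property
    def total_effect_estimate(self) -> float:
        return self.total_effect()[0]

    @property
    def total_effect_se(self) -> float:
        return self.total_effect()[1]

    def total_effect_wald(self, component: str = "intercept", level: float = 0.95):
        est, se = self.total_effect(component)
        return wald_summary(est, se, level=level)

    # -- fit statistics --------------------------------------------------------

    def fit_statistics(self) -> FitStats:
        if self._stats is not None:
            return self._stats
        n = self.model._n
        ll_sat, p_sat = self.model.saturated_loglike()
        chi2 = max(2.0 * (ll_sat - self.llf), 0.0)
        df = p_sat - self.n_params
        rmsea_val = rmsea(chi2, df, n)
        # SRMR: covariance + mean residuals standardized by saturated SDs
        Msat, Ssat = self.model.saturated_moments()
        d = self.estimates
        Mmod, Smod = self.model._moments(d)
        sd = np.sqrt(np.diag(Ssat))
        tri = np.tril_indices(self.model._k)
        cov_res = ((Ssat - Smod) / np.outer(sd, sd))[tri]
        wbar = self.model._Sww[:, 0] / n  # (1, mean z1, mean z2)
        mean_res = ((Msat - Mmod) @ wbar) / sd
        resids = np.concatenate([cov_res, mean_res])
        srmr = float(np.sqrt(np.mean(resids**2)))
        k = self.n_params
        self._stats = FitStats(
            chi_square=chi2, df=df, rmsea=rmsea_val, srmr=srmr,
            aic=-2.0 * self.llf + 2.0 * k,
            bic=-2.0 * self.llf + k * np.log(n),
            neg2loglik=-2.0 * self.llf,
        )
        return self._stats

    def summary(self) -> str:
        lines = [
            f"Mediated growth curve SEM — ML, {self.model._n} subjects, "
            f"{'converged' if self.converged else 'NOT converged'}",
            f"log-likelihood {self.llf:.3f}",
            f"{'param':>8} {'estimate':>10} {'se':>8}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>8} {est:10.4f} {se:8.4f}")
        if "gamma33" in self.param_names:
            est, se = self.total_effect()
            lo, hi, z, p, rej = wald_summary(est, se)
            lines.append(
                f"total effect (gamma13 + b13*gamma33): {est:.4f} "
                f"(SE {se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}], p={p:.3g})")
        return "\n".join(lines)


def fit_sem(
    ds: TrialDataset,
    params_init: SEMParameters | None = None,
    **kwargs,
) -> SEMResults:
    """Fit the full mediated growth SEM to a dataset."""
    return MediatedGrowthSEM(ds, **kwargs).fit(start=params_init)
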