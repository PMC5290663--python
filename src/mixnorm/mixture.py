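"""Two-part mixture likelihood for a single metabolite.

The model couples a logistic regression for metabolite *presence* with a
normal model for its abundance, left-truncated at batch-specific detection
thresholds. For sample i with covariate rows x_i (presence) and z_i (mean),
detection indicator d_i, observed log2 abundance y_i and threshold T_i:

* p_i = expit(x_i' beta) is the probability the metabolite is present;
* mu_i = z_i' alpha is its mean abundance when present, with common
  residual standard deviation sigma across samples.

An undetected sample contributes (1 - p_i) + p_i * Phi((T_i - mu_i)/sigma)
to the likelihood — the metabolite is either truly absent or present below
the batch's detectability floor. A detected sample contributes
p_i * N(y_i; mu_i, sigma^2). Maximum likelihood estimates are obtained by
quasi-Newton (BFGS) minimisation of the negative log likelihood over
(beta, alpha, log sigma), with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "MixtureDesign",
    "MixtureParams",
    "MixtureFit",
    "FitOptions",
    "NotFittableError",
    "neg_log_likelihood",
    "fit_mixture",
    "wald_test",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_P_CLAMP = 1e-12  # presence probability kept inside (0, 1) for stable logs
_LOG_SIGMA_BOUND = 30.0


class NotFittableError(ValueError):
    """The likelihood has no interior maximum (e.g. nothing was detected)."""


@dataclass
class MixtureDesign:
    """Design matrices for the presence (x) and mean (z) model components.

    Rows correspond to fitting samples; both matrices must include an
    intercept column and be of full column rank on those samples. The
    presence design may use a subset of the mean design's covariates when
    few samples or few non-detects make the full logistic model fragile.
    """

    x: np.ndarray
    z: np.ndarray
    x_names: list[str]
    z_names: list[str]

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.x.shape[0] != self.z.shape[0]:
            raise ValueError("x and z designs must have the same number of rows")
        if self.x.shape[1] != len(self.x_names):
            raise ValueError("x_names does not match x design width")
        if self.z.shape[1] != len(self.z_names):
            raise ValueError("z_names does not match z design width")
        for name, mat in (("x", self.x), ("z", self.z)):
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"non-finite entries in {name} design")
            if np.linalg.matrix_rank(mat) < mat.shape[1]:
                raise ValueError(f"{name} design is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]


@dataclass
class MixtureParams:
    """Packed parameters: logistic beta, linear alpha, and log sigma."""

    beta: np.ndarray
    alpha: np.ndarray
    log_sigma: float

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha, [self.log_sigma]])

    @staticmethod
    def unpack(theta: np.ndarray, p_x: int, p_z: int) -> "MixtureParams":
        theta = np.asarray(theta, dtype=float)
        return MixtureParams(
            beta=theta[:p_x].copy(),
            alpha=theta[p_x : p_x + p_z].copy(),
            log_sigma=float(theta[p_x + p_z]),
        )


@dataclass
class MixtureFit:
    """Result of a per-metabolite maximum-likelihood fit."""

    params: MixtureParams
    neg_log_lik: float
    converged: bool
    n_detected: int
    n_undetected: int
    x_names: list[str]
    z_names: list[str]
    metabolite_id: Optional[str] = None
    standard_errors: Optional[np.ndarray] = None  # aligned with params.pack()
    logistic_bypassed: bool = False
    n_iterations: int = 0

    def coefficient(self, name: str, component: str = "linear") -> float:
        idx, _ = self._locate(name, component)
        return float(self.params.pack()[idx])

    def _locate(self, name: str, component: str) -> tuple[int, str]:
        if component == "linear":
            if name not in self.z_names:
                raise KeyError(f"{name!r} not in linear component {self.z_names}")
            return len(self.x_names) + self.z_names.index(name), "linear"
        if component == "logistic":
            if name not in self.x_names:
                raise KeyError(f"{name!r} not in logistic component {self.x_names}")
            return self.x_names.index(name), "logistic"
        raise ValueError("component must be 'linear' or 'logistic'")


@dataclass
class FitOptions:
    """Optimiser settings for :func:`fit_mixture`."""

    gtol: float = 1e-6
    maxiter: int = 500
    restart_jitter_sd: float = 0.1
    seed: int = 0
    compute_standard_errors: bool = False
    bypass_all_detected: bool = True


def _clamped_p(eta: np.ndarray) -> np.ndarray:
    return np.clip(expit(eta), _P_CLAMP, 1.0 - _P_CLAMP)


def _nll_and_grad(
    theta: np.ndarray,
    y: np.ndarray,
    detected: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    thresholds: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log likelihood and its gradient, vectorised over samples."""
    p_x, p_z = x.shape[1], z.shape[1]
    beta = theta[:p_x]
    alpha = theta[p_x : p_x + p_z]
    s = float(np.clip(theta[p_x + p_z], -_LOG_SIGMA_BOUND, _LOG_SIGMA_BOUND))
    sigma = np.exp(s)

    eta = x @ beta
    mu = z @ alpha
    p = _clamped_p(eta)

    ll = 0.0
    g_eta = np.zeros(len(y))
    g_mu = np.zeros(len(y))
    g_s = 0.0

    det = detected
    if det.any():
        r = (y[det] - mu[det]) / sigma
        ll += float(np.sum(np.log(p[det]) - 0.5 * r * r - s - 0.5 * _LOG_2PI))
        g_eta[det] = 1.0 - p[det]
        g_mu[det] = r / sigma
        g_s += float(np.sum(r * r - 1.0))

    und = ~det
    if und.any():
        u = (thresholds[und] - mu[und]) / sigma
        log_mix = np.logaddexp(
            np.log1p(-p[und]), np.log(p[und]) + log_ndtr(u)
        )
        ll += float(np.sum(log_mix))
        big_phi = ndtr(u)
        mix = (1.0 - p[und]) + p[und] * big_phi  # >= _P_CLAMP * big_phi > 0
        phi = np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
        g_eta[und] = p[und] * (1.0 - p[und]) * (big_phi - 1.0) / mix
        g_mu[und] = -p[und] * phi / (sigma * mix)
        g_s += float(np.sum(-p[und] * u * phi / mix))

    grad = np.empty_like(theta)
    grad[:p_x] = -(x.T @ g_eta)
    grad[p_x : p_x + p_z] = -(z.T @ g_mu)
    grad[p_x + p_z] = -g_s
    return -ll, grad


def neg_log_likelihood(
    params: MixtureParams,
    y: np.ndarray,
    detected: np.ndarray,
    design: MixtureDesign,
    thresholds: np.ndarray,
) -> float:
    """Negative log likelihood of one metabolite's data under ``params``.

    ``y`` holds observed log2 abundances (entries where ``detected`` is
    False are ignored); ``thresholds`` gives each sample's batch detection
    floor T_i.
    """
    y = np.asarray(y, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    thresholds = np.asarray(thresholds, dtype=float)
    if not (len(y) == len(detected) == len(thresholds) == design.n_samples):
        raise ValueError("y, detected, thresholds and design rows must align")
    theta = params.pack()
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    nll, _ = _nll_and_grad(theta, y, detected, design.x, design.z, thresholds)
    return nll


def _gaussian_fit(
    y: np.ndarray,
    design: MixtureDesign,
    options: FitOptions,
    metabolite_id: Optional[str],
) -> MixtureFit:
    """Closed-form Gaussian MLE used when every sample is detected.

    With no non-detects the presence model is unidentified (the likelihood
    is maximised as p -> 1), so the fit reduces to least squares on z.
    """
    z = design.z
    n, p_z = z.shape
    alpha, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ alpha
    sigma2 = float(resid @ resid) / n  # MLE divisor n
    sigma2 = max(sigma2, 1e-300)
    nll = 0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    params = MixtureParams(
        beta=np.full(len(design.x_names), np.nan),
        alpha=alpha,
        log_sigma=0.5 * float(np.log(sigma2)),
    )
    se = None
    if options.compute_standard_errors:
        cov_alpha = sigma2 * np.linalg.inv(z.T @ z)
        se = np.concatenate(
            [
                np.full(len(design.x_names), np.nan),
                np.sqrt(np.diag(cov_alpha)),
                [np.sqrt(1.0 / (2.0 * n))],
            ]
        )
    return MixtureFit(
        params=params,
        neg_log_lik=float(nll),
        converged=True,
        n_detected=n,
        n_undetected=0,
        x_names=list(design.x_names),
        z_names=list(design.z_names),
        metabolite_id=metabolite_id,
        standard_errors=se,
        logistic_bypassed=True,
    )


def _initial_theta(
    y: np.ndarray,
    detected: np.ndarray,
    design: MixtureDesign,
) -> np.ndarray:
    """Deterministic start: least squares on detected values, logistic
    intercept at the observed detection log-odds, slopes at zero."""
    p_x, p_z = design.x.shape[1], design.z.shape[1]
    z_det = design.z[detected]
    y_det = y[detected]
    if z_det.shape[0] >= 1:
        alpha0, *_ = np.linalg.lstsq(z_det, y_det, rcond=None)
        resid = y_det - z_det @ alpha0
        sd = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
    else:  # pragma: no cover - guarded by NotFittableError upstream
        alpha0 = np.zeros(p_z)
        sd = 1.0
    sd = max(sd, 1e-3)
    beta0 = np.zeros(p_x)
    frac = float(np.clip(np.mean(detected), 0.01, 0.99))
    intercept_cols = [
        j for j in range(p_x) if np.all(design.x[:, j] == design.x[0, j])
        and design.x[0, j] != 0
    ]
    if intercept_cols:
        beta0[intercept_cols[0]] = np.log(frac / (1.0 - frac)) / design.x[
            0, intercept_cols[0]
        ]
    return np.concatenate([beta0, alpha0, [np.log(sd)]])


def _observed_information_se(theta, args) -> np.ndarray:
    """Standard errors from the inverse observed information, with the
    Hessian formed by central differences of the analytic gradient."""
    k = len(theta)
    hess = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _nll_and_grad(tp, *args)
        _, gm = _nll_and_grad(tm, *args)
        hess[:, i] = (gp - gm) / (2.0 * h)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)
    diag = np.diag(cov)
    with np.errstate(invalid="ignore"):
        return np.where(diag > 0, np.sqrt(diag), np.nan)


def fit_mixture(
    y: np.ndarray,
    detected: np.ndarray,
    design: MixtureDesign,
    thresholds: np.ndarray,
    options: Optional[FitOptions] = None,
    metabolite_id: Optional[str] = None,
) -> MixtureFit:
    """Maximum-likelihood fit of the mixture model for one metabolite.

    Minimises the negative log likelihood by BFGS over (beta, alpha,
    log sigma) from a deterministic start, with one seeded random-jitter
    restart on non-convergence. If every sample is detected the logistic
    component is bypassed and the fit is closed-form Gaussian least squares
    (see :func:`_gaussian_fit`); if nothing is detected the metabolite is
    not fittable.
    """
    options = options or FitOptions()
    y = np.asarray(y, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    thresholds = np.asarray(thresholds, dtype=float)
    if not (len(y) == len(detected) == len(thresholds) == design.n_samples):
        raise ValueError("y, detected, thresholds and design rows must align")
    n_det = int(detected.sum())
    if n_det == 0:
        raise NotFittableError(
            f"metabolite {metabolite_id!r}: no detected values; the "
            "likelihood has no interior maximum"
        )
    if n_det == len(y) and options.bypass_all_detected:
        return _gaussian_fit(y, design, options, metabolite_id)

    y_safe = np.where(detected, y, 0.0)  # undefined entries never read
    args = (y_safe, detected, design.x, design.z, thresholds)
    theta0 = _initial_theta(y_safe, detected, design)

    def solve(t0):
        return optimize.minimize(
            _nll_and_grad,
            t0,
            args=args,
            jac=True,
            method="BFGS",
            options={"gtol": options.gtol, "maxiter": options.maxiter},
        )

    res = solve(theta0)
    if not res.success:
        # restarting from the stalled point resets the Hessian approximation
        # and usually recovers from line-search precision loss
        polished = solve(res.x)
        if polished.fun <= res.fun:
            res = polished
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) <= 10 * options.gtol
    if not converged:
        rng = np.random.default_rng(options.seed)
        res2 = solve(theta0 + options.restart_jitter_sd * rng.standard_normal(len(theta0)))
        conv2 = bool(res2.success) or float(np.max(np.abs(res2.jac))) <= 10 * options.gtol
        if res2.fun < res.fun or (conv2 and not converged):
            res, converged = res2, conv2

    p_x, p_z = design.x.shape[1], design.z.shape[1]
    params = MixtureParams.unpack(res.x, p_x, p_z)
    se = None
    if options.compute_standard_errors:
        se = _observed_information_se(res.x, args)
    return MixtureFit(
        params=params,
        neg_log_lik=float(res.fun),
        converged=converged,
        n_detected=n_det,
        n_undetected=len(y) - n_det,
        x_names=list(design.x_names),
        z_names=list(design.z_names),
        metabolite_id=metabolite_id,
        standard_errors=se,
        logistic_bypassed=False,
        n_iterations=int(res.nit),
    )


@dataclass
class WaldResult:
    coefficient: str
    component: str
    estimate: float
    std_error: float
    z_value: float
    p_value: float


def wald_test(fit: MixtureFit, coefficient: str, component: str = "linear") -> WaldResult:
    """Two-sided normal-theory Wald test for one fitted coefficient.

    Standard errors come from the inverse observed information, so the fit
    must have been run with ``compute_standard_errors=True``.
    """
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    if fit.standard_errors is None:
        raise ValueError(
            "fit has no standard errors; refit with compute_standard_errors=True"
        )
    idx, _ = fit._locate(coefficient, component)
    est = float(fit.params.pack()[idx])
    se = float(fit.standard_errors[idx])
    if not np.isfinite(se) or se <= 0:
        raise ValueError(
            f"singular information for {component} coefficient {coefficient!r}"
        )
    zval = est / se
    pval = float(2.0 * (1.0 - ndtr(abs(zval))))
    return WaldResult(coefficient, component, est, se, zval, pval)
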