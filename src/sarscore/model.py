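"""Core of the score-driven SARAR Student-t model.

The observation model for an ``R``-vector panel ``y_t``, ``t = 1..T`` is

    Z1 y_t = X_t beta + mu_t + eps_t,      Z2 eps_t = eta_t,

with spatial filters ``Z1 = I - rho1 W1`` and ``Z2 = I - rho2 W2`` built
from row-stochastic weight matrices, and heavy-tailed innovations
``eta_t ~ iid t_nu(0, Lambda)``, ``Lambda = diag(exp(2 lam_r))``.  The
latent signal ``mu_t`` is tracked by an observation-driven recursion whose
innovation is proportional to the score of the conditional log-likelihood
with respect to the location:

    mu_{t+1|t} = phi mu_{t|t-1} + K u_t,       u_t = Z2 Z1 v_t / alpha_t,

where ``v_t`` is the one-step-ahead prediction error of the reduced form
and ``alpha_t = 1 + (Z2 Z1 v_t)' Lambda^{-1} (Z2 Z1 v_t) / nu``.  Because
``u_t = Z2 Z1 v_t (1 - b_t)`` with ``b_t = 1 - 1/alpha_t`` a
``Beta(R/2, nu/2)`` variate, the update winsorizes extreme prediction
errors: the smaller ``nu``, the more an outlying observation is
down-weighted, while as ``nu -> inf`` the filter collapses to its linear
Gaussian counterpart.

The per-step operations are exposed as plain functions; :func:`run_filter`
runs the full recursion through a compiled loop and returns a
:class:`FilterOutput` carrying the filtered signal, prediction errors,
scores, weights and per-observation log-likelihood contributions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from numba import njit
from scipy.linalg import lu_factor, lu_solve
from scipy.special import gammaln

from .weights import SpatialWeights

__all__ = [
    "ModelParameters",
    "PanelData",
    "FilterOutput",
    "spatial_filter",
    "prediction_error",
    "alpha_weight",
    "score_innovation",
    "beta_variate",
    "signal_update",
    "conditional_logdensity",
    "score_wrt_location",
    "run_filter",
    "gaussian_expansion_correction",
    "invertibility_diagnostic",
]


@dataclasses.dataclass
class ModelParameters:
    """Static parameter vector theta = (beta, rho1, rho2, nu, lam, phi, kappa).

    Attributes
    ----------
    beta
        Regression coefficients, length ``p + 1`` (intercept first).
    rho1, rho2
        Spatial autoregressive parameters of the response and of the
        disturbances; the model requires ``|rho| < 1``.
    nu
        Degrees of freedom of the Student-t innovations, ``nu > 0``.
    lam
        Per-region log-scales: the innovation shape matrix is
        ``diag(exp(2 lam_r))``.
    phi
        Temporal autoregressive parameter of the latent signal, ``|phi| < 1``.
    kappa
        Per-region positive score loadings ``K = diag(kappa)``.
    """

    beta: np.ndarray
    rho1: float
    rho2: float
    nu: float
    lam: np.ndarray
    phi: float
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if self.kappa.shape != self.lam.shape:
            raise ValueError("lam and kappa must have equal length R")

    @property
    def n_regions(self) -> int:
        return self.lam.shape[0]

    @property
    def n_covariates(self) -> int:
        """p: number of regressors beyond the intercept."""
        return self.beta.shape[0] - 1

    @property
    def dimension(self) -> int:
        return 2 * self.n_regions + self.n_covariates + 5

    def validate(self) -> "ModelParameters":
        """Raise unless all stationarity/positivity constraints hold."""
        if not abs(self.rho1) < 1:
            raise ValueError(f"|rho1| must be < 1, got {self.rho1}")
        if not abs(self.rho2) < 1:
            raise ValueError(f"|rho2| must be < 1, got {self.rho2}")
        if not abs(self.phi) < 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not np.all(self.kappa > 0):
            raise ValueError("all kappa_r must be > 0")
        return self


@dataclasses.dataclass
class PanelData:
    """Observed panel ``y`` (R x T) with nonstochastic covariates.

    ``X`` is stored as a (T, R, p+1) array, one design matrix per time
    step with the intercept in the first column; ``None`` means an
    intercept-only design.  ``latent_mu`` carries the simulation truth when
    the panel was generated by :func:`sarscore.simulation.simulate_panel`.
    """

    y: np.ndarray
    X: np.ndarray | None = None
    latent_mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be an R x T matrix")
        R, T = self.y.shape
        if T < 2:
            raise ValueError(f"need T >= 2 time points, got {T}")
        if not np.all(np.isfinite(self.y)):
            r, t = np.argwhere(~np.isfinite(self.y))[0]
            raise ValueError(f"non-finite observation at (region {r}, time {t})")
        if self.X is None:
            self.X = np.ones((T, R, 1))
        else:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[:2] != (T, R):
                raise ValueError(
                    f"X shape {self.X.shape} inconsistent with y {self.y.shape}"
                )
            if not np.all(np.isfinite(self.X)):
                raise ValueError("covariates must be finite")
        if self.latent_mu is not None:
            self.latent_mu = np.asarray(self.latent_mu, dtype=float)
            if self.latent_mu.shape != self.y.shape:
                raise ValueError("latent_mu must match y in shape")

    @property
    def n_regions(self) -> int:
        return self.y.shape[0]

    @property
    def n_times(self) -> int:
        return self.y.shape[1]


@dataclasses.dataclass
class FilterOutput:
    """Full path of the score-driven filter.

    All R x T arrays are region-by-time.  ``mu_pred[:, t]`` is the
    predicted signal ``mu_{t|t-1}`` (i.e. before seeing ``y_t``), ``v`` the
    prediction errors, ``u`` the winsorized score innovations, ``alpha``
    and ``b`` the scalar robustness weights, ``loglik_t`` the per-``t``
    conditional log-density contributions and ``loglik`` their sum.
    """

    mu_pred: np.ndarray
    v: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    b: np.ndarray
    loglik_t: np.ndarray
    loglik: float

    def spatial_residuals(self, Z: np.ndarray) -> np.ndarray:
        """Spatially filtered prediction errors ``Z v_t`` (R x T)."""
        return Z @ self.v


def _as_matrix(W: SpatialWeights | np.ndarray) -> np.ndarray:
    return W.W if isinstance(W, SpatialWeights) else np.asarray(W, dtype=float)


def spatial_filter(rho: float, W: SpatialWeights | np.ndarray) -> np.ndarray:
    """The spatial filtering matrix ``Z = I - rho W``; requires ``|rho| < 1``."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    Wm = _as_matrix(W)
    return np.eye(Wm.shape[0]) - rho * Wm


def prediction_error(
    y_t: np.ndarray,
    X_t: np.ndarray,
    params: ModelParameters,
    mu_pred_t: np.ndarray,
    Z1: np.ndarray,
) -> np.ndarray:
    """One-step-ahead prediction error of the reduced form.

    ``v_t = y_t - Z1^{-1} X_t beta - Z1^{-1} mu_{t|t-1}``, computed by a
    linear solve rather than an explicit inverse.
    """
    rhs = np.asarray(X_t, dtype=float) @ params.beta + np.asarray(mu_pred_t, float)
    return np.asarray(y_t, dtype=float) - np.linalg.solve(Z1, rhs)


def _spatial_error(v_t, Z1, Z2):
    return Z2 @ (Z1 @ np.asarray(v_t, dtype=float))


def alpha_weight(
    v_t: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    lam: np.ndarray,
    nu: float,
) -> float:
    """Robustness weight ``alpha_t >= 1``.

    ``alpha_t = 1 + e_t' Lambda^{-1} e_t / nu`` with ``e_t = Z2 Z1 v_t``:
    one plus the squared Mahalanobis distance of the spatial prediction
    error, scaled by the degrees of freedom.
    """
    if not nu > 0:
        raise ValueError(f"nu must be > 0, got {nu}")
    e = _spatial_error(v_t, Z1, Z2)
    q = float(e @ (np.exp(-2.0 * np.asarray(lam, float)) * e)) / nu
    return 1.0 + q


def beta_variate(
    v_t: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    lam: np.ndarray,
    nu: float,
) -> float:
    """The winsorizing fraction ``b_t = 1 - 1/alpha_t`` in ``[0, 1)``.

    Under the model, ``b_t`` is a ``Beta(R/2, nu/2)`` random variable: the
    share of the spatial prediction error that the score discards.
    """
    alpha = alpha_weight(v_t, Z1, Z2, lam, nu)
    return (alpha - 1.0) / alpha


def score_innovation(
    v_t: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    alpha_t: float,
) -> np.ndarray:
    """Winsorized score innovation ``u_t = Z2 Z1 v_t / alpha_t``."""
    return _spatial_error(v_t, Z1, Z2) / alpha_t


def signal_update(
    mu_pred_t: np.ndarray,
    phi: float,
    kappa: np.ndarray,
    u_t: np.ndarray,
) -> np.ndarray:
    """One step of the signal recursion ``mu_{t+1|t} = phi mu_{t|t-1} + K u_t``."""
    return phi * np.asarray(mu_pred_t, float) + np.asarray(kappa, float) * np.asarray(
        u_t, float
    )


def _lgamma_diff(x: float, a: float) -> float:
    """log Gamma(x + a) - log Gamma(x), stable for very large x.

    Direct subtraction of two log-gammas of order ``x log x`` loses the
    low-order bits needed at nu ~ 1e8; beyond x = 1e7 a Stirling-based
    difference (all terms of moderate size) is used instead.
    """
    if x < 1e7:
        return float(gammaln(x + a) - gammaln(x))
    return (
        a * math.log(x)
        + (x + a - 0.5) * math.log1p(a / x)
        - a
        + (1.0 / (12.0 * (x + a)) - 1.0 / (12.0 * x))
    )


def _log_normalizer(params: ModelParameters, Z1: np.ndarray, Z2: np.ndarray) -> float:
    """Log of the Student-t density constant, including the log-determinant
    of the reduced-form shape matrix ``Z1^{-1} Z2^{-1} Lambda Z2^{-T} Z1^{-T}``."""
    R = params.n_regions
    nu = params.nu
    _, ld1 = np.linalg.slogdet(Z1)
    _, ld2 = np.linalg.slogdet(Z2)
    half_logdet_shape = float(np.sum(params.lam)) - ld1 - ld2
    return float(
        _lgamma_diff(nu / 2.0, R / 2.0)
        - 0.5 * R * math.log(math.pi * nu)
        - half_logdet_shape
    )


def conditional_logdensity(
    y_t: np.ndarray,
    X_t: np.ndarray,
    params: ModelParameters,
    mu_pred_t: np.ndarray,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
) -> float:
    """Log-density of ``y_t`` given the past.

    The conditional law is multivariate Student-t with location
    ``Z1^{-1}(X_t beta + mu_{t|t-1})`` and shape
    ``Z1^{-1} Z2^{-1} Lambda Z2^{-T} Z1^{-T}``.  Evaluated in log-gamma /
    ``log1p`` arithmetic so that ``nu`` up to ``1e12`` stays finite.
    """
    if W2 is None:
        W2 = W1
    Z1 = spatial_filter(params.rho1, W1)
    Z2 = spatial_filter(params.rho2, W2)
    v = prediction_error(y_t, X_t, params, mu_pred_t, Z1)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite prediction error")
    e = _spatial_error(v, Z1, Z2)
    q = float(e @ (np.exp(-2.0 * params.lam) * e)) / params.nu
    R = params.n_regions
    return _log_normalizer(params, Z1, Z2) - 0.5 * (params.nu + R) * math.log1p(q)


def score_wrt_location(
    y_t: np.ndarray,
    X_t: np.ndarray,
    params: ModelParameters,
    mu_pred_t: np.ndarray,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of the conditional log-density with respect to ``mu_{t|t-1}``.

    Equals ``((nu + R)/nu) Z2' Lambda^{-1} u_t`` — the score whose scaled
    version drives the signal recursion.
    """
    if W2 is None:
        W2 = W1
    Z1 = spatial_filter(params.rho1, W1)
    Z2 = spatial_filter(params.rho2, W2)
    v = prediction_error(y_t, X_t, params, mu_pred_t, Z1)
    alpha = alpha_weight(v, Z1, Z2, params.lam, params.nu)
    u = score_innovation(v, Z1, Z2, alpha)
    R = params.n_regions
    return ((params.nu + R) / params.nu) * (Z2.T @ (np.exp(-2.0 * params.lam) * u))


@njit(cache=True)
def _filter_loop(y, cx, Z1inv, A, lam_inv2, nu, phi, kappa, mu0, lognorm):
    """Sequential filter recursion; A = Z2 @ Z1, lam_inv2 = exp(-2 lam)."""
    R, T = y.shape
    mu_pred = np.empty((R, T))
    v = np.empty((R, T))
    u = np.empty((R, T))
    alpha = np.empty(T)
    b = np.empty(T)
    ll = np.empty(T)
    mu = mu0.copy()
    half = 0.5 * (nu + R)
    for t in range(T):
        for r in range(R):
            mu_pred[r, t] = mu[r]
        vt = y[:, t] - cx[:, t] - Z1inv @ mu
        et = A @ vt
        q = 0.0
        for r in range(R):
            q += et[r] * et[r] * lam_inv2[r]
        q /= nu
        at = 1.0 + q
        for r in range(R):
            v[r, t] = vt[r]
            u[r, t] = et[r] / at
        alpha[t] = at
        b[t] = q / at
        ll[t] = lognorm - half * np.log1p(q)
        mu = phi * mu + kappa * u[:, t]
    return mu_pred, v, u, alpha, b, ll


def run_filter(
    data: PanelData,
    params: ModelParameters,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
    mu_init: np.ndarray | None = None,
) -> FilterOutput:
    """Run the score-driven filter over the whole panel.

    The recursion is initialized at ``mu_{1|0} = 0`` (the unconditional
    mean of the signal recursion) unless ``mu_init`` is given; under the
    contraction condition the initialization is forgotten exponentially
    fast.  The spatial filters are LU-factorized once per call and all
    applications of ``Z1^{-1}`` are linear solves on those factors.
    """
    R, T = data.y.shape
    if params.n_regions != R:
        raise ValueError(f"params are for R={params.n_regions}, data has R={R}")
    if W2 is None:
        W2 = W1
    Z1 = spatial_filter(params.rho1, W1)
    Z2 = spatial_filter(params.rho2, W2)
    lu1 = lu_factor(Z1)
    Z1inv = lu_solve(lu1, np.eye(R))
    # Z1^{-1} X_t beta for every t in one batched solve
    cx = np.ascontiguousarray(lu_solve(lu1, (data.X @ params.beta).T))
    mu0 = (
        np.zeros(R)
        if mu_init is None
        else np.asarray(mu_init, dtype=float).copy()
    )
    if mu0.shape != (R,):
        raise ValueError("mu_init must be an R-vector")
    lognorm = _log_normalizer(params, Z1, Z2)
    mu_pred, v, u, alpha, b, ll = _filter_loop(
        np.ascontiguousarray(data.y),
        np.ascontiguousarray(cx),
        np.ascontiguousarray(Z1inv),
        np.ascontiguousarray(Z2 @ Z1),
        np.exp(-2.0 * params.lam),
        float(params.nu),
        float(params.phi),
        np.ascontiguousarray(params.kappa, dtype=float),
        mu0,
        lognorm,
    )
    if not np.all(np.isfinite(ll)):
        t_bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log-likelihood at t={t_bad}")
    return FilterOutput(mu_pred, v, u, alpha, b, ll, float(ll.sum()))


def gaussian_expansion_correction(y: np.ndarray, R: int, nu: float) -> float:
    """First-order term of the Student-t-to-Gaussian density expansion.

    For the standardized ``R``-variate Student-t density ``f`` and standard
    normal density ``phi``, ``f(y) = phi(y) (1 + c(y)/1 + O(nu^{-2}))`` with

        c(y) = ((y'y)^2 - 2 R y'y + R (R - 2)) / (4 nu).

    The correction shrinks like ``1/nu`` but grows with ``R``: normal
    approximation of a multivariate t requires roughly ``nu >= 30 R^2``.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    s = float(y @ y)
    return (s * s - 2.0 * R * s + R * (R - 2.0)) / (4.0 * nu)


@dataclasses.dataclass
class InvertibilityDiagnostic:
    """Output of :func:`invertibility_diagnostic`.

    ``decay_rate`` is the fitted per-step geometric rate (log scale) at
    which filter paths started from different initializations approach one
    another; ``lyapunov_exponent`` is a Monte-Carlo estimate of the top
    Lyapunov exponent of the recursion ``mu_{t+1|t} = s_t(mu_{t|t-1})``
    along the data path.  ``contractive`` is False when the exponent
    estimate is nonnegative.
    """

    decay_rate: float
    lyapunov_exponent: float
    contractive: bool
    final_spread: float


def _one_step(mu, t, y, cx, Z1inv, A, lam_inv2, nu, phi, kappa):
    v = y[:, t] - cx[:, t] - Z1inv @ mu
    e = A @ v
    q = float(e @ (lam_inv2 * e)) / nu
    return phi * mu + kappa * e / (1.0 + q)


def invertibility_diagnostic(
    data: PanelData,
    params: ModelParameters,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
    n_init: int = 5,
    horizon: int | None = None,
    rng: np.random.Generator | None = None,
    init_scale: float = 5.0,
) -> InvertibilityDiagnostic:
    """Empirical check that the filter forgets its initialization.

    Runs the filter from ``n_init`` random starts and from zero, fits the
    geometric decay rate of the pairwise path differences, and estimates
    the top Lyapunov exponent by propagating a random direction through
    central-difference Jacobian-vector products of the one-step map.
    """
    if W2 is None:
        W2 = W1
    R, T = data.y.shape
    horizon = T if horizon is None else min(horizon, T)
    rng = np.random.default_rng(0) if rng is None else rng

    # phi may deliberately violate |phi| < 1 here; the rho's must be valid
    Z1 = spatial_filter(params.rho1, W1)
    Z2 = np.eye(R) - params.rho2 * _as_matrix(W2)
    Z1inv = np.linalg.inv(Z1)
    A = Z2 @ Z1
    lam_inv2 = np.exp(-2.0 * params.lam)
    cx = ((data.X @ params.beta) @ Z1inv.T).T
    args = (data.y, cx, Z1inv, A, lam_inv2, float(params.nu), float(params.phi),
            params.kappa)

    inits = [np.zeros(R)] + [init_scale * rng.standard_normal(R) for _ in range(n_init)]
    paths = []
    for mu0 in inits:
        path = np.empty((R, horizon))
        mu = mu0.copy()
        for t in range(horizon):
            path[:, t] = mu
            mu = _one_step(mu, t, *args)
        paths.append(path)

    # geometric decay of pairwise differences
    rates = []
    spreads = []
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            d = np.linalg.norm(paths[i] - paths[j], axis=0)
            spreads.append(d[-1])
            usable = np.flatnonzero(d > 1e-14)
            if usable.size >= 3:
                k = usable[: max(3, usable.size)]
                slope = np.polyfit(k, np.log(d[k]), 1)[0]
                rates.append(slope)
    decay_rate = float(np.median(rates)) if rates else -np.inf

    # top Lyapunov exponent along the zero-init path
    mu = np.zeros(R)
    d = rng.standard_normal(R)
    d /= np.linalg.norm(d)
    log_growth = 0.0
    h = 1e-6
    for t in range(horizon):
        jd = (_one_step(mu + h * d, t, *args) - _one_step(mu - h * d, t, *args)) / (
            2.0 * h
        )
        norm = np.linalg.norm(jd)
        if norm == 0.0:
            log_growth += -np.inf
            break
        log_growth += math.log(norm)
        d = jd / norm
        mu = _one_step(mu, t, *args)
    lyap = log_growth / horizon
    return InvertibilityDiagnostic(
        decay_rate=decay_rate,
        lyapunov_exponent=float(lyap),
        contractive=bool(lyap < 0),
        final_spread=float(np.max(spreads)) if spreads else 0.0,
    )
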