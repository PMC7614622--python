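"""Maximum likelihood estimation of the score-driven SARAR Student-t model.

The static parameter vector theta = (beta, rho1, rho2, nu, lam, phi, kappa)
is estimated by maximizing the empirical log-likelihood produced by the
filter started at ``mu_{1|0} = 0``.  Optimization runs in an unconstrained
space: atanh for the autoregressive parameters, log for ``nu`` and
``kappa``, identity for ``beta`` and ``lam``.  Asymptotic standard errors
come from numeric curvature (inverse Hessian by default, outer product of
per-observation score contributions or the sandwich combination as
alternatives), delta-method mapped back to the natural scale.

Nested variants pin parts of theta:

``full_sarar``
    all parameters free;
``sar_only``
    no spatial structure in the disturbances (``rho2 = 0``);
``sem_only``
    no spatial lag in the response (``rho1 = 0``);
``nonspatial``
    ``rho1 = rho2 = 0`` — the purely dynamic Student-t location filter;
``gaussian_sarar``
    static Gaussian SARAR regression (``nu -> inf``, ``phi = 0``,
    ``K = 0``), the model of classical spatial econometrics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve

from .model import FilterOutput, ModelParameters, PanelData, run_filter, spatial_filter
from .weights import SpatialWeights

__all__ = [
    "VARIANTS",
    "FitResult",
    "FreeParameterLayout",
    "transform_params",
    "untransform_params",
    "negative_loglik",
    "loglik_contributions",
    "gaussian_sarar_loglik",
    "fit_mle",
    "standard_errors",
    "information_criteria",
    "default_start",
]

VARIANTS = ("full_sarar", "sar_only", "sem_only", "nonspatial", "gaussian_sarar")

#: upper bound for log(nu) in the optimizer; hitting it flags the fit as
#: effectively Gaussian.
LOG_NU_BOUND = 30.0

_PENALTY = 1e10


def _atanh(x: float) -> float:
    if not abs(x) < 1:
        raise ValueError(f"value {x} outside (-1, 1)")
    return math.atanh(x)


def _log(x: float) -> float:
    if not x > 0:
        raise ValueError(f"value {x} must be positive")
    return math.log(x)


def _tanh_open(x: float) -> float:
    """tanh clipped strictly inside (-1, 1) so constraints never saturate
    in floating point (tanh(25) rounds to 1.0 exactly)."""
    return min(max(math.tanh(x), -1.0 + 1e-12), 1.0 - 1e-12)


@dataclasses.dataclass(frozen=True)
class FreeParameterLayout:
    """Mapping between the free parameter vector of a variant and theta."""

    variant: str
    R: int
    p: int
    names: tuple[str, ...]
    kinds: tuple[str, ...]  # 'id' | 'atanh' | 'log', aligned with names

    @classmethod
    def for_variant(cls, variant: str, R: int, p: int) -> "FreeParameterLayout":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        names: list[str] = []
        kinds: list[str] = []
        for j in range(p + 1):
            names.append(f"beta{j}")
            kinds.append("id")
        if variant in ("full_sarar", "sar_only", "gaussian_sarar"):
            names.append("rho1")
            kinds.append("atanh")
        if variant in ("full_sarar", "sem_only", "gaussian_sarar"):
            names.append("rho2")
            kinds.append("atanh")
        if variant != "gaussian_sarar":
            names.append("nu")
            kinds.append("log")
        for r in range(R):
            names.append(f"lam{r}")
            kinds.append("id")
        if variant != "gaussian_sarar":
            names.append("phi")
            kinds.append("atanh")
            for r in range(R):
                names.append(f"kappa{r}")
                kinds.append("log")
        return cls(variant, R, p, tuple(names), tuple(kinds))

    @property
    def n_free(self) -> int:
        return len(self.names)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [
            (None, LOG_NU_BOUND) if name == "nu" else (None, None)
            for name in self.names
        ]

    def pack(self, params: ModelParameters) -> np.ndarray:
        """Map a constrained parameter set to the free vector."""
        values = {
            **{f"beta{j}": params.beta[j] for j in range(self.p + 1)},
            "rho1": params.rho1,
            "rho2": params.rho2,
            "nu": params.nu,
            **{f"lam{r}": params.lam[r] for r in range(self.R)},
            "phi": params.phi,
            **{f"kappa{r}": params.kappa[r] for r in range(self.R)},
        }
        out = np.empty(self.n_free)
        for i, (name, kind) in enumerate(zip(self.names, self.kinds)):
            v = float(values[name])
            out[i] = v if kind == "id" else (_atanh(v) if kind == "atanh" else _log(v))
        return out

    def unpack(self, x: np.ndarray) -> ModelParameters:
        """Map a free vector back to constrained parameters (pinned values
        filled per variant)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free parameters, got {x.shape}")
        vals: dict[str, float] = {}
        for name, kind, xi in zip(self.names, self.kinds, x):
            vals[name] = xi if kind == "id" else (
                _tanh_open(xi) if kind == "atanh" else math.exp(xi)
            )
        gaussian = self.variant == "gaussian_sarar"
        return ModelParameters(
            beta=np.array([vals[f"beta{j}"] for j in range(self.p + 1)]),
            rho1=vals.get("rho1", 0.0),
            rho2=vals.get("rho2", 0.0),
            nu=math.inf if gaussian else vals["nu"],
            lam=np.array([vals[f"lam{r}"] for r in range(self.R)]),
            phi=0.0 if gaussian else vals["phi"],
            kappa=np.zeros(self.R)
            if gaussian
            else np.array([vals[f"kappa{r}"] for r in range(self.R)]),
        )

    def natural_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Diagonal of d(constrained)/d(free) at ``x`` (delta method)."""
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for i, kind in enumerate(self.kinds):
            if kind == "id":
                out[i] = 1.0
            elif kind == "atanh":
                out[i] = 1.0 - math.tanh(x[i]) ** 2
            else:
                out[i] = math.exp(x[i])
        return out


def transform_params(params: ModelParameters) -> np.ndarray:
    """Full-model bijection theta -> unconstrained vector."""
    layout = FreeParameterLayout.for_variant(
        "full_sarar", params.n_regions, params.n_covariates
    )
    return layout.pack(params)


def untransform_params(x: np.ndarray, R: int, p: int = 0) -> ModelParameters:
    """Inverse of :func:`transform_params`."""
    return FreeParameterLayout.for_variant("full_sarar", R, p).unpack(x)


def gaussian_sarar_loglik(
    data: PanelData,
    params: ModelParameters,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
) -> np.ndarray:
    """Per-t log-likelihood of the static Gaussian SARAR regression.

    ``y_t ~ N(Z1^{-1} X_t beta, S)`` with
    ``S = Z1^{-1} Z2^{-1} Lambda Z2^{-T} Z1^{-T}``, evaluated through the
    explicit covariance (log-determinant and linear solves on ``S``).
    """
    if W2 is None:
        W2 = W1
    R, T = data.y.shape
    Z1 = spatial_filter(params.rho1, W1)
    Z2 = spatial_filter(params.rho2, W2)
    Z1inv = np.linalg.inv(Z1)
    Z2inv = np.linalg.inv(Z2)
    Lam = np.diag(np.exp(2.0 * params.lam))
    S = Z1inv @ Z2inv @ Lam @ Z2inv.T @ Z1inv.T
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    V = data.y - lu_solve(lu_factor(Z1), (data.X @ params.beta).T)
    quad = np.einsum("rt,rt->t", V, np.linalg.solve(S, V))
    return -0.5 * (R * math.log(2.0 * math.pi) + logdet + quad)


def loglik_contributions(
    x: np.ndarray,
    data: PanelData,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None,
    layout: FreeParameterLayout,
) -> np.ndarray:
    """Per-observation log-likelihood at a free parameter vector."""
    params = layout.unpack(x)
    if layout.variant == "gaussian_sarar":
        return gaussian_sarar_loglik(data, params, W1, W2)
    return run_filter(data, params, W1, W2).loglik_t


def negative_loglik(
    x: np.ndarray,
    data: PanelData,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
    variant: str = "full_sarar",
    layout: FreeParameterLayout | None = None,
) -> float:
    """Objective for the optimizer: ``-loglik`` with a finite penalty on
    numerical failure so quasi-Newton line searches can recover."""
    if layout is None:
        layout = FreeParameterLayout.for_variant(
            variant, data.n_regions, data.X.shape[2] - 1
        )
    try:
        with np.errstate(all="ignore"):
            ll = float(loglik_contributions(x, data, W1, W2, layout).sum())
    except (FloatingPointError, np.linalg.LinAlgError, ValueError, OverflowError):
        return _PENALTY
    if not np.isfinite(ll):
        return _PENALTY
    return -ll


@dataclasses.dataclass
class FitResult:
    """Outcome of :func:`fit_mle`.

    ``se`` and ``free_params`` are aligned with ``layout.names``; ``se`` is
    on the natural (constrained) scale, ``vcov`` on the free scale.
    """

    params_hat: ModelParameters
    loglik: float
    layout: FreeParameterLayout
    free_params: np.ndarray
    se: np.ndarray | None
    vcov: np.ndarray | None
    n_iter: int
    converged: bool
    aic: float
    bic: float
    variant: str
    n_obs: int
    nu_at_bound: bool = False
    se_method: str | None = None
    message: str = ""

    def se_for(self, name: str) -> float:
        if self.se is None:
            raise ValueError("standard errors not computed; call standard_errors()")
        return float(self.se[self.layout.names.index(name)])


def default_start(data: PanelData, layout: FreeParameterLayout) -> np.ndarray:
    """Data-driven starting values.

    beta from pooled least squares of ``y`` on ``X``; ``lam_r`` the log
    sample standard deviation of region ``r``; ``nu = 10``, ``phi = 0.5``,
    ``rho1 = rho2 = 0``, ``kappa_r = 0.1``.
    """
    T, R, k = data.X.shape
    Xf = data.X.reshape(T * R, k)
    yf = data.y.T.reshape(T * R)
    beta0, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    sd = np.std(data.y - (data.X @ beta0).T, axis=1)
    sd = np.maximum(sd, 1e-8)
    start = ModelParameters(
        beta=beta0,
        rho1=0.0,
        rho2=0.0,
        nu=10.0,
        lam=np.log(sd),
        phi=0.5,
        kappa=np.full(R, 0.1),
    )
    return layout.pack(start)


def fit_mle(
    data: PanelData,
    W1: SpatialWeights | np.ndarray,
    W2: SpatialWeights | np.ndarray | None = None,
    variant: str = "full_sarar",
    start: ModelParameters | np.ndarray | None = None,
    n_starts: int = 1,
    rng: np.random.Generator | None = None,
    maxiter: int = 500,
    gtol: float = 1e-6,
    ftol: float = 1e-10,
    compute_se: bool = False,
    se_method: str = "hessian",
) -> FitResult:
    """Maximize the empirical likelihood over the unconstrained space.

    Quasi-Newton (L-BFGS-B) with numerical gradients; optional jittered
    multi-start (``n_starts > 1``).  Non-convergence is reported in the
    result, never silently ignored.
    """
    if W2 is None:
        W2 = W1
    p = data.X.shape[2] - 1
    layout = FreeParameterLayout.for_variant(variant, data.n_regions, p)
    if data.n_times <= layout.n_free:
        raise ValueError(
            f"T={data.n_times} too short for {layout.n_free} free parameters"
        )
    if start is None:
        x0 = default_start(data, layout)
    elif isinstance(start, ModelParameters):
        x0 = layout.pack(start)
    else:
        x0 = np.asarray(start, dtype=float)

    rng = np.random.default_rng(0) if rng is None else rng
    starts = [x0] + [
        x0 + 0.25 * rng.standard_normal(layout.n_free) for _ in range(n_starts - 1)
    ]
    best = None
    for x_init in starts:
        res = optimize.minimize(
            negative_loglik,
            x_init,
            args=(data, W1, W2, variant, layout),
            method="L-BFGS-B",
            bounds=layout.bounds(),
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    x_hat = np.asarray(best.x, dtype=float)
    ll = -float(best.fun)
    k = layout.n_free
    T = data.n_times
    nu_at_bound = False
    if "nu" in layout.names:
        nu_at_bound = bool(x_hat[layout.names.index("nu")] >= LOG_NU_BOUND - 1e-8)
    fit = FitResult(
        params_hat=layout.unpack(x_hat),
        loglik=ll,
        layout=layout,
        free_params=x_hat,
        se=None,
        vcov=None,
        n_iter=int(best.nit),
        converged=bool(best.success),
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(T),
        variant=variant,
        n_obs=T,
        nu_at_bound=nu_at_bound,
        message=str(best.message),
    )
    if compute_se:
        fit = standard_errors(fit, data, W1, W2, method=se_method)
    return fit


def _nll(x, data, W1, W2, layout):
    return negative_loglik(x, data, W1, W2, layout.variant, layout)


def _numeric_hessian(f, x, h_scale=1e-4):
    """Central fourth-point Hessian of a scalar function."""
    k = x.size
    h = h_scale * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        f0 = f(x)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4.0 * h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def score_contributions(
    x: np.ndarray,
    data: PanelData,
    W1,
    W2,
    layout: FreeParameterLayout,
    h_scale: float = 1e-5,
) -> np.ndarray:
    """Per-t score vectors (k x T) by central differences of the
    per-observation log-likelihood contributions."""
    k = x.size
    h = h_scale * np.maximum(1.0, np.abs(x))
    S = np.empty((k, data.n_times))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        lp = loglik_contributions(x + ei, data, W1, W2, layout)
        lm = loglik_contributions(x - ei, data, W1, W2, layout)
        S[i] = (lp - lm) / (2.0 * h[i])
    return S


def _safe_inverse(M: np.ndarray, what: str) -> np.ndarray:
    eigs = np.linalg.eigvalsh((M + M.T) / 2.0)
    if np.min(eigs) <= 0:
        warnings.warn(
            f"{what} not positive definite (min eigenvalue {np.min(eigs):.3g}); "
            "using pseudo-inverse",
            RuntimeWarning,
        )
        return np.linalg.pinv(M)
    return np.linalg.inv(M)


def standard_errors(
    fit: FitResult,
    data: PanelData,
    W1,
    W2=None,
    method: str = "hessian",
) -> FitResult:
    """Attach asymptotic standard errors to a converged fit.

    ``hessian``: inverse numeric Hessian of the negative log-likelihood;
    ``opg``: inverse outer product of per-t score contributions;
    ``sandwich``: ``H^{-1} G H^{-1}``.  Free-scale covariance is mapped to
    the natural scale by the delta method.
    """
    if method not in ("hessian", "opg", "sandwich"):
        raise ValueError(f"unknown SE method {method!r}")
    if W2 is None:
        W2 = W1
    x = fit.free_params
    layout = fit.layout
    if method in ("hessian", "sandwich"):
        H = _numeric_hessian(lambda z: _nll(z, data, W1, W2, layout), x)
        Hinv = _safe_inverse(H, "numeric Hessian")
    if method in ("opg", "sandwich"):
        S = score_contributions(x, data, W1, W2, layout)
        G = S @ S.T
    if method == "hessian":
        vcov = Hinv
    elif method == "opg":
        vcov = _safe_inverse(G, "outer product of gradients")
    else:
        vcov = Hinv @ G @ Hinv
    J = layout.natural_jacobian(x)
    var_nat = J * np.diag(vcov) * J
    se = np.sqrt(np.maximum(var_nat, 0.0))
    return dataclasses.replace(fit, se=se, vcov=vcov, se_method=method)


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) with ``k`` the number of free parameters of the variant."""
    k = fit.layout.n_free
    return (-2.0 * fit.loglik + 2.0 * k, -2.0 * fit.loglik + k * math.log(fit.n_obs))
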