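"""Exact data-generating process of the score-driven SARAR Student-t model.

The latent signal follows the stationary stochastic recurrence

    mu_{t+1} = phi mu_t + K eta_t / (1 + eta_t' Lambda^{-1} eta_t / nu),

driven by the same innovations that enter the observations,

    eps_t = Z2^{-1} eta_t,        y_t = Z1^{-1} (X_t beta + mu_t + eps_t),

with ``eta_t ~ iid t_nu(0, Lambda)`` drawn through the normal/chi-square
scale mixture.  Under ``|phi| < 1`` and positive ``kappa`` the generated
panel is strictly stationary and ergodic; a burn-in discards the
transient from the ``mu_0 = 0`` start.

A Gaussian noise family is included for misspecification experiments
(fitting the Student-t model to thin-tailed data).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import ModelParameters, PanelData, spatial_filter
from .weights import SpatialWeights

__all__ = ["SimulationConfig", "sample_noise", "make_covariates", "simulate_panel"]

COVARIATE_DESIGNS = ("intercept_only", "intercept_plus_noise", "intercept_plus_boxcar")
NOISE_FAMILIES = ("student_t", "gaussian")

#: period of the boxcar stimulus regressor (20 steps on, 20 off)
BOXCAR_HALF_PERIOD = 20


@dataclasses.dataclass
class SimulationConfig:
    """Settings of one simulated panel.

    ``burn_in`` defaults to 500 steps, long enough for the geometric
    memory of the signal recursion to fade at ``|phi| <= 0.9``.
    """

    params: ModelParameters
    W1: SpatialWeights
    W2: SpatialWeights | None = None
    T: int = 500
    burn_in: int = 500
    covariate_design: str = "intercept_only"
    noise_family: str = "student_t"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.covariate_design not in COVARIATE_DESIGNS:
            raise ValueError(f"unknown covariate design {self.covariate_design!r}")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if self.W2 is None:
            self.W2 = self.W1


def sample_noise(
    lam: np.ndarray,
    nu: float,
    family: str = "student_t",
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw innovation vectors ``eta ~ t_nu(0, Lambda)`` or ``N(0, Lambda)``.

    The Student-t draw uses the scale-mixture construction
    ``eta = z * sqrt(nu / g)`` with ``z ~ N(0, Lambda)`` and
    ``g ~ chi^2_nu``, so each component has variance
    ``exp(2 lam_r) * nu / (nu - 2)`` when ``nu > 2``.

    Returns an ``R``-vector, or an ``R x size`` matrix when ``size`` is
    given.
    """
    rng = np.random.default_rng() if rng is None else rng
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    R = lam.shape[0]
    n = 1 if size is None else size
    z = np.exp(lam)[:, None] * rng.standard_normal((R, n))
    if family == "student_t":
        if not nu > 0:
            raise ValueError(f"nu must be > 0, got {nu}")
        g = rng.chisquare(nu, size=n)
        eta = z * np.sqrt(nu / g)[None, :]
    elif family == "gaussian":
        eta = z
    else:
        raise ValueError(f"unknown noise family {family!r}")
    return eta[:, 0] if size is None else eta


def make_covariates(
    R: int,
    T: int,
    design: str = "intercept_only",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build a (T, R, p+1) covariate array for the requested design.

    ``intercept_only`` gives the all-ones column; ``intercept_plus_noise``
    adds a fixed smooth sinusoidal regressor (common across regions);
    ``intercept_plus_boxcar`` adds a 0/1 block stimulus that switches every
    20 steps, mimicking a task-based experimental design.
    """
    if R < 1 or T < 1:
        raise ValueError("R and T must be positive")
    ones = np.ones((T, R, 1))
    if design == "intercept_only":
        return ones
    if design == "intercept_plus_noise":
        t = np.arange(T)
        reg = np.sin(2.0 * np.pi * t / 50.0) + 0.5 * np.cos(2.0 * np.pi * t / 17.0)
        X = np.concatenate([ones, np.broadcast_to(reg[:, None, None], (T, R, 1))], axis=2)
        return np.ascontiguousarray(X)
    if design == "intercept_plus_boxcar":
        t = np.arange(T)
        box = ((t // BOXCAR_HALF_PERIOD) % 2 == 1).astype(float)
        X = np.concatenate([ones, np.broadcast_to(box[:, None, None], (T, R, 1))], axis=2)
        return np.ascontiguousarray(X)
    raise ValueError(f"unknown covariate design {design!r}")


def simulate_panel(cfg: SimulationConfig) -> PanelData:
    """Generate a panel from the model's exact data-generating process.

    Iterates the latent recursion from ``mu_0 = 0`` over ``burn_in + T``
    steps, maps the innovations through the spatial filters, and returns
    the observed panel together with the latent signal path.  Fully
    reproducible from ``cfg.seed``.
    """
    p = cfg.params.validate()
    rng = np.random.default_rng(cfg.seed)
    R = p.n_regions
    if cfg.W1.n_regions != R:
        raise ValueError("weight matrix size does not match parameters")
    Z1 = spatial_filter(p.rho1, cfg.W1)
    Z2 = spatial_filter(p.rho2, cfg.W2)
    n_total = cfg.burn_in + cfg.T
    X = make_covariates(R, cfg.T, cfg.covariate_design, rng)
    if X.shape[2] != p.beta.shape[0]:
        raise ValueError(
            f"design {cfg.covariate_design!r} has {X.shape[2]} columns, "
            f"beta has {p.beta.shape[0]}"
        )
    eta = sample_noise(p.lam, p.nu, cfg.noise_family, rng, size=n_total)
    lam_inv2 = np.exp(-2.0 * p.lam)

    mu = np.zeros(R)
    mu_path = np.empty((R, cfg.T))
    y = np.empty((R, cfg.T))
    for t in range(n_total):
        s = t - cfg.burn_in
        if s >= 0:
            mu_path[:, s] = mu
            eps = np.linalg.solve(Z2, eta[:, t])
            y[:, s] = np.linalg.solve(Z1, X[s] @ p.beta + mu + eps)
        if cfg.noise_family == "student_t":
            q = float(eta[:, t] @ (lam_inv2 * eta[:, t])) / p.nu
            mu = p.phi * mu + p.kappa * eta[:, t] / (1.0 + q)
        else:
            # Gaussian limit of the score update: alpha_t -> 1
            mu = p.phi * mu + p.kappa * eta[:, t]
    return PanelData(y=y, X=X, latent_mu=mu_path)
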