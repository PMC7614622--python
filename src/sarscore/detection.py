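"""Detection of spontaneous activations from robust filter residuals.

The robust filter leaves the information on anomalous observations in the
spatial prediction errors ``Z1 v_t`` (or ``Z2 Z1 v_t`` when a spatial
error component is present), while the winsorized scores ``u_t`` are
thin-tailed by construction.  An activation at region ``r`` and time ``t``
is declared when the residual exceeds an empirical quantile threshold of
the rescaled score series ``kappa~_r u_{r,t}``, with
``kappa~_r = max(kappa_hat_r, 1)`` a conservative floor on the loading,
and quantile levels Bonferroni-corrected over the ``R`` simultaneous
two-sided comparisons made at each time step: levels ``alpha/(2R)`` and
``1 - alpha/(2R)``.  In the effectively Gaussian limit the scores equal
the residuals and the rule collapses to residual self-quantiles.

Co-activation of two regions is summarized by the Dice similarity of
their binary activation series.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .estimation import FitResult
from .model import FilterOutput, spatial_filter

__all__ = [
    "ActivationMap",
    "detection_thresholds",
    "detect_activations",
    "dice_index",
    "dice_matrix",
]

#: empirical quantile interpolation rule, fixed for reproducibility
QUANTILE_METHOD = "median_unbiased"


@dataclasses.dataclass
class ActivationMap:
    """Binary exceedance matrix with the thresholds that produced it."""

    flags: np.ndarray  # R x T, values in {0, 1}
    thresholds_low: np.ndarray
    thresholds_high: np.ndarray
    alpha_level: float
    kappa_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags)
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be binary")

    @property
    def n_activations(self) -> int:
        return int(self.flags.sum())


def detection_thresholds(
    u: np.ndarray,
    kappa_hat: np.ndarray,
    alpha: float,
    pooled: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-corrected quantile thresholds of the rescaled scores.

    For each region the series ``kappa~_r u_{r,t}`` is reduced to its
    empirical quantiles at levels ``alpha/(2R)`` and ``1 - alpha/(2R)``
    (median-unbiased interpolation).  With ``pooled=True`` the quantiles
    are computed on all regions jointly and shared.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("u must be an R x T matrix")
    R, T = u.shape
    if T < 20:
        raise ValueError(f"need T >= 20 time points for quantiles, got {T}")
    kt = np.maximum(np.atleast_1d(np.asarray(kappa_hat, float)), 1.0)
    if kt.shape != (R,):
        raise ValueError("kappa_hat must be an R-vector")
    scaled = kt[:, None] * u
    lo_level = alpha / (2.0 * R)
    hi_level = 1.0 - lo_level
    if pooled:
        lo, hi = np.quantile(scaled, [lo_level, hi_level], method=QUANTILE_METHOD)
        return np.full(R, lo), np.full(R, hi)
    lo = np.quantile(scaled, lo_level, axis=1, method=QUANTILE_METHOD)
    hi = np.quantile(scaled, hi_level, axis=1, method=QUANTILE_METHOD)
    return lo, hi


def detect_activations(
    filter_out: FilterOutput,
    fit: FitResult | np.ndarray,
    alpha: float = 0.05,
    W1=None,
    W2=None,
    pooled: bool = False,
) -> ActivationMap:
    """Flag residual exceedances of the score-quantile thresholds.

    ``fit`` supplies the estimated loadings ``kappa_hat`` (an R-vector may
    be passed directly) and, when it is a :class:`FitResult`, the spatial
    parameters used to build the residuals: ``Z1 v_t`` for variants
    without a spatial error component, ``Z2 Z1 v_t`` for the full SARAR
    model (then ``W2`` is required).  ``W1`` is required whenever
    ``rho1 != 0``.
    """
    if isinstance(fit, FitResult):
        kappa_hat = fit.params_hat.kappa
        rho1, rho2 = fit.params_hat.rho1, fit.params_hat.rho2
        use_z2 = fit.variant in ("full_sarar", "sem_only") and rho2 != 0.0
    else:
        kappa_hat = np.asarray(fit, dtype=float)
        rho1, rho2, use_z2 = 0.0, 0.0, False
    R, T = filter_out.v.shape
    if rho1 != 0.0 and W1 is None:
        raise ValueError("W1 required to build residuals when rho1 != 0")
    Z1 = spatial_filter(rho1, W1) if rho1 != 0.0 else np.eye(R)
    resid = Z1 @ filter_out.v
    if use_z2:
        if W2 is None:
            raise ValueError("W2 required for the spatial-error residuals")
        resid = spatial_filter(rho2, W2) @ resid
    if resid.shape != filter_out.u.shape:
        raise ValueError("residual and score shapes disagree")
    lo, hi = detection_thresholds(filter_out.u, kappa_hat, alpha, pooled=pooled)
    flags = ((resid < lo[:, None]) | (resid > hi[:, None])).astype(np.int8)
    return ActivationMap(
        flags=flags,
        thresholds_low=lo,
        thresholds_high=hi,
        alpha_level=alpha,
        kappa_tilde=np.maximum(kappa_hat, 1.0),
    )


def dice_index(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity ``2 |a AND b| / (|a| + |b|)`` of two binary series.

    Returns ``nan`` (with a warning) when both series are all-zero, where
    the index is undefined.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice index undefined for two empty series", RuntimeWarning)
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def dice_matrix(act: ActivationMap) -> np.ndarray:
    """Pairwise Dice similarity of region activation series (symmetric R x R).

    The diagonal is 1 where a region has any activation and ``nan`` where
    the index is undefined (no activations at all).
    """
    flags = act.flags
    R = flags.shape[0]
    M = np.empty((R, R))
    counts = flags.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(R):
            M[i, i] = 1.0 if counts[i] > 0 else float("nan")
            for j in range(i + 1, R):
                M[i, j] = M[j, i] = dice_index(flags[i], flags[j])
    return M
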