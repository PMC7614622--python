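"""CSV/JSON input-output for panels, filter paths, and fit results.

Orientation convention: panel CSV files are region-by-time (R rows, T
columns), matching the in-memory layout.  Fit results round-trip through
a schema-versioned JSON document.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings

import numpy as np
import pandas as pd

from .estimation import FitResult, FreeParameterLayout
from .model import FilterOutput, ModelParameters, PanelData

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_panel",
    "write_panel",
    "write_fit",
    "read_fit",
    "write_filter_output",
    "file_sha256",
    "FIT_SCHEMA",
]

FIT_SCHEMA = "sarscore-fit/1"


def read_matrix_csv(path) -> np.ndarray:
    """Read a numeric matrix from headerless CSV; NaN or non-numeric cells
    raise with (row, column) coordinates."""
    try:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed CSV ({exc})") from exc
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"{path}: non-numeric or NaN cell at (row {r}, col {c})")
    return arr


def write_matrix_csv(M: np.ndarray, path) -> None:
    """Write a matrix to headerless CSV at full precision."""
    M = np.atleast_2d(np.asarray(M))
    with open(path, "w") as fh:
        for row in M:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_panel(y_path, x_dir=None) -> PanelData:
    """Load observations (R x T CSV) and optional covariates.

    ``x_dir`` may hold one design per time step (``X_0000.csv`` ...,
    each R x (p+1)) or a single ``X.csv`` broadcast over time; absent, the
    design is intercept-only.
    """
    y = read_matrix_csv(y_path)
    R, T = y.shape
    if x_dir is None:
        return PanelData(y=y)
    x_dir = pathlib.Path(x_dir)
    per_t = sorted(x_dir.glob("X_*.csv"))
    if per_t:
        if len(per_t) != T:
            raise ValueError(f"{x_dir}: found {len(per_t)} X files for T={T}")
        X = np.stack([read_matrix_csv(p) for p in per_t])
    else:
        static = x_dir / "X.csv"
        if not static.exists():
            raise FileNotFoundError(f"no X_*.csv or X.csv in {x_dir}")
        Xs = read_matrix_csv(static)
        X = np.broadcast_to(Xs, (T,) + Xs.shape).copy()
    return PanelData(y=y, X=X)


def write_panel(data: PanelData, out_dir, static_x: bool | None = None) -> None:
    """Write ``y.csv`` (and covariates / latent signal when present)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(data.y, out / "y.csv")
    if static_x is None:
        static_x = bool(np.all(data.X == data.X[0]))
    if static_x:
        write_matrix_csv(data.X[0], out / "X.csv")
    else:
        for t in range(data.X.shape[0]):
            write_matrix_csv(data.X[t], out / f"X_{t:04d}.csv")
    if data.latent_mu is not None:
        write_matrix_csv(data.latent_mu, out / "mu_latent.csv")


def write_filter_output(fo: FilterOutput, out_dir) -> None:
    """One CSV per filter field, region-by-time orientation."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(fo.mu_pred, out / "mu_pred.csv")
    write_matrix_csv(fo.v, out / "v.csv")
    write_matrix_csv(fo.u, out / "u.csv")
    write_matrix_csv(fo.alpha, out / "alpha.csv")
    write_matrix_csv(fo.b, out / "b.csv")
    write_matrix_csv(fo.loglik_t, out / "loglik_t.csv")


_REQUIRED_FIT_KEYS = {
    "schema",
    "variant",
    "params",
    "loglik",
    "free_params",
    "layout",
    "n_iter",
    "converged",
    "aic",
    "bic",
    "n_obs",
    "nu_at_bound",
    "se",
    "vcov",
    "se_method",
    "message",
}


def write_fit(fit: FitResult, path) -> None:
    """Serialize a fit result to schema-versioned JSON (lossless)."""
    p = fit.params_hat
    doc = {
        "schema": FIT_SCHEMA,
        "variant": fit.variant,
        "params": {
            "beta": p.beta.tolist(),
            "rho1": p.rho1,
            "rho2": p.rho2,
            "nu": "inf" if np.isinf(p.nu) else p.nu,
            "lam": p.lam.tolist(),
            "phi": p.phi,
            "kappa": p.kappa.tolist(),
        },
        "loglik": fit.loglik,
        "free_params": fit.free_params.tolist(),
        "layout": {"R": fit.layout.R, "p": fit.layout.p},
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "nu_at_bound": fit.nu_at_bound,
        "se": None if fit.se is None else fit.se.tolist(),
        "vcov": None if fit.vcov is None else fit.vcov.tolist(),
        "se_method": fit.se_method,
        "message": fit.message,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_fit(path) -> FitResult:
    """Inverse of :func:`write_fit`; unknown keys warn, missing keys raise."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != FIT_SCHEMA:
        raise ValueError(f"unknown fit schema {doc.get('schema')!r}")
    missing = _REQUIRED_FIT_KEYS - doc.keys()
    if missing:
        raise ValueError(f"fit file missing fields: {sorted(missing)}")
    extra = doc.keys() - _REQUIRED_FIT_KEYS
    if extra:
        warnings.warn(f"ignoring unknown fit fields: {sorted(extra)}", RuntimeWarning)
    pd_ = doc["params"]
    params = ModelParameters(
        beta=np.asarray(pd_["beta"], float),
        rho1=float(pd_["rho1"]),
        rho2=float(pd_["rho2"]),
        nu=float("inf") if pd_["nu"] == "inf" else float(pd_["nu"]),
        lam=np.asarray(pd_["lam"], float),
        phi=float(pd_["phi"]),
        kappa=np.asarray(pd_["kappa"], float),
    )
    layout = FreeParameterLayout.for_variant(
        doc["variant"], int(doc["layout"]["R"]), int(doc["layout"]["p"])
    )
    return FitResult(
        params_hat=params,
        loglik=float(doc["loglik"]),
        layout=layout,
        free_params=np.asarray(doc["free_params"], float),
        se=None if doc["se"] is None else np.asarray(doc["se"], float),
        vcov=None if doc["vcov"] is None else np.asarray(doc["vcov"], float),
        n_iter=int(doc["n_iter"]),
        converged=bool(doc["converged"]),
        aic=float(doc["aic"]),
        bic=float(doc["bic"]),
        variant=doc["variant"],
        n_obs=int(doc["n_obs"]),
        nu_at_bound=bool(doc["nu_at_bound"]),
        se_method=doc["se_method"],
        message=doc["message"],
    )


def file_sha256(path) -> str:
    """Provenance hash of an input file."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
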