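"""Proportion estimation: fit bulk ~ C @ p with five solver families.

All solvers share the same post-processing: raw coefficients are clipped at
zero and normalized to the simplex; an all-zero raw vector falls back to
uniform proportions with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from sklearn.svm import NuSVR

from .signature import SignatureMatrix

__all__ = ["SolverConfig", "ProportionTable", "deconvolve_sample", "deconvolve_cohort", "METHODS"]

METHODS = ("ols", "nnls", "rlr", "nusvr", "dwls")


@dataclass(frozen=True)
class SolverConfig:
    method: str = "nnls"
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    huber_k: float = 1.345
    dwls_damping_grid: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    dwls_floor: float = 1e-6
    standardize: bool = True  # nusvr only

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not all(0 < nu < 1 for nu in self.nu_grid):
            raise ValueError("nu_grid values must lie in (0, 1)")
        if self.huber_k <= 0:
            raise ValueError("huber_k must be positive")


@dataclass
class ProportionTable:
    """Samples x cell types simplex rows plus pre-clipping raw coefficients."""

    values: pd.DataFrame
    method_name: str
    raw_coefficients: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each proportion row must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.values.columns)


def _match_genes(sig: SignatureMatrix, bulk: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if bulk.index.duplicated().any():
        warnings.warn("duplicated gene ids in bulk collapsed by mean", stacklevel=3)
        bulk = bulk.groupby(level=0).mean()
    shared = [g for g in sig.gene_ids if g in bulk.index]
    K = len(sig.cell_type_ids)
    if len(shared) < K:
        raise ValueError(
            f"only {len(shared)} genes shared between signature and bulk; need >= {K}"
        )
    return sig.values.loc[shared].to_numpy(dtype=float), bulk.loc[shared].to_numpy(dtype=float)


def _fit_ols(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("signature matrix is rank-deficient for OLS; try method='nnls'")
    coef, *_ = np.linalg.lstsq(C, b, rcond=None)
    return coef


def _fit_nnls(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    coef, _ = scipy.optimize.nnls(C, b)
    return coef


def _fit_rlr(C: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    if C.shape[0] <= C.shape[1]:  # no residual dof: Huber scale undefined
        return _fit_ols(C, b)
    scale = np.linalg.norm(b)
    if scale == 0:
        return np.zeros(C.shape[1])
    # fit on the unit-norm bulk so the absolute convergence tolerance does
    # not make the iteration path scale-dependent
    model = sm.RLM(b / scale, C, M=sm.robust.norms.HuberT(t=k))
    res = model.fit(maxiter=100, tol=1e-6)
    return np.asarray(res.params) * scale


def _fit_nusvr(C: np.ndarray, b: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    if cfg.standardize:
        # global (not per-column) standardization keeps the columns' relative
        # scales, so the SVR weights stay proportional to the mixing vector
        s = C.std() if C.std() > 0 else 1.0
        Cs = (C - C.mean()) / s
        bs = (b - b.mean()) / (b.std() if b.std() > 0 else 1.0)
    else:
        Cs, bs = C, b
    best_coef, best_rmse = None, np.inf
    for nu in cfg.nu_grid:
        svr = NuSVR(kernel="linear", nu=nu, C=1.0)
        svr.fit(Cs, bs)
        coef = np.asarray(svr.coef_).ravel()
        rmse = float(np.sqrt(np.mean((Cs @ coef - bs) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_coef = rmse, coef
    return best_coef


def _fit_dwls(C: np.ndarray, b: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    """Iterated weighted NNLS from the plain-NNLS start, weights 1/fitted^2.

    The weight dynamic range is capped at the damping constant; the
    constant minimizing the unweighted reconstruction error wins.
    """
    p0 = _fit_nnls(C, b)
    best_coef, best_err = p0, float(np.linalg.norm(C @ p0 - b))
    for damping in cfg.dwls_damping_grid:
        p = p0.copy()
        for _ in range(100):
            fitted = np.maximum(C @ p, cfg.dwls_floor)
            w = 1.0 / fitted**2
            w = np.minimum(w, damping * w.min())
            sw = np.sqrt(w)
            p_new = _fit_nnls(C * sw[:, None], b * sw)
            if np.max(np.abs(p_new - p)) < 1e-8:
                p = p_new
                break
            p = p_new
        err = float(np.linalg.norm(C @ p - b))
        if err < best_err:
            best_err, best_coef = err, p
    return best_coef


def deconvolve_sample(
    sig: SignatureMatrix, bulk_column: pd.Series, cfg: SolverConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate one sample's cell-type proportions.

    Returns ``(proportions, raw_coefficients)`` over ``sig.cell_type_ids``;
    proportions are the raw coefficients clipped at zero and renormalized.
    """
    cfg = cfg or SolverConfig()
    cfg.validate()
    C, b = _match_genes(sig, bulk_column)

    if cfg.method == "ols":
        raw = _fit_ols(C, b)
    elif cfg.method == "nnls":
        raw = _fit_nnls(C, b)
    elif cfg.method == "rlr":
        raw = _fit_rlr(C, b, cfg.huber_k)
    elif cfg.method == "nusvr":
        raw = _fit_nusvr(C, b, cfg)
    else:
        raw = _fit_dwls(C, b, cfg)

    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        warnings.warn("all-zero raw coefficient vector; falling back to uniform", stacklevel=2)
        p = np.full(len(raw), 1.0 / len(raw))
    else:
        p = clipped / total
    return p, raw


def deconvolve_cohort(
    sig: SignatureMatrix, bulk: pd.DataFrame, cfg: SolverConfig | None = None
) -> ProportionTable:
    """Column-wise deconvolution of a genes x samples bulk matrix."""
    cfg = cfg or SolverConfig()
    cfg.validate()
    if bulk.shape[1] < 1:
        raise ValueError("bulk matrix must contain at least one sample")
    props, raws = [], []
    for sid in bulk.columns:
        try:
            p, raw = deconvolve_sample(sig, bulk[sid], cfg)
        except Exception as exc:
            raise RuntimeError(f"deconvolution failed for sample {sid!r}: {exc}") from exc
        props.append(p)
        raws.append(raw)
    types = sig.cell_type_ids
    return ProportionTable(
        values=pd.DataFrame(props, index=bulk.columns, columns=types),
        method_name=cfg.method,
        raw_coefficients=pd.DataFrame(raws, index=bulk.columns, columns=types),
    )
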