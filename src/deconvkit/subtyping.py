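"""Unsupervised subtype discovery.

Highly-variable-gene selection (binned mean/dispersion), feature scaling,
NMF consensus clustering over random restarts, cophenetic-coefficient rank
selection, and construction of integrated multi-cell-type profiles from an
imputed expression cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .imputation import CellTypeExpressionCube

__all__ = [
    "HvgConfig",
    "ConsensusResult",
    "select_hvgs",
    "nmf_consensus",
    "choose_k",
    "build_integrated_profile",
    "scan_dispersion_cutoff",
]


@dataclass(frozen=True)
class HvgConfig:
    mean_cutoff: float = 0.5
    dispersion_cutoff: float = 1.0
    n_bins: int = 20

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples in [0, 1]
    cophenetic_cc: float
    labels: pd.Series  # cluster id (1..k) per sample
    n_runs: int
    seed: int


def select_hvgs(expr: pd.DataFrame, cfg: HvgConfig | None = None) -> list[str]:
    """Highly variable genes by within-bin dispersion z-score on log1p values.

    Per gene: mean and dispersion (variance/mean) of log1p values; genes
    are split into ``n_bins`` equal-frequency bins by mean and the
    dispersion is z-scored within each bin. Kept genes satisfy
    mean > mean_cutoff and scaled dispersion > dispersion_cutoff.
    """
    cfg = cfg or HvgConfig()
    cfg.validate()
    logx = np.log1p(expr.to_numpy(dtype=float))
    mean = logx.mean(axis=1)
    var = logx.var(axis=1, ddof=1) if logx.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    nonzero_var = var > 0
    if nonzero_var.sum() < cfg.n_bins:
        raise ValueError(f"need at least n_bins={cfg.n_bins} genes with non-zero variance")

    bins = pd.qcut(mean, q=cfg.n_bins, labels=False, duplicates="drop")
    scaled = np.zeros_like(disp)
    for b in np.unique(bins):
        mask = bins == b
        mu, sd = disp[mask].mean(), disp[mask].std(ddof=0)
        scaled[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0

    keep = (mean > cfg.mean_cutoff) & (scaled > cfg.dispersion_cutoff) & nonzero_var
    selected = list(expr.index[keep])
    if not selected:
        raise ValueError(
            "no highly variable genes selected; lower mean_cutoff or dispersion_cutoff"
        )
    return selected


def _to_nonnegative(X: np.ndarray, mode: str) -> np.ndarray:
    """Map signed scaled data to the non-negative domain NMF requires.

    ``"double"`` stacks the positive and negative parts as separate feature
    rows, so up- and down-patterns each get a clean parts-based encoding;
    ``"shift"`` subtracts each row's minimum, which leaves a large shared
    baseline that the factorization must also explain and makes the argmax
    cluster assignment unreliable on signed data.
    """
    if mode == "double":
        return np.vstack([np.clip(X, 0.0, None), np.clip(-X, 0.0, None)])
    if mode == "shift":
        return X - X.min(axis=1, keepdims=True)
    raise ValueError("nonneg mode must be 'double' or 'shift'")


def nmf_consensus(
    expr_scaled: pd.DataFrame,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    nonneg: str = "double",
) -> ConsensusResult:
    """Consensus clustering from repeated randomly initialized NMF runs.

    Each run factorizes the non-negative-mapped features x samples matrix
    with a multiplicative-update Frobenius NMF and assigns every sample to
    its argmax coefficient row; run-level connectivity matrices are
    averaged into the consensus. Final labels come from average-linkage
    hierarchical clustering of ``1 - consensus``; the cophenetic
    coefficient correlates those distances with the dendrogram's cophenetic
    distances.
    """
    S = expr_scaled.shape[1]
    if not 2 <= k < S:
        raise ValueError("need 2 <= k < n_samples")
    X = _to_nonnegative(expr_scaled.to_numpy(dtype=float), nonneg)
    rng = np.random.default_rng(seed)

    consensus = np.zeros((S, S))
    n_kept = 0
    for _ in range(n_runs):
        rs = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=500,
            tol=1e-5,
            random_state=rs,
        )
        # the iteration cap is a budget, not a failure criterion: a run at the
        # cap is near-stationary and still usable; only degenerate output
        # (non-finite factors) is discarded
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X)
        if not np.isfinite(model.components_).all():
            warnings.warn(f"NMF run (random_state={rs}) produced non-finite factors; discarded")
            continue
        H = model.components_  # k x samples
        assign = H.argmax(axis=0)
        conn = (assign[:, None] == assign[None, :]).astype(float)
        consensus += conn
        n_kept += 1
    if n_kept < n_runs / 2:
        raise RuntimeError(f"more than half of the NMF runs were degenerate ({n_kept}/{n_runs})")
    consensus /= n_kept
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    condensed = ssd.squareform(dist, checks=False)
    Z = sch.linkage(condensed, method="average")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    coph_dists = sch.cophenet(Z)
    if np.std(condensed) == 0 or np.std(coph_dists) == 0:
        cc = 1.0  # perfectly consistent consensus: distances are exactly reproduced
    else:
        cc = float(scipy.stats.pearsonr(condensed, coph_dists).statistic)

    samples = list(expr_scaled.columns)
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cophenetic_cc=cc,
        labels=pd.Series(labels, index=samples, name="cluster"),
        n_runs=n_kept,
        seed=seed,
    )


def choose_k(cc_by_k: dict[int, float], drop_tol: float = 0.05) -> int:
    """Largest k whose cophenetic coefficients have not yet dropped.

    Chosen k is the largest k such that cc(j) >= cc(k_min) - drop_tol for
    every j <= k in the map; if the curve never drops, the maximum of the
    range is returned with a warning.
    """
    if not cc_by_k:
        raise ValueError("empty cophenetic map")
    ks = sorted(cc_by_k)
    ref = cc_by_k[ks[0]]
    chosen = ks[0]
    for k in ks:
        if cc_by_k[k] >= ref - drop_tol:
            chosen = k
        else:
            break
    if chosen == ks[-1]:
        warnings.warn("cophenetic coefficient never dropped; returning the largest k scanned")
    return chosen


def build_integrated_profile(
    cube: CellTypeExpressionCube,
    cell_types: list[str],
    hvg_cfg: HvgConfig | None = HvgConfig(),
    exclusivity_ratio: float | None = None,
    center_blocks: bool = True,
    clip: float | None = 2.5,
) -> pd.DataFrame:
    """Concatenate per-type slices of the cube into one features x samples
    matrix with ``celltype:gene`` feature ids.

    Each slice is log1p-transformed (HVG statistics are computed on the
    same scale) and every feature row is z-scored, mirroring the
    log-normalize -> HVG -> scale convention of single-cell workflows.
    ``hvg_cfg=None`` skips the HVG filter and keeps every surviving gene.

    ``exclusivity_ratio`` keeps a gene in a type's block only if that
    type's sample-averaged imputed expression exceeds the second-highest
    type's by the given factor — imputed profiles are only reliable for
    genes a cell type expresses distinctly. ``center_blocks`` subtracts the
    per-sample mean inside each block, removing sample-level allocation
    factors that are deconvolution artifacts rather than biology. ``clip``
    winsorizes z-scores (then re-standardizes) so heavy-tailed imputation
    noise cannot dominate a feature's variance.
    """
    missing = [ct for ct in cell_types if ct not in cube.cell_type_ids]
    if missing:
        raise ValueError(f"cell types not in cube: {missing}")
    mean_prof = cube.mean_profiles() if exclusivity_ratio is not None else None

    blocks = []
    for ct in cell_types:
        sl = cube.slice_type(ct)
        sl = sl.dropna(axis=0, how="any")
        if exclusivity_ratio is not None and not sl.empty:
            m = mean_prof.loc[sl.index]
            own = m[ct]
            second = m.drop(columns=[ct]).max(axis=1)
            sl = sl.loc[own >= exclusivity_ratio * (second + 1e-12)]
        if sl.empty:
            warnings.warn(f"cell type {ct!r} has no usable genes; omitted")
            continue
        if hvg_cfg is not None:
            try:
                sl = sl.loc[select_hvgs(sl, hvg_cfg)]
            except ValueError:
                warnings.warn(f"cell type {ct!r} contributed zero HVGs; omitted")
                continue
        block = np.log1p(sl)
        if center_blocks:
            block = block - block.mean(axis=0)
        block.index = [f"{ct}:{g}" for g in sl.index]
        blocks.append(block)
    if not blocks:
        raise ValueError("no cell type contributed any feature")

    prof = pd.concat(blocks, axis=0)
    vals = prof.to_numpy(dtype=float)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd
    if clip is not None:  # winsorize like ScaleData's clip.max; no re-scaling
        vals = np.clip(vals, -clip, clip)
    return pd.DataFrame(vals, index=prof.index, columns=prof.columns)


def scan_dispersion_cutoff(
    cube: CellTypeExpressionCube,
    cell_types: list[str],
    cutoffs=tuple(np.round(np.arange(1.0, 2.51, 0.1), 1)),
    k_range: range = range(2, 11),
    n_runs: int = 30,
    seed: int = 0,
    drop_tol: float = 0.05,
) -> tuple[float, int, dict[int, float]]:
    """Scan HVG dispersion cutoffs; keep the one whose chosen k has the
    highest cophenetic coefficient (ties go to the larger cutoff)."""
    best = None
    for cutoff in cutoffs:
        cfg = HvgConfig(dispersion_cutoff=float(cutoff))
        try:
            prof = build_integrated_profile(cube, cell_types, cfg)
        except ValueError:
            continue
        cc_by_k = {}
        for k in k_range:
            if k >= prof.shape[1]:
                break
            cc_by_k[k] = nmf_consensus(prof, k, n_runs=n_runs, seed=seed).cophenetic_cc
        if not cc_by_k:
            continue
        k_star = choose_k(cc_by_k, drop_tol)
        score = (cc_by_k[k_star], float(cutoff))
        if best is None or score >= best[0]:
            best = (score, float(cutoff), k_star, cc_by_k)
    if best is None:
        raise ValueError("no dispersion cutoff produced a usable profile")
    return best[1], best[2], best[3]
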