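"""Marker statistics, marker selection and signature-matrix construction.

The signature matrix is the ``C`` in the linear mixing model ``T = C @ P``:
marker genes x cell types, holding each type's mean CPM. Marker candidacy
is scored by three per-gene statistics — logFC (highest-expressing type vs.
the mean of the rest), logCPM (overall expression level) and SecondFC
(highest vs. second-highest type, the exclusivity filter) — plus the
fraction of top-type cells actually expressing the gene. All ratios use a
pseudocount of 1 so zero means stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SingleCellReference

__all__ = [
    "SignatureMatrix",
    "ThresholdScan",
    "compute_marker_stats",
    "select_markers",
    "build_signature",
    "avg_celltype_correlation",
    "choose_secondfc_threshold",
    "subset_top_fraction",
    "DEFAULT_SECONDFC_GRID",
]

PSEUDOCOUNT = 1.0
#: covers both printed settings seen in practice (1.5 for tissue, >=6 for PBMC)
DEFAULT_SECONDFC_GRID = tuple(np.arange(1.0, 8.01, 0.5))


@dataclass
class SignatureMatrix:
    """Marker genes x cell types mean-CPM matrix with per-gene metadata."""

    values: pd.DataFrame  # genes x cell types
    logfc: pd.Series  # per marker gene, for fraction subsetting
    top_type: pd.Series  # marker gene -> cell type it marks

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("signature matrix must contain at least one marker")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.values.columns)

    def markers_by_type(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {ct: [] for ct in self.cell_type_ids}
        for gene, ct in self.top_type.items():
            out.setdefault(ct, []).append(gene)
        return out


@dataclass
class ThresholdScan:
    thresholds: list[float]
    avg_correlation: list[float]
    chosen_threshold: float
    marker_counts: list[int] = field(default_factory=list)


def compute_marker_stats(ref: SingleCellReference) -> pd.DataFrame:
    """Per-gene marker statistics from a labeled single-cell reference.

    Returns a DataFrame indexed by gene id with columns ``logFC``,
    ``logCPM``, ``SecondFC``, ``top_type`` and ``frac_expressed_in_top``.
    """
    types = ref.cell_types
    if len(types) < 2:
        raise ValueError("need at least 2 cell types to contrast")

    mean_cpm = ref.mean_cpm_by_type()  # genes x types
    m = mean_cpm.to_numpy()
    order = np.argsort(-m, axis=1)
    top_idx = order[:, 0]
    second_idx = order[:, 1]
    rows = np.arange(m.shape[0])
    m1 = m[rows, top_idx]
    m2 = m[rows, second_idx]
    rest_mean = (m.sum(axis=1) - m1) / (m.shape[1] - 1)

    eps = PSEUDOCOUNT
    logfc = np.log2((m1 + eps) / (rest_mean + eps))
    secondfc = (m1 + eps) / (m2 + eps)
    logcpm = np.log2(m.mean(axis=1) + eps)
    top_type = np.array(mean_cpm.columns)[top_idx]

    frac = np.empty(m.shape[0])
    expressed = ref.counts > 0
    for ct in types:
        mask = ref.cell_type_labels == ct
        frac_ct = expressed[mask].mean(axis=0)
        sel = top_type == ct
        frac[sel] = frac_ct[sel]

    return pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": logcpm,
            "SecondFC": secondfc,
            "top_type": top_type,
            "frac_expressed_in_top": frac,
        },
        index=mean_cpm.index,
    )


def select_markers(
    stats: pd.DataFrame,
    logfc_min: float = 1.0,
    logcpm_min: float = 1.0,
    secondfc_min: float = 1.5,
    min_frac_expressed: float = 0.30,
) -> dict[str, list[str]]:
    """Apply the four marker filters; returns cell type -> marker gene ids.

    A gene is kept iff logFC >= logfc_min, logCPM >= logcpm_min,
    SecondFC >= secondfc_min and it is expressed in at least
    ``min_frac_expressed`` of its top type's cells. Raises if no cell type
    retains a marker; a type losing all markers only triggers a warning.
    """
    keep = (
        (stats["logFC"] >= logfc_min)
        & (stats["logCPM"] >= logcpm_min)
        & (stats["SecondFC"] >= secondfc_min)
        & (stats["frac_expressed_in_top"] >= min_frac_expressed)
    )
    selected = stats[keep]
    all_types = sorted(stats["top_type"].unique())
    markers = {ct: [] for ct in all_types}
    for gene, ct in selected["top_type"].items():
        markers[ct].append(gene)
    empty = [ct for ct, genes in markers.items() if not genes]
    if len(empty) == len(markers):
        raise ValueError("no markers survive the thresholds for any cell type")
    if empty:
        warnings.warn(f"cell types with zero surviving markers: {empty}", stacklevel=2)
    return {ct: genes for ct, genes in markers.items() if genes}


def build_signature(ref: SingleCellReference, markers: dict[str, list[str]]) -> SignatureMatrix:
    """Mean-CPM signature matrix restricted to the selected marker genes."""
    if not markers or not any(markers.values()):
        raise ValueError("marker list is empty")
    known = set(ref.gene_ids)
    for ct, genes in markers.items():
        for g in genes:
            if g not in known:
                raise ValueError(f"marker gene {g!r} (type {ct}) absent from reference")

    stats = compute_marker_stats(ref)
    mean_cpm = ref.mean_cpm_by_type()
    genes: list[str] = []
    types_of: list[str] = []
    for ct in sorted(markers):
        for g in markers[ct]:
            if g not in genes:
                genes.append(g)
                types_of.append(ct)
    values = mean_cpm.loc[genes]
    return SignatureMatrix(
        values=values,
        logfc=stats.loc[genes, "logFC"],
        top_type=pd.Series(types_of, index=genes),
    )


def avg_celltype_correlation(sig: SignatureMatrix) -> float:
    """Mean pairwise Pearson correlation between signature columns.

    Pairs involving a constant column are undefined and excluded; if every
    pair is undefined an error is raised.
    """
    X = sig.values.to_numpy(dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need >=2 cell types and >=2 genes")
    sd = X.std(axis=0)
    cors = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if sd[i] == 0 or sd[j] == 0:
                continue
            cors.append(float(np.corrcoef(X[:, i], X[:, j])[0, 1]))
    if not cors:
        raise ValueError("all column pairs have undefined correlation (constant columns)")
    return float(np.mean(cors))


def choose_secondfc_threshold(
    ref: SingleCellReference,
    candidate_thresholds=DEFAULT_SECONDFC_GRID,
    plateau_tol: float = 0.05,
    logfc_min: float = 1.0,
    logcpm_min: float = 1.0,
    min_frac_expressed: float = 0.30,
) -> ThresholdScan:
    """Scan SecondFC candidates and pick the threshold where the between-type
    correlation curve plateaus.

    The chosen threshold is the smallest candidate whose forward decrease
    in average correlation to the next candidate falls below
    ``plateau_tol`` (the last candidate if the curve is steep everywhere).
    Candidates that empty the marker set truncate the scan with a warning.
    """
    cands = [float(t) for t in candidate_thresholds]
    if len(cands) < 3:
        raise ValueError("need at least 3 candidate thresholds")
    if sorted(cands) != cands:
        raise ValueError("candidate thresholds must be increasing")

    stats = compute_marker_stats(ref)
    avg_cors: list[float] = []
    counts: list[int] = []
    kept: list[float] = []
    for t in cands:
        try:
            markers = select_markers(
                stats,
                logfc_min=logfc_min,
                logcpm_min=logcpm_min,
                secondfc_min=t,
                min_frac_expressed=min_frac_expressed,
            )
            sig = build_signature(ref, markers)
        except ValueError:
            warnings.warn(
                f"SecondFC threshold {t} empties the marker set; scan truncated", stacklevel=2
            )
            break
        kept.append(t)
        counts.append(len(sig.gene_ids))
        avg_cors.append(avg_celltype_correlation(sig))
    if not kept:
        raise ValueError("no candidate threshold yields a non-empty signature")

    chosen = kept[-1]
    for i in range(len(kept) - 1):
        if avg_cors[i] - avg_cors[i + 1] < plateau_tol:
            chosen = kept[i]
            break
    return ThresholdScan(
        thresholds=kept, avg_correlation=avg_cors, chosen_threshold=chosen, marker_counts=counts
    )


def subset_top_fraction(sig: SignatureMatrix, fraction: float) -> SignatureMatrix:
    """Keep, per cell type, the ceil(fraction * n_markers) markers of highest
    logFC (ties broken by gene id), and rebuild the matrix on their union."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    keep: list[str] = []
    for ct, genes in sig.markers_by_type().items():
        if not genes:
            continue
        n_keep = math.ceil(fraction * len(genes))
        ranked = sorted(genes, key=lambda g: (-sig.logfc[g], g))
        keep.extend(ranked[:n_keep])
    keep = [g for g in sig.gene_ids if g in set(keep)]  # preserve original row order
    return SignatureMatrix(
        values=sig.values.loc[keep],
        logfc=sig.logfc.loc[keep],
        top_type=sig.top_type.loc[keep],
    )
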