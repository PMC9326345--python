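"""Evaluation harness: proportion/reconstruction correlations, marker-fraction
scans and average-rank stability across benchmark tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .signature import SignatureMatrix, subset_top_fraction
from .solvers import ProportionTable, SolverConfig, deconvolve_cohort

__all__ = [
    "BenchmarkRecord",
    "RankSummary",
    "pcc_proportions",
    "pcc_transcripts",
    "run_fraction_scan",
    "rank_methods",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 1.001, 0.05), 2))


@dataclass(frozen=True)
class BenchmarkRecord:
    test_name: str
    method_name: str
    marker_fraction: float
    pcc_p: float
    pcc_t1: float
    pcc_t2: float


@dataclass
class RankSummary:
    #: method -> rank per (test, fraction) cell, aligned with `cells`
    ranks: dict[str, list[float]]
    average_rank: dict[str, float]
    cells: list[tuple[str, float]]


def pcc_proportions(estimated: ProportionTable, truth: pd.DataFrame) -> float:
    """Pearson correlation between estimated and true proportions, flattened
    over samples x cell types after aligning both tables by id."""
    est = estimated.values
    truth = truth.loc[est.index, est.columns]
    x = est.to_numpy().ravel()
    y = truth.to_numpy().ravel()
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("correlation undefined: constant proportion table")
    return float(scipy.stats.pearsonr(x, y).statistic)


def pcc_transcripts(
    sig_used: SignatureMatrix,
    sig_full: SignatureMatrix,
    estimated: ProportionTable,
    bulk: pd.DataFrame,
    mode: str = "T2",
    flatten: bool = False,
) -> float:
    """Correlation between reconstructed (C @ p) and observed bulk expression.

    ``mode="T1"`` reconstructs on the fraction signature actually used for
    deconvolution; ``mode="T2"`` on the full-marker signature. Per-sample
    Pearson correlations are averaged unless ``flatten`` is set.
    """
    if mode not in ("T1", "T2"):
        raise ValueError("mode must be 'T1' or 'T2'")
    sig = sig_used if mode == "T1" else sig_full
    missing = [g for g in sig.gene_ids if g not in bulk.index]
    if missing:
        raise ValueError(f"bulk is missing signature genes: {missing[:10]}")
    C = sig.values.loc[:, estimated.cell_type_ids].to_numpy()
    P = estimated.values.to_numpy()  # samples x types
    T_hat = C @ P.T  # genes x samples
    obs = bulk.loc[sig.gene_ids, estimated.sample_ids].to_numpy()
    if flatten:
        return float(scipy.stats.pearsonr(T_hat.ravel(), obs.ravel()).statistic)
    cors = [
        float(scipy.stats.pearsonr(T_hat[:, s], obs[:, s]).statistic)
        for s in range(obs.shape[1])
    ]
    return float(np.mean(cors))


def run_fraction_scan(
    sig_full: SignatureMatrix,
    bulk: pd.DataFrame,
    truth: pd.DataFrame,
    methods: list[str],
    fractions=DEFAULT_FRACTIONS,
    test_name: str = "test",
    solver_overrides: dict[str, SolverConfig] | None = None,
) -> list[BenchmarkRecord]:
    """Deconvolve at each (method, marker fraction) and record the three PCCs.

    A failing cell is recorded as missing (skipped with a warning), never
    fabricated.
    """
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    records = []
    for frac in fractions:
        sig_frac = subset_top_fraction(sig_full, frac)
        for method in methods:
            cfg = (solver_overrides or {}).get(method, SolverConfig(method=method))
            try:
                est = deconvolve_cohort(sig_frac, bulk, cfg)
                rec = BenchmarkRecord(
                    test_name=test_name,
                    method_name=method,
                    marker_fraction=float(frac),
                    pcc_p=pcc_proportions(est, truth),
                    pcc_t1=pcc_transcripts(sig_frac, sig_full, est, bulk, mode="T1"),
                    pcc_t2=pcc_transcripts(sig_frac, sig_full, est, bulk, mode="T2"),
                )
            except Exception as exc:
                warnings.warn(
                    f"scan cell (method={method}, fraction={frac}) failed: {exc}", stacklevel=2
                )
                continue
            records.append(rec)
    return records


def rank_methods(
    records: list[BenchmarkRecord], fraction_window: tuple[float, float] = (0.25, 1.0)
) -> RankSummary:
    """Rank methods by PCC_P within each (test, fraction) cell and average.

    Rank 1 is best; ties share the mean rank. Every method must be present
    at every cell inside the window.
    """
    lo, hi = fraction_window
    in_window = [r for r in records if lo <= r.marker_fraction <= hi]
    if not in_window:
        raise ValueError("no records inside the fraction window")
    methods = sorted({r.method_name for r in in_window})
    cells = sorted({(r.test_name, r.marker_fraction) for r in in_window})
    by_cell: dict[tuple[str, float], dict[str, float]] = {c: {} for c in cells}
    for r in in_window:
        by_cell[(r.test_name, r.marker_fraction)][r.method_name] = r.pcc_p

    ranks: dict[str, list[float]] = {m: [] for m in methods}
    for cell in cells:
        vals = by_cell[cell]
        missing = [m for m in methods if m not in vals]
        if missing:
            raise ValueError(f"missing methods {missing} in cell {cell}")
        scores = np.array([vals[m] for m in methods])
        cell_ranks = scipy.stats.rankdata(-scores, method="average")
        for m, rk in zip(methods, cell_ranks):
            ranks[m].append(float(rk))
    return RankSummary(
        ranks=ranks,
        average_rank={m: float(np.mean(rs)) for m, rs in ranks.items()},
        cells=cells,
    )
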