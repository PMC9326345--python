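"""Cohort-level statistics: group-wise proportion comparisons, the DEG +
linear-SVM classification stage, and clinical-feature association tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .solvers import ProportionTable

__all__ = [
    "SvmConfig",
    "AssociationResult",
    "compare_group_proportions",
    "select_degs",
    "train_eval_svm",
    "test_clinical_association",
]


@dataclass(frozen=True)
class SvmConfig:
    cost_grid: tuple[float, ...] = tuple(np.round(np.arange(0.2, 2.01, 0.2), 1))
    n_folds: int = 5
    train_fraction: float = 0.8
    logcpm_min: float = 4.0
    de_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not all(c > 0 for c in self.cost_grid):
            raise ValueError("cost_grid must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class AssociationResult:
    feature: str
    test_name: str  # "anova" or "chi_square"
    statistic: float
    p: float
    pairwise: pd.DataFrame | None = None  # FDR-adjusted pairwise p-values


def compare_group_proportions(props: ProportionTable, labels: pd.Series) -> pd.DataFrame:
    """Per-cell-type two-sided rank-sum test between two groups, BH-adjusted.

    Returns a DataFrame indexed by cell type with columns ``statistic``,
    ``p`` and ``p_adjusted``. Cell types constant in both groups get p = 1.
    """
    labels = labels.loc[props.values.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    a_mask = labels == groups[0]
    if a_mask.sum() < 2 or (~a_mask).sum() < 2:
        raise ValueError("need at least 2 samples per group")

    stats_, pvals = [], []
    for ct in props.cell_type_ids:
        x = props.values.loc[a_mask, ct].to_numpy()
        y = props.values.loc[~a_mask, ct].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            stats_.append(len(x) * len(y) / 2)
            pvals.append(1.0)
            continue
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        stats_.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stats_, "p": pvals, "p_adjusted": adj}, index=props.cell_type_ids
    )


def select_degs(
    expr: pd.DataFrame,
    labels: pd.Series,
    logcpm_min: float = 4.0,
    alpha: float = 0.05,
) -> list[str]:
    """Differential genes between two groups on a log-scale matrix.

    Genes with mean log expression above ``logcpm_min`` are tested with an
    unequal-variance t-test and BH-adjusted; adjusted p < alpha survive.
    This is a continuous-data surrogate for a count-model DE fit.
    """
    labels = labels.loc[expr.columns]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    expressed = expr.mean(axis=1) > logcpm_min
    if not expressed.any():
        raise ValueError(f"no gene exceeds the expression filter (mean log expr > {logcpm_min})")
    sub = expr.loc[expressed]
    a = sub.loc[:, labels == groups[0]].to_numpy()
    b = sub.loc[:, labels == groups[1]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return list(sub.index[adj < alpha])


def train_eval_svm(
    expr: pd.DataFrame, labels: pd.Series, cfg: SvmConfig | None = None
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Linear SVM with cost chosen by cross-validated ROC-AUC.

    Splits samples 80/20 stratified by label (seeded), selects DEGs on the
    training set only, grid-searches the cost by mean k-fold CV ROC-AUC
    (ties resolved toward the smallest cost), refits on the full training
    set and reports the held-out ROC-AUC. Returns
    ``(best_cost, test_auc, (fpr, tpr))``.
    """
    cfg = cfg or SvmConfig()
    cfg.validate()
    labels = labels.loc[expr.columns]
    y = pd.factorize(labels)[0]
    if len(np.unique(y)) != 2:
        raise ValueError("expected exactly two classes")

    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        test_size=1 - cfg.train_fraction,
        stratify=y,
        random_state=cfg.seed,
    )
    train_cols = expr.columns[idx_train]
    degs = select_degs(expr[train_cols], labels[train_cols], cfg.logcpm_min, cfg.de_alpha)
    if not degs:
        raise ValueError("no differential genes found on the training set")

    X = expr.loc[degs].T.to_numpy()
    X_train, y_train = X[idx_train], y[idx_train]
    X_test, y_test = X[idx_test], y[idx_test]

    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    best_cost, best_auc = None, -np.inf
    for cost in cfg.cost_grid:
        aucs = []
        for tr, va in cv.split(X_train, y_train):
            if len(np.unique(y_train[tr])) < 2 or len(np.unique(y_train[va])) < 2:
                continue
            clf = SVC(kernel="linear", C=cost)
            clf.fit(X_train[tr], y_train[tr])
            aucs.append(roc_auc_score(y_train[va], clf.decision_function(X_train[va])))
        if not aucs:
            raise ValueError("cross-validation folds lost a class; too few samples per class")
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:  # strict improvement: ties keep the smaller cost
            best_auc, best_cost = mean_auc, float(cost)

    clf = SVC(kernel="linear", C=best_cost)
    clf.fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    test_auc = float(roc_auc_score(y_test, scores))
    fpr, tpr, _ = roc_curve(y_test, scores)
    return best_cost, test_auc, (fpr, tpr)


def test_clinical_association(
    clusters: pd.Series, clinical_table: pd.DataFrame, yates: bool = False
) -> list[AssociationResult]:
    """Association of each clinical feature with a clustering.

    Numeric features: one-way ANOVA across clusters plus all-pairs
    unequal-variance t-tests with BH correction. Categorical features:
    chi-square on the cluster x category contingency table (no continuity
    correction by default). Features with a single distinct value are
    skipped with a warning.
    """
    clinical_table = clinical_table.loc[clusters.index]
    cluster_ids = sorted(clusters.unique())
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters")

    results: list[AssociationResult] = []
    for feat in clinical_table.columns:
        col = clinical_table[feat]
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"clinical feature {feat!r} has a single value; skipped")
            continue
        if pd.api.types.is_numeric_dtype(col):
            groups = [col[clusters == c].dropna().to_numpy() for c in cluster_ids]
            if any(len(g) < 3 for g in groups):
                warnings.warn(f"feature {feat!r}: a cluster has <3 samples; skipped")
                continue
            stat, p = scipy.stats.f_oneway(*groups)
            pw_p = []
            pairs = [
                (i, j) for i in range(len(cluster_ids)) for j in range(i + 1, len(cluster_ids))
            ]
            for i, j in pairs:
                pw_p.append(scipy.stats.ttest_ind(groups[i], groups[j], equal_var=False).pvalue)
            adj = multipletests(pw_p, method="fdr_bh")[1]
            pairwise = pd.DataFrame(np.nan, index=cluster_ids, columns=cluster_ids)
            for (i, j), q in zip(pairs, adj):
                pairwise.iloc[i, j] = pairwise.iloc[j, i] = q
            results.append(AssociationResult(feat, "anova", float(stat), float(p), pairwise))
        else:
            table = pd.crosstab(clusters, col)
            stat, p, _, _ = scipy.stats.chi2_contingency(table.to_numpy(), correction=yates)
            results.append(AssociationResult(feat, "chi_square", float(stat), float(p)))
    return results
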