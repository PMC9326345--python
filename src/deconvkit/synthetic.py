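"""Synthetic single-cell references, pseudo-bulk mixtures and case/control cohorts.

Everything here is fully determined by the spec dataclass plus an integer
seed, so downstream estimators can be tested against exact ground truth.
Bulk mixtures are built from per-type mean CPM profiles (not resampled
cells) so that the noiseless case is exactly linear in the mixing
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSpec",
    "CohortSpec",
    "SingleCellReference",
    "SyntheticCohort",
    "generate_reference",
    "generate_mixtures",
    "generate_cohort",
]


@dataclass(frozen=True)
class ReferenceSpec:
    """Parameters controlling a synthetic labeled single-cell reference."""

    n_cell_types: int = 4
    n_genes: int = 1000
    cells_per_type: int = 50
    markers_per_type: int = 20
    marker_log2fc: float = 3.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    count_depth: int = 20_000
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be >= 2")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "infeasible spec: markers_per_type x n_cell_types "
                f"({self.markers_per_type * self.n_cell_types}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.cells_per_type < 1 or self.count_depth < 1:
            raise ValueError("cells_per_type and count_depth must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for a two-group cohort with planted subtype structure."""

    n_samples_per_group: int = 50
    group_proportion_shift: dict[str, float] = field(default_factory=dict)
    dirichlet_concentration: tuple[float, ...] | None = None
    noise_log_sd: float = 0.2
    platform_bias_sd: float = 0.3
    n_subtypes: int = 1
    #: subtype index -> one activation (cell type, gene ids, log2 fold) or a
    #: list of them, letting subtypes share pathway components
    subtype_pathway_genes: dict = field(default_factory=dict)
    #: per-sample activation dosage spread: log2fc is scaled by U(1-j, 1+j)
    activation_jitter: float = 0.0
    #: optional (cell type, gene ids, max log2fc) activated in every case
    #: sample with a continuous per-sample dosage U(0, 1) — a shared
    #: severity axis orthogonal to the subtype structure
    shared_pathway: tuple[str, tuple[str, ...], float] | None = None
    clinical_effect_size: float = 0.0
    seed: int = 0

    def validate(self, cell_types: list[str]) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.dirichlet_concentration is not None:
            conc = np.asarray(self.dirichlet_concentration, dtype=float)
            if conc.shape != (len(cell_types),):
                raise ValueError("dirichlet_concentration length must match cell types")
            if np.any(conc <= 0):
                raise ValueError("Dirichlet concentrations must be strictly positive")
        unknown = set(self.group_proportion_shift) - set(cell_types)
        if unknown:
            raise ValueError(f"group_proportion_shift names unknown cell types: {sorted(unknown)}")
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")


@dataclass
class SingleCellReference:
    """Labeled counts matrix: ``counts[cell, gene]`` with one type label per cell."""

    counts: np.ndarray
    cell_type_labels: np.ndarray
    gene_ids: list[str]
    #: cell type -> list of planted marker gene ids (provenance, may be empty)
    planted_markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_type_labels = np.asarray(self.cell_type_labels)
        if self.counts.shape[0] != self.cell_type_labels.shape[0]:
            raise ValueError("one label per cell required")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match counts columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type_labels.tolist()))

    def cpm(self) -> np.ndarray:
        """Counts-per-million per cell; cells with zero depth stay zero."""
        depth = self.counts.sum(axis=1, keepdims=True).astype(float)
        depth[depth == 0] = 1.0
        return self.counts / depth * 1e6

    def mean_cpm_by_type(self) -> pd.DataFrame:
        """Genes x cell types matrix of mean CPM over cells of each type."""
        cpm = self.cpm()
        cols = {}
        for ct in self.cell_types:
            cols[ct] = cpm[self.cell_type_labels == ct].mean(axis=0)
        return pd.DataFrame(cols, index=self.gene_ids)


@dataclass
class SyntheticCohort:
    bulk: pd.DataFrame  # genes x samples, strictly positive
    true_proportions: pd.DataFrame  # samples x cell types, rows on the simplex
    group_labels: pd.Series  # "case"/"control" per sample
    subtype_labels: pd.Series  # int per case sample (controls: -1)
    clinical_table: pd.DataFrame  # samples x features
    reference_spec: ReferenceSpec | None = None
    cohort_spec: CohortSpec | None = None


def generate_reference(spec: ReferenceSpec) -> SingleCellReference:
    """Draw a labeled count matrix with planted cell-type markers.

    Each gene gets a log-normal baseline expression level shared across
    types; each cell type elevates its own block of marker genes by
    ``2**marker_log2fc``. Cells are multinomial draws of ``count_depth``
    counts from the (dropout-masked) type profile.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_types, n_genes = spec.n_cell_types, spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    type_names = [f"T{t}" for t in range(n_types)]

    baseline = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_genes))
    profiles = np.tile(baseline, (n_types, 1))
    planted: dict[str, list[str]] = {}
    for t, name in enumerate(type_names):
        block = slice(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        profiles[t, block] *= 2.0 ** spec.marker_log2fc
        planted[name] = gene_ids[block]

    cells = []
    labels = []
    for t, name in enumerate(type_names):
        for _ in range(spec.cells_per_type):
            prof = profiles[t].copy()
            if spec.dropout_rate > 0:
                keep = rng.random(n_genes) >= spec.dropout_rate
                prof = prof * keep
            total = prof.sum()
            if total == 0:  # full dropout: emit an empty cell
                cells.append(np.zeros(n_genes, dtype=np.int64))
            else:
                cells.append(rng.multinomial(spec.count_depth, prof / total))
            labels.append(name)

    return SingleCellReference(
        counts=np.asarray(cells, dtype=np.int64),
        cell_type_labels=np.asarray(labels),
        gene_ids=gene_ids,
        planted_markers=planted,
    )


def generate_mixtures(
    ref: SingleCellReference,
    n_samples: int,
    concentration,
    noise_log_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudo-bulk mixtures with Dirichlet proportions over the reference types.

    Bulk column ``s`` is ``sum_t p[s,t] * m_t`` times i.i.d. log-normal
    noise ``exp(N(0, noise_log_sd^2))`` per gene and sample, where ``m_t``
    is the per-type mean CPM profile. Returns ``(bulk, true_proportions)``.
    """
    conc = np.asarray(concentration, dtype=float)
    types = ref.cell_types
    if conc.shape != (len(types),):
        raise ValueError("concentration length must equal the number of cell types")
    if np.any(conc <= 0):
        raise ValueError("Dirichlet concentration must be strictly positive")
    rng = np.random.default_rng(seed)

    M = ref.mean_cpm_by_type().to_numpy()  # genes x types
    P = rng.dirichlet(conc, size=n_samples)  # samples x types
    bulk = M @ P.T
    if noise_log_sd > 0:
        bulk = bulk * np.exp(rng.normal(0.0, noise_log_sd, size=bulk.shape))

    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    bulk_df = pd.DataFrame(bulk, index=ref.gene_ids, columns=sample_ids)
    props = pd.DataFrame(P, index=sample_ids, columns=types)
    return bulk_df, props


def _group_concentration(base_conc: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift the Dirichlet mean by `shift` while keeping total mass."""
    total = base_conc.sum()
    mean = base_conc / total + shift
    if np.any(mean <= 0):
        raise ValueError("group_proportion_shift produces non-positive mean proportions")
    if abs(mean.sum() - 1.0) > 1e-9:
        raise ValueError("group_proportion_shift must sum to zero across cell types")
    return mean * total


def generate_cohort(ref: SingleCellReference, spec: CohortSpec) -> SyntheticCohort:
    """Case/control pseudo-bulk cohort with planted subtypes and clinical features.

    Case samples are split evenly over ``n_subtypes`` blocks; each block's
    pathway activation multiplies the stated genes by ``2**log2fc`` inside
    the stated cell type's contribution before summation, so cell-type
    level imputation can be validated against the planting. Numeric
    clinical features separate subtypes by ``clinical_effect_size``
    standard deviations on top of unit noise; planted categorical features
    get subtype-dependent category frequencies. Null features (suffix
    ``_null``) carry no signal.
    """
    types = ref.cell_types
    spec.validate(types)
    rng = np.random.default_rng(spec.seed)
    K = len(types)

    base_conc = (
        np.asarray(spec.dirichlet_concentration, dtype=float)
        if spec.dirichlet_concentration is not None
        else np.full(K, 10.0)
    )
    shift = np.array([spec.group_proportion_shift.get(ct, 0.0) for ct in types])
    residual = -shift.sum()  # balance the shift over unshifted types
    unshifted = np.array([ct not in spec.group_proportion_shift for ct in types])
    if residual != 0.0:
        if not unshifted.any():
            raise ValueError("group_proportion_shift must leave at least one type free to balance")
        shift = shift + unshifted * (residual / unshifted.sum())

    conc_control = base_conc
    conc_case = _group_concentration(base_conc, shift)

    M = ref.mean_cpm_by_type()  # genes x types
    gene_index = {g: i for i, g in enumerate(ref.gene_ids)}
    n = spec.n_samples_per_group
    sample_ids = [f"case{i:04d}" for i in range(n)] + [f"ctrl{i:04d}" for i in range(n)]
    groups = ["case"] * n + ["control"] * n
    subtypes = [i % spec.n_subtypes for i in range(n)] + [-1] * n

    P = np.vstack(
        [rng.dirichlet(conc_case, size=n), rng.dirichlet(conc_control, size=n)]
    )  # samples x types

    platform_bias = (
        np.exp(rng.normal(0.0, spec.platform_bias_sd, size=M.shape[0]))
        if spec.platform_bias_sd > 0
        else np.ones(M.shape[0])
    )

    Mv = M.to_numpy()
    bulk = np.empty((M.shape[0], len(sample_ids)))
    for s, (p, st) in enumerate(zip(P, subtypes)):
        contrib = Mv * p[np.newaxis, :]  # genes x types
        if st >= 0 and st in spec.subtype_pathway_genes:
            activations = spec.subtype_pathway_genes[st]
            if isinstance(activations, tuple) and len(activations) == 3 and isinstance(
                activations[0], str
            ):
                activations = [activations]
            for ct, genes, l2fc in activations:
                if spec.activation_jitter > 0:
                    l2fc = l2fc * rng.uniform(
                        1 - spec.activation_jitter, 1 + spec.activation_jitter
                    )
                t_idx = types.index(ct)
                g_idx = [gene_index[g] for g in genes]
                contrib[g_idx, t_idx] *= 2.0 ** l2fc
        if st >= 0 and spec.shared_pathway is not None:
            ct, genes, max_l2fc = spec.shared_pathway
            dose = rng.uniform(0.0, 1.0)
            t_idx = types.index(ct)
            g_idx = [gene_index[g] for g in genes]
            contrib[g_idx, t_idx] *= 2.0 ** (max_l2fc * dose)
        col = contrib.sum(axis=1) * platform_bias
        if spec.noise_log_sd > 0:
            col = col * np.exp(rng.normal(0.0, spec.noise_log_sd, size=col.shape))
        bulk[:, s] = np.maximum(col, 1e-12)  # keep strictly positive

    clinical = _clinical_table(rng, sample_ids, subtypes, spec)

    return SyntheticCohort(
        bulk=pd.DataFrame(bulk, index=ref.gene_ids, columns=sample_ids),
        true_proportions=pd.DataFrame(P, index=sample_ids, columns=types),
        group_labels=pd.Series(groups, index=sample_ids, name="group"),
        subtype_labels=pd.Series(subtypes, index=sample_ids, name="subtype"),
        clinical_table=clinical,
        cohort_spec=spec,
    )


def _clinical_table(
    rng: np.random.Generator, sample_ids: list[str], subtypes: list[int], spec: CohortSpec
) -> pd.DataFrame:
    st = np.asarray(subtypes, dtype=float)
    effect = spec.clinical_effect_size
    n = len(sample_ids)

    planted_num = np.where(st >= 0, st * effect, 0.0) + rng.normal(0.0, 1.0, size=n)
    null_num = rng.normal(0.0, 1.0, size=n)

    n_cat = max(2, spec.n_subtypes)
    cats = np.array([f"c{j}" for j in range(n_cat)])
    planted_cat = []
    for s in subtypes:
        probs = np.ones(n_cat)
        if s >= 0 and effect > 0:
            probs[s % n_cat] += 3.0 * effect  # skew toward the subtype's own category
        probs /= probs.sum()
        planted_cat.append(rng.choice(cats, p=probs))
    null_cat = rng.choice(cats, size=n)

    return pd.DataFrame(
        {
            "feat_num_planted": planted_num,
            "feat_num_null": null_num,
            "feat_cat_planted": planted_cat,
            "feat_cat_null": null_cat,
        },
        index=sample_ids,
    )
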