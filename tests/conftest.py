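import numpy as np
import pandas as pd
import pytest

from deconvkit.signature import SignatureMatrix, build_signature, compute_marker_stats, select_markers
from deconvkit.synthetic import ReferenceSpec, SingleCellReference, generate_reference


@pytest.fixture(scope="session")
def small_ref() -> SingleCellReference:
    """3 types x 200 genes, 10 planted markers per type at log2FC 3."""
    return generate_reference(
        ReferenceSpec(
            n_cell_types=3,
            n_genes=200,
            cells_per_type=50,
            markers_per_type=10,
            marker_log2fc=3.0,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def small_sig(small_ref) -> SignatureMatrix:
    stats = compute_marker_stats(small_ref)
    markers = select_markers(stats, secondfc_min=1.5)
    return build_signature(small_ref, markers)


def make_reference_from_cpm(profiles: dict[str, list[float]], gene_ids: list[str]) -> SingleCellReference:
    """Reference with one cell per type whose CPM equals the stated profile.

    A filler gene absorbs the rest of the 1e6 depth so counts == CPM for
    the listed genes; used for hand-arithmetic oracle tests.
    """
    types = sorted(profiles)
    counts = []
    for ct in types:
        prof = [int(v) for v in profiles[ct]]
        filler = 1_000_000 - sum(prof)
        assert filler >= 0
        counts.append(prof + [filler])
    return SingleCellReference(
        counts=np.asarray(counts, dtype=np.int64),
        cell_type_labels=np.asarray(types),
        gene_ids=gene_ids + ["__filler__"],
    )


def make_signature(values: np.ndarray, genes=None, types=None, logfc=None) -> SignatureMatrix:
    """Assemble a SignatureMatrix directly from a dense array (test helper)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    types = types or [f"T{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=types)
    if logfc is None:
        logfc = pd.Series(np.arange(len(genes), 0, -1, dtype=float), index=genes)
    top = df.idxmax(axis=1)
    return SignatureMatrix(values=df, logfc=pd.Series(logfc, index=genes), top_type=top)
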