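"""Readers and writers for the plain-text interchange formats.

TSV is the canonical matrix format (first column = row ids, header = column
ids). Single-cell references round-trip through MTX (coordinate, 1-based)
plus TSV sidecars for labels and gene ids; gene sets through GMT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .pathway import GeneSet
from .synthetic import SingleCellReference

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_reference",
    "write_reference",
    "read_proportions_tsv",
    "write_proportions_tsv",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix.

    Duplicate gene ids are collapsed by mean with a warning; ragged rows
    and non-numeric cells raise a parse error citing the line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        sample_ids = header[1:]
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} fields, found {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    df = pd.DataFrame(rows, index=genes, columns=sample_ids)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        warnings.warn(f"duplicated gene ids collapsed by mean: {dups[:10]}", stacklevel=2)
        df = df.groupby(level=0, sort=False).mean()
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_proportions_tsv(path: str | Path) -> pd.DataFrame:
    """Samples x cell types proportion table (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_proportions_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a set are dropped with a warning; a line with
    fewer than three fields is an error citing its line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} removed")
            sets.append(GeneSet(name=name, gene_ids=tuple(deduped)))
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.gene_ids]) + "\n")


def write_reference(ref: SingleCellReference, out_dir: str | Path) -> None:
    """Write a reference as MTX (cells x genes) + label and gene-id TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "counts.mtx"), scipy.sparse.coo_matrix(ref.counts))
    pd.Series(ref.cell_type_labels).to_csv(
        out / "cell_type_labels.tsv", sep="\t", index=False, header=["cell_type"]
    )
    pd.Series(ref.gene_ids).to_csv(out / "gene_ids.tsv", sep="\t", index=False, header=["gene_id"])


def read_reference(in_dir: str | Path) -> SingleCellReference:
    in_dir = Path(in_dir)
    counts = np.asarray(scipy.io.mmread(str(in_dir / "counts.mtx")).todense())
    labels = pd.read_csv(in_dir / "cell_type_labels.tsv", sep="\t")["cell_type"].to_numpy()
    genes = pd.read_csv(in_dir / "gene_ids.tsv", sep="\t")["gene_id"].astype(str).tolist()
    return SingleCellReference(counts=counts.astype(np.int64), cell_type_labels=labels, gene_ids=genes)
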