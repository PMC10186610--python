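"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and expression travel as TSV (genes as rows) or MatrixMarket with
row/column name sidecars; gene sets as GMT; intervals as BED (0-based
half-open); metadata and annotations as TSV/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from lhasig.containers import CountMatrix, ExpressionMatrix, GeneSet

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------- matrices

def write_counts_tsv(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_counts_tsv(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    return CountMatrix(counts=counts, metadata=metadata)


def write_counts_mtx(cm: CountMatrix, prefix) -> None:
    """Write counts as ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` /
    ``<prefix>.samples.txt`` name files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(cm.counts.values))
    prefix.with_suffix(".genes.txt").write_text("\n".join(cm.counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(cm.counts.columns) + "\n")


def read_counts_mtx(mtx_path, genes_path, samples_path, metadata_path) -> CountMatrix:
    values = scipy.io.mmread(mtx_path).toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    counts = pd.DataFrame(values, index=genes, columns=samples)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    return CountMatrix(counts=counts, metadata=metadata)


def write_expression(em: ExpressionMatrix, values_path, provenance_path=None) -> None:
    em.values.to_csv(values_path, sep="\t", index_label="gene", float_format="%.10g")
    if provenance_path is not None:
        Path(provenance_path).write_text(
            json.dumps(em.provenance, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )


def read_expression(values_path, metadata_path=None, provenance_path=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    metadata = (
        pd.read_csv(metadata_path, sep="\t", index_col="sample")
        if metadata_path is not None
        else None
    )
    provenance = (
        json.loads(Path(provenance_path).read_text()) if provenance_path else {}
    )
    return ExpressionMatrix(values=values, metadata=metadata, provenance=provenance)


def write_matrix_tsv(df: pd.DataFrame, path, index_label="id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix_tsv(path, index_label="id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------- gene sets

def write_gmt(gene_sets, path) -> None:
    """Write gene sets one per GMT line: name, description, members."""
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write(
                "\t".join([gs.name, gs.direction] + gs.sorted_members()) + "\n"
            )


def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, desc = fields[0], fields[1]
            direction = desc if desc in ("up", "down") else "none"
            sets.append(GeneSet.from_iterable(name, fields[2:], direction))
    return sets


# ---------------------------------------------------------------- intervals

def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write an interval table as 6-column BED (0-based half-open)."""
    df = intervals.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(intervals_path, one_based: bool = False) -> pd.DataFrame:
    """Read BED into a DataFrame; ``one_based=True`` converts 1-based
    inclusive starts to the 0-based half-open convention used internally."""
    df = pd.read_csv(
        intervals_path, sep="\t", header=None, comment="#",
        names=BED_COLUMNS[: None], usecols=range(6),
    )
    if one_based:
        df["start"] = df["start"] - 1
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} intervals with start >= end")
    return df


# ---------------------------------------------------------------- misc

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
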