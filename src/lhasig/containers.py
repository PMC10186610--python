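"""Core in-memory containers shared across pipeline stages.

Conventions
-----------
* Bulk matrices are genes x samples (rows are genes), following the layout
  of count matrices as deposited with cohort studies.
* Single-cell matrices are cells x genes (rows are observations), following
  the scanpy/AnnData convention.
* Sample metadata is a DataFrame indexed by sample id with columns such as
  ``group``, ``age``, ``sex``, ``batch``, ``library``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative counts, genes as rows, samples as columns.
    metadata
        Per-sample table indexed by sample id.  Must cover exactly the
        samples present in ``counts`` (same order is enforced on init).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        extra = set(self.metadata.index) - set(self.counts.columns)
        if missing or extra:
            raise ValueError(
                f"metadata does not match samples (missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]})"
            )
        # align metadata rows to column order
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """Real-valued (log2-scale) gene x sample matrix with provenance.

    ``provenance`` records every transformation applied (size factors,
    pseudocount, covariates removed) so downstream consumers can tell what
    scale the values are on.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression values must be finite")
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSet:
    """A named, optionally directional, set of gene identifiers."""

    name: str
    members: frozenset
    direction: str = "none"  # "up" | "down" | "none"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_iterable(
        cls, name: str, members: Iterable[str], direction: str = "none"
    ) -> "GeneSet":
        return cls(name=name, members=frozenset(members), direction=direction)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted_members(self) -> list:
        return sorted(self.members)
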