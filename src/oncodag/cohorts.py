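"""Cross-sectional binary mutation matrices (patients/samples x genes)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortMatrix"]


@dataclass(frozen=True)
class CohortMatrix:
    """Binary patients-by-genes mutation matrix.

    Rows are independent tumor samples (one consensus genotype per tumor),
    columns are driver genes, entries are 0/1.  This is the input format of
    cancer progression models.
    """

    gene_names: tuple[str, ...]
    matrix: np.ndarray  # shape (n_samples, m), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.int8)
        if mat.ndim != 2 or mat.shape[1] != len(self.gene_names):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.gene_names)} genes"
            )
        if not np.isin(mat, (0, 1)).all():
            raise ValueError("cohort entries must be 0/1")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        mat.setflags(write=False)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def genotype_ints(self) -> np.ndarray:
        """Each row encoded as the integer genotype (bit k = gene k)."""
        weights = 1 << np.arange(self.m, dtype=np.int64)
        return (self.matrix.astype(np.int64) * weights).sum(axis=1)

    def genotype_counts(self) -> dict[int, int]:
        ints, counts = np.unique(self.genotype_ints(), return_counts=True)
        return {int(g): int(c) for g, c in zip(ints, counts)}

    def genotype_frequencies(self) -> dict[int, float]:
        n = self.n_samples
        return {g: c / n for g, c in self.genotype_counts().items()}

    def gene_marginals(self) -> np.ndarray:
        """Per-gene mutation frequency across samples."""
        return self.matrix.mean(axis=0)

    def drop_wildtype(self) -> "CohortMatrix":
        keep = self.matrix.any(axis=1)
        return CohortMatrix(self.gene_names, self.matrix[keep])

    @classmethod
    def from_genotype_ints(
        cls, gene_names: Sequence[str], genotypes: Iterable[int]
    ) -> "CohortMatrix":
        genes = tuple(gene_names)
        rows = [[g >> k & 1 for k in range(len(genes))] for g in genotypes]
        return cls(genes, np.asarray(rows, dtype=np.int8).reshape(-1, len(genes)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.gene_names))

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortMatrix":
        return cls(tuple(df.columns), df.to_numpy())

    @classmethod
    def from_csv(cls, path_or_buf) -> "CohortMatrix":
        return cls.from_frame(pd.read_csv(path_or_buf))
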