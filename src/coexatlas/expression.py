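"""Per-tissue expression matrices and their tab-separated on-disk format.

An :class:`ExpressionMatrix` holds one tissue's genes × samples values.
The on-disk format is plain TSV: first column ``gene_id``, header row of
sample identifiers — the shape every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values for a single tissue.

    Parameters
    ----------
    tissue
        Tissue identifier (e.g. ``"T01"`` or ``"Spleen"``).
    data
        DataFrame indexed by gene id with one column per sample id.
    """

    tissue: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError(f"duplicate gene ids in tissue {self.tissue!r}")
        if self.data.columns.has_duplicates:
            raise ValueError(f"duplicate sample ids in tissue {self.tissue!r}")
        if self.data.isna().to_numpy().any():
            raise ValueError(f"missing values in tissue {self.tissue!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        missing = set(gene_ids) - set(self.data.index)
        if missing:
            raise KeyError(
                f"genes absent from tissue {self.tissue!r}: {sorted(missing)[:5]}"
            )
        return ExpressionMatrix(self.tissue, self.data.loc[gene_ids].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, tissue: str | None = None) -> "ExpressionMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(tissue if tissue is not None else path.stem, df)
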