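"""Gene-universe intersection and per-gene rank inverse-normal transform.

All tissues are first restricted to their common gene set, then each
gene's profile is mapped to standard-normal quantiles of its ranks
(Blom offset, average ranks for ties), so that every gene's profile is
marginally normal and Pearson correlation downstream is rank-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .expression import ExpressionMatrix

# Blom constant: rank r of n maps to quantile (r - 3/8) / (n + 1/4)
_BLOM_C = 3.0 / 8.0


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene set, in lexicographic order.

    Raises
    ------
    ValueError
        If no matrices are given or the intersection is empty.
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no common genes across tissues")
    order = sorted(common)
    return [m.restrict_genes(order) for m in matrices]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map a vector to standard-normal quantiles of its (Blom-offset) ranks.

    ``output[i] = ndtri((r_i - 3/8) / (n + 1/4))`` where ``r_i`` is the
    average rank of ``values[i]``.  Nondecreasing in the input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector")
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if np.ptp(values) == 0:
        raise ValueError("zero variance: constant vector cannot be rank-normalized")
    ranks = rankdata(values, method="average")
    return ndtri((ranks - _BLOM_C) / (n + 0.25))


def normalize_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply :func:`rank_inverse_normal` independently to each gene row."""
    x = m.values
    const = np.ptp(x, axis=1) == 0
    if const.any():
        bad = [m.gene_ids[i] for i in np.flatnonzero(const)[:5]]
        raise ValueError(
            f"constant expression rows in tissue {m.tissue!r}: {bad}"
        )
    n = x.shape[1]
    # vectorized row-wise rank-INT; ties handled by average ranks
    ranks = rankdata(x, method="average", axis=1)
    out = ndtri((ranks - _BLOM_C) / (n + 0.25))
    return ExpressionMatrix(
        m.tissue, pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    )


def preprocess_all(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Intersect gene universes, then rank-normalize every tissue."""
    return [normalize_matrix(m) for m in intersect_genes(matrices)]
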