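"""Weighted coexpression network construction for one tissue.

The pipeline follows the standard weighted-network recipe: similarity is
the absolute Pearson correlation between gene profiles, S_mn = |cor(m, n)|;
the adjacency soft-thresholds it with an integer power, a_mn = S_mn^beta;
and the topological overlap matrix (TOM)

    omega_mn = (l_mn + a_mn) / (min(k_m, k_n) + 1 - a_mn),
    l_mn = sum_{u != m,n} a_mu * a_un,   k_m = sum_{u != m} a_mu

measures how much two genes share neighbours in addition to their direct
link.  Connectivity k excludes the self term, which keeps omega <= 1.
Clustering consumes the dissimilarity D = 1 - omega.

The soft power is chosen by a scale-free-topology diagnostic: node
connectivities are binned, and the squared correlation between
log10(mean k) and log10(p(k)) over nonempty bins (signed by the slope)
measures how closely the degree distribution follows a power law.  The
pipeline default keeps a single power of 6 for every tissue so that the
networks are comparable; a strict mode instead takes the smallest power
whose fit reaches the R^2 >= 0.8 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import ExpressionMatrix

DEFAULT_POWER = 6
SCALE_FREE_R2_THRESHOLD = 0.8


@dataclass
class CoexpressionNetwork:
    """Similarity, adjacency, TOM and dissimilarity for one tissue."""

    tissue: str
    gene_ids: list[str]
    S: np.ndarray = field(repr=False)
    beta: int = DEFAULT_POWER
    A: np.ndarray = field(repr=False, default=None)
    Omega: np.ndarray = field(repr=False, default=None)
    D: np.ndarray = field(repr=False, default=None)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class PowerDiagnostics:
    """Scale-free fit and mean connectivity across candidate powers."""

    powers: list[int]
    signed_r2: list[float]  # sign(slope) * correlation^2; NaN when undefined
    mean_connectivity: list[float]
    chosen_power: int

    def as_dict(self) -> dict:
        return {
            "powers": self.powers,
            "signed_r2": self.signed_r2,
            "mean_connectivity": self.mean_connectivity,
            "chosen_power": self.chosen_power,
        }


def similarity_matrix(m: ExpressionMatrix) -> np.ndarray:
    """Absolute Pearson correlation between every pair of gene profiles."""
    x = m.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    if (np.ptp(x, axis=1) == 0).any():
        raise ValueError("constant expression rows; normalize/filter first")
    s = np.abs(np.corrcoef(x))
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


def adjacency(S: np.ndarray, beta: int) -> np.ndarray:
    """Soft-threshold the similarity: A = S**beta, unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    a = np.power(S, beta)
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(A: np.ndarray) -> np.ndarray:
    """Node connectivities k_m = sum of off-diagonal adjacency weights."""
    return A.sum(axis=1) - np.diag(A)


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = A.copy()
    np.fill_diagonal(a0, 0.0)
    # (a0 @ a0)[m, n] = sum_{u != m, n} a_mu a_un exactly, since the zeroed
    # diagonal removes the u == m and u == n terms
    l = a0 @ a0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + a0) / denom
    omega[denom == 0] = 0.0
    np.fill_diagonal(omega, 1.0)
    np.clip(omega, 0.0, 1.0, out=omega)
    return omega


def tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    return 1.0 - tom(A)


def scale_free_fit_from_connectivity(
    k: np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """Signed scale-free fit statistic from a connectivity vector.

    Bins ``k`` into ``n_bins`` equal-width bins; over nonempty bins with
    positive mean connectivity, returns ``sign(slope) * r^2`` of
    log10(mean k) vs log10(frequency), plus the mean connectivity.
    Returns NaN for the fit when fewer than two usable bins exist
    (e.g. a regular graph, where every connectivity is equal).
    """
    k = np.asarray(k, dtype=float)
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    mean_k = float(k.mean())
    if np.ptp(k) == 0:
        return float("nan"), mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        mk = float(k[mask].mean())
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(cnt / k.size))
    if len(xs) < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), mean_k
    r = float(np.corrcoef(xs, ys)[0, 1])
    slope_sign = 1.0 if r >= 0 else -1.0
    return slope_sign * r * r, mean_k


def scale_free_fit(A: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free fit of an adjacency matrix (see the connectivity variant)."""
    return scale_free_fit_from_connectivity(connectivity(A), n_bins)


def power_sweep(
    m: ExpressionMatrix,
    powers: list[int] | None = None,
    strict: bool = False,
    default_power: int = DEFAULT_POWER,
    r2_threshold: float = SCALE_FREE_R2_THRESHOLD,
    n_bins: int = 10,
) -> PowerDiagnostics:
    """Scale-free diagnostics over candidate powers, with a chosen power.

    By default the chosen power is ``default_power`` regardless of the sweep
    (one fixed power keeps all tissues comparable); with ``strict=True`` it
    is the smallest candidate whose |signed r^2| reaches ``r2_threshold``
    (falling back to the best-fitting candidate if none does).
    """
    if powers is None:
        powers = list(range(1, 21))
    S = similarity_matrix(m)
    r2s, mks = [], []
    for beta in powers:
        r2, mk = scale_free_fit(adjacency(S, beta), n_bins=n_bins)
        r2s.append(r2)
        mks.append(mk)
    chosen = default_power
    if strict:
        chosen = None
        for beta, r2 in zip(powers, r2s):
            if np.isfinite(r2) and abs(r2) >= r2_threshold:
                chosen = beta
                break
        if chosen is None:
            finite = [(abs(r2), beta) for beta, r2 in zip(powers, r2s) if np.isfinite(r2)]
            chosen = max(finite)[1] if finite else default_power
    return PowerDiagnostics(list(powers), r2s, mks, chosen)


def build_network(m: ExpressionMatrix, beta: int = DEFAULT_POWER) -> CoexpressionNetwork:
    """Full network construction: similarity -> adjacency -> TOM -> D."""
    S = similarity_matrix(m)
    A = adjacency(S, beta)
    Omega = tom(A)
    return CoexpressionNetwork(
        tissue=m.tissue, gene_ids=m.gene_ids, S=S, beta=beta, A=A,
        Omega=Omega, D=1.0 - Omega,
    )


def plot_power_sweep(diag: PowerDiagnostics, path: str | Path, tissue: str = "") -> None:
    """Two-panel diagnostic plot: power vs signed R^2, power vs mean k."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(diag.powers, diag.signed_r2, "o-")
    ax1.axhline(SCALE_FREE_R2_THRESHOLD, ls="--", c="red", lw=0.8)
    ax1.set_xlabel("soft power")
    ax1.set_ylabel("signed scale-free fit $R^2$")
    ax2.plot(diag.powers, diag.mean_connectivity, "o-")
    ax2.set_xlabel("soft power")
    ax2.set_ylabel("mean connectivity")
    fig.suptitle(tissue or "power sweep")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
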