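"""All-pairs module overlap testing across tissues.

Every non-grey module in one tissue is tested against every non-grey
module in every other tissue with a one-sided (enrichment) Fisher exact
test on the 2x2 membership table over the common gene universe.  The test
is one-sided because an edge means "these modules share more genes than
chance" — depletion is not a relationship here.  Module pairs with
p < alpha (raw, 0.05 by default, mirroring the original edge rule; an
optional Bonferroni mode is provided) become edges of the module overlap
graph, whose maximum clique downstream identifies modules conserved
across many tissues.

The hypergeometric tail is accumulated in log space (log-sum-exp over
log pmf terms), so p-values far below the smallest positive double
(~1e-308) still yield a finite log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .modules import ModulePartition

DEFAULT_ALPHA = 0.05
_LOG10E = np.log10(np.e)


def overlap_table(genes_a: set, genes_b: set, universe: set) -> tuple[int, int, int, int]:
    """2x2 contingency counts (both, a_only, b_only, neither) over a universe."""
    if not universe:
        raise ValueError("universe must be nonempty")
    if not genes_a <= universe or not genes_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    both = len(genes_a & genes_b)
    a_only = len(genes_a) - both
    b_only = len(genes_b) - both
    neither = len(universe) - both - a_only - b_only
    return both, a_only, b_only, neither


def log_fisher_p(table: tuple[int, int, int, int]) -> float:
    """Natural-log one-sided (upper tail) Fisher exact p for a 2x2 table.

    P(X >= both) where X ~ Hypergeometric(N, |a|, |b|) with the table's
    margins.  Computed as a log-sum-exp over log pmf terms, stable down to
    arbitrarily small p.  Empty margins give log(1) = 0.
    """
    both, a_only, b_only, neither = table
    if min(table) < 0:
        raise ValueError("table counts must be nonnegative")
    n = both + a_only + b_only + neither
    size_a = both + a_only
    size_b = both + b_only
    if both == 0 or size_a == 0 or size_b == 0:
        return 0.0
    hi = min(size_a, size_b)
    xs = np.arange(both, hi + 1)
    return float(logsumexp(hypergeom.logpmf(xs, n, size_a, size_b)))


def fisher_p(table: tuple[int, int, int, int]) -> float:
    """One-sided Fisher exact p (may underflow to 0 for extreme overlaps;
    use :func:`log_fisher_p` when the magnitude matters)."""
    return float(np.exp(log_fisher_p(table)))


def fisher_log10_p(table: tuple[int, int, int, int]) -> float:
    return log_fisher_p(table) * _LOG10E


@dataclass
class ModuleOverlapGraph:
    """Thresholded overlap graph plus the full (unthresholded) results table.

    ``graph`` nodes are ``(tissue, module_label)`` pairs; edges exist for
    inter-tissue pairs with p < alpha and carry the contingency counts and
    p-values.  ``results`` keeps every tested pair, one row each.
    """

    graph: nx.Graph = field(repr=False)
    results: pd.DataFrame = field(repr=False)
    alpha: float = DEFAULT_ALPHA
    universe_size: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_module_graph(
    partitions: list[ModulePartition],
    universe: set,
    alpha: float = DEFAULT_ALPHA,
    bonferroni: bool = False,
) -> ModuleOverlapGraph:
    """Test every inter-tissue non-grey module pair; threshold at alpha.

    With ``bonferroni=True`` the threshold becomes alpha / n_tests.
    """
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tissues = [p.tissue for p in partitions]
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue identifiers")
    for p in partitions:
        covered = set(p.assignment)
        if covered != universe:
            raise ValueError(
                f"partition for tissue {p.tissue!r} does not cover the universe"
            )
    module_sets = {p.tissue: dict(sorted(p.modules().items())) for p in partitions}

    rows = []
    for pa, pb in combinations(partitions, 2):
        for mod_a, genes_a in module_sets[pa.tissue].items():
            for mod_b, genes_b in module_sets[pb.tissue].items():
                table = overlap_table(genes_a, genes_b, universe)
                lp = log_fisher_p(table)
                rows.append(
                    (
                        pa.tissue, mod_a, pb.tissue, mod_b,
                        table[0], table[1], table[2], table[3],
                        lp * _LOG10E, float(np.exp(lp)),
                    )
                )
    results = pd.DataFrame(
        rows,
        columns=[
            "tissue_a", "module_a", "tissue_b", "module_b",
            "n11", "n10", "n01", "n00", "log10_p", "p",
        ],
    )
    n_tests = len(results)
    threshold = alpha / n_tests if (bonferroni and n_tests) else alpha

    g = nx.Graph()
    for p in partitions:
        for mod in module_sets[p.tissue]:
            g.add_node((p.tissue, mod))
    for row in results.itertuples(index=False):
        if row.p < threshold:
            g.add_edge(
                (row.tissue_a, row.module_a),
                (row.tissue_b, row.module_b),
                table=(row.n11, row.n10, row.n01, row.n00),
                p=row.p,
                log10_p=row.log10_p,
            )
    return ModuleOverlapGraph(g, results, alpha, len(universe))


def tissue_similarity(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per tissue pair: best (minimum) module-pair p and significant count.

    Ranking by ``min_log10_p`` orders tissue pairs from most to least
    similar in their module structure.  Minima are taken on the log scale
    so pairs remain ranked even when p underflows to zero.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["tissue_a", "tissue_b", "min_log10_p", "min_p", "n_significant"]
        )
    grouped = results.groupby(["tissue_a", "tissue_b"], sort=True)
    out = grouped.agg(
        min_log10_p=("log10_p", "min"),
        min_p=("p", "min"),
        n_significant=("p", lambda s: int((s < alpha).sum())),
    ).reset_index()
    return out.sort_values("min_log10_p", kind="mergesort").reset_index(drop=True)
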