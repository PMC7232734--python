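"""Hypergeometric gene-set enrichment against a GMT collection.

For a query gene set of size q drawn from a universe of size N, and a
term covering K universe genes, the enrichment p-value is the upper
hypergeometric tail P(X >= overlap), and

    fold enrichment = (overlap / q) / (K / N).

Reported corrections: Bonferroni (min(1, m*p) over the m tested terms)
and Benjamini-Hochberg step-up; the FDR column is an alias of the BH
value.  Terms are intersected with the universe before testing and
dropped when the intersection is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_LOG10E = np.log10(np.e)


@dataclass
class GeneSetCollection:
    """Term id -> (description, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def term_genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one term per line, ``term<TAB>description<TAB>gene...``.

    Duplicate genes within a term are deduplicated; a term with no genes,
    a duplicated term id, or a short line is a parse error reported with
    its line number.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected term, description and >=1 gene"
                )
            term_id, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: term {term_id!r} has no genes")
            if term_id in terms:
                raise ValueError(f"{path.name}:{lineno}: duplicate term {term_id!r}")
            terms[term_id] = (description, genes)
    return GeneSetCollection(terms, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def _log_upper_tail(n_universe: int, n_term: int, n_query: int, overlap: int) -> float:
    """Natural log of P(X >= overlap), X ~ Hypergeom(N, K, q); stable."""
    if overlap <= 0:
        return 0.0
    hi = min(n_term, n_query)
    xs = np.arange(overlap, hi + 1)
    return float(logsumexp(hypergeom.logpmf(xs, n_universe, n_term, n_query)))


def hypergeom_enrich(
    query: set, collection: GeneSetCollection, universe: set
) -> pd.DataFrame:
    """Enrichment of ``query`` in every term of ``collection``.

    Returns one row per tested term, sorted by ascending p (ties by term
    id), with columns mirroring the usual enrichment-table layout:
    term_id, description, overlap, query_size, term_size, universe_size,
    fold_enrichment, p_value, log10_p, bonferroni, benjamini, fdr.
    """
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_u = len(universe)
    q = len(query)
    rows = []
    for term_id in sorted(collection.terms):
        desc, genes = collection.terms[term_id]
        term_in_universe = genes & universe
        k = len(term_in_universe)
        if k == 0:
            continue
        overlap = len(query & term_in_universe)
        log_p = _log_upper_tail(n_u, k, q, overlap)
        fold = (overlap / q) / (k / n_u) if q else 0.0
        rows.append(
            {
                "term_id": term_id,
                "description": desc,
                "overlap": overlap,
                "query_size": q,
                "term_size": k,
                "universe_size": n_u,
                "fold_enrichment": fold,
                "p_value": float(np.exp(log_p)),
                "log10_p": log_p * _LOG10E,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "description", "overlap", "query_size", "term_size",
            "universe_size", "fold_enrichment", "p_value", "log10_p",
        ],
    )
    if df.empty:
        for col in ("bonferroni", "benjamini", "fdr"):
            df[col] = pd.Series(dtype=float)
        return df
    m = len(df)
    df["bonferroni"] = np.minimum(1.0, df["p_value"] * m)
    df["benjamini"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["fdr"] = df["benjamini"]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def enrich_clique(
    clique_report: pd.DataFrame,
    collection: GeneSetCollection,
    universe: set,
    bh_alpha: float = 0.05,
    min_member_fraction: float = 0.5,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Enrichment for every clique member plus a cross-member summary.

    Returns a mapping ``(tissue, module) -> enrichment table`` and a
    summary of terms significant (BH < ``bh_alpha``) in at least
    ``min_member_fraction`` of the members.
    """
    per_member: dict[tuple[str, str], pd.DataFrame] = {}
    term_hits: dict[str, int] = {}
    for row in clique_report.itertuples(index=False):
        genes = set(row.genes.split(",")) if row.genes else set()
        table = hypergeom_enrich(genes & universe, collection, universe)
        per_member[(row.tissue, row.module)] = table
        for term in table.loc[table["benjamini"] < bh_alpha, "term_id"]:
            term_hits[term] = term_hits.get(term, 0) + 1
    n_members = len(per_member)
    shared = [
        {"term_id": t, "n_members_significant": c, "member_fraction": c / n_members}
        for t, c in sorted(term_hits.items())
        if n_members and c / n_members >= min_member_fraction
    ]
    summary = pd.DataFrame(
        shared, columns=["term_id", "n_members_significant", "member_fraction"]
    )
    if not summary.empty:
        summary = summary.sort_values(
            ["n_members_significant", "term_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return per_member, summary
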