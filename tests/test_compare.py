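"""Fisher exact module overlap tests and the module overlap graph."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from coexatlas import (
    AtlasSpec,
    ModulePartition,
    PlantedModule,
    build_module_graph,
    build_network,
    detect_modules,
    fisher_log10_p,
    fisher_p,
    generate_atlas,
    log_fisher_p,
    normalize_matrix,
    overlap_table,
    tissue_similarity,
)
from oracles import exact_fisher_upper


class TestOverlapTable:
    def test_full_overlap(self):
        u = {f"g{i}" for i in range(10)}
        assert overlap_table(u, u, u) == (10, 0, 0, 0)

    def test_disjoint(self):
        u = {f"g{i}" for i in range(10)}
        a = {"g0", "g1"}
        b = {"g2", "g3", "g4"}
        assert overlap_table(a, b, u) == (0, 2, 3, 5)

    def test_partial(self):
        u = {f"g{i}" for i in range(10)}
        a = {"g1", "g2", "g3"}
        b = {"g2", "g3", "g4"}
        assert overlap_table(a, b, u) == (2, 1, 1, 6)

    def test_membership_violation(self):
        with pytest.raises(ValueError, match="subset"):
            overlap_table({"x"}, set(), {"g1"})

    def test_empty_universe(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_table(set(), set(), set())


class TestFisherP:
    def test_zero_overlap_is_one(self):
        assert fisher_p((0, 5, 7, 100)) == 1.0
        assert fisher_p((0, 0, 0, 0)) == 1.0

    def test_known_small_table(self):
        # P(X>=3) with margins 4/4 of 8 = (C(4,3)C(4,1)+C(4,4))/C(8,4) = 17/70
        assert fisher_p((3, 1, 1, 3)) == pytest.approx(17 / 70, rel=1e-12)

    def test_monotone_in_overlap_at_fixed_margins(self):
        # margins: |a| = 10, |b| = 12, N = 40
        ps = []
        for both in range(0, 11):
            table = (both, 10 - both, 12 - both, 40 - 22 + both)
            ps.append(fisher_p(table))
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            table = (int(a), int(b), int(c), int(d))
            expected = float(exact_fisher_upper(table))
            got = fisher_p(table)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    def test_log_space_survives_extreme_tables(self):
        # perfect overlap of two 600-gene halves: p = 1/C(1200, 600) ~ 1e-360
        lp = fisher_log10_p((600, 0, 0, 600))
        assert np.isfinite(lp)
        assert lp < -250

    def test_log_space_agrees_with_linear_space(self):
        for table in [(5, 3, 2, 20), (12, 0, 0, 12), (8, 1, 7, 30)]:
            p = fisher_p(table)
            assert np.log(p) == pytest.approx(log_fisher_p(table), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_fisher_p((-1, 2, 3, 4))


def _partition(tissue, modules, universe):
    assignment = {g: "grey" for g in universe}
    for label, genes in modules.items():
        for g in genes:
            assignment[g] = label
    return ModulePartition(tissue, assignment, min_module_size=0)


class TestBuildModuleGraph:
    def test_identical_partitions_give_strong_edge(self):
        universe = {f"g{i:03d}" for i in range(100)}
        half = set(sorted(universe)[:50])
        p1 = _partition("t1", {"blue": half}, universe)
        p2 = _partition("t2", {"red": half}, universe)
        g = build_module_graph([p1, p2], universe)
        assert g.n_edges == 1
        edge = g.graph.edges[("t1", "blue"), ("t2", "red")]
        assert edge["p"] == pytest.approx(float(exact_fisher_upper((50, 0, 0, 50))))
        assert edge["p"] < 1e-20

    def test_single_tissue_no_edges(self):
        universe = {f"g{i}" for i in range(20)}
        p1 = _partition("t1", {"blue": set(sorted(universe)[:10])}, universe)
        g = build_module_graph([p1], universe)
        assert g.n_nodes == 1
        assert g.n_edges == 0

    def test_grey_excluded_and_every_pair_tested_once(self):
        universe = {f"g{i:02d}" for i in range(30)}
        genes = sorted(universe)
        p1 = _partition("t1", {"blue": set(genes[:10]), "red": set(genes[10:20])}, universe)
        p2 = _partition("t2", {"blue": set(genes[:10])}, universe)
        g = build_module_graph([p1, p2], universe)
        assert len(g.results) == 2  # 2 modules x 1 module
        assert not any("grey" in (r.module_a, r.module_b) for r in g.results.itertuples())
        pairs = set(
            (r.tissue_a, r.module_a, r.tissue_b, r.module_b)
            for r in g.results.itertuples()
        )
        assert len(pairs) == 2

    def test_no_intra_tissue_edges(self):
        universe = {f"g{i:02d}" for i in range(30)}
        genes = sorted(universe)
        p1 = _partition("t1", {"blue": set(genes[:10]), "red": set(genes[:10])}, universe)
        p2 = _partition("t2", {"blue": set(genes[:10])}, universe)
        g = build_module_graph([p1, p2], universe)
        assert all(u[0] != v[0] for u, v in g.graph.edges)

    def test_mismatched_universe_rejected(self):
        universe = {"g1", "g2"}
        p1 = _partition("t1", {"blue": {"g1"}}, universe)
        p2 = _partition("t2", {"blue": {"g1"}}, {"g1"})
        with pytest.raises(ValueError, match="cover"):
            build_module_graph([p1, p2], universe)

    def test_bonferroni_mode_tightens_threshold(self):
        universe = {f"g{i:03d}" for i in range(60)}
        genes = sorted(universe)
        rng = np.random.default_rng(0)
        mods1 = {"blue": set(genes[:20]), "red": set(genes[20:40])}
        perm = rng.permutation(genes)
        mods2 = {"blue": set(perm[:20]), "red": set(perm[20:40])}
        p1 = _partition("t1", mods1, universe)
        p2 = _partition("t2", mods2, universe)
        raw = build_module_graph([p1, p2], universe)
        bonf = build_module_graph([p1, p2], universe, bonferroni=True)
        assert bonf.n_edges <= raw.n_edges

    def test_null_edge_rate_near_nominal(self):
        # shuffled labels: rejection probability of the one-sided exact test
        # is computable from the hypergeometric null; the empirical edge rate
        # should sit near it
        universe = [f"g{i:03d}" for i in range(300)]
        sizes = [50, 40, 30, 25]
        observed, expected = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            parts = []
            for t in range(2):
                perm = list(rng.permutation(universe))
                mods, start = {}, 0
                for i, s in enumerate(sizes):
                    mods[f"m{i}"] = set(perm[start : start + s])
                    start += s
                parts.append(_partition(f"t{t}", mods, set(universe)))
            g = build_module_graph(parts, set(universe))
            observed.append((g.results["p"] < 0.05).mean())
            for r in g.results.itertuples():
                n_a, n_b = r.n11 + r.n10, r.n11 + r.n01
                n = len(universe)
                ks = np.arange(0, min(n_a, n_b) + 1)
                tail = np.array(
                    [float(exact_fisher_upper((k, n_a - k, n_b - k, n - n_a - n_b + k))) for k in ks]
                )
                k_star = ks[tail < 0.05]
                exp_p = hypergeom.sf(k_star[0] - 1, n, n_a, n_b) if len(k_star) else 0.0
                expected.append(exp_p)
        assert abs(np.mean(observed) - np.mean(expected)) < 0.05


class TestTissueSimilarity:
    def test_shared_module_pair_ranks_first(self):
        # 3 tissues; tissues 1 and 2 share a planted module absent from 3
        mods = (PlantedModule("shared12", 40, 0.9, frozenset(["T01", "T02"])),)
        spec = AtlasSpec(3, 300, 80, mods, seed=21)
        matrices, _ = generate_atlas(spec)
        parts = []
        universe = None
        for m in matrices:
            net = build_network(normalize_matrix(m), beta=6)
            parts.append(
                detect_modules(net.D, net.gene_ids, tissue=m.tissue, min_module_size=20)
            )
            universe = set(net.gene_ids)
        g = build_module_graph(parts, universe)
        sim = tissue_similarity(g.results)
        top = sim.iloc[0]
        assert {top.tissue_a, top.tissue_b} == {"T01", "T02"}
        others = sim.iloc[1:]
        assert (top.min_log10_p < others["min_log10_p"]).all()

    def test_empty_results(self):
        import pandas as pd

        sim = tissue_similarity(pd.DataFrame(columns=["tissue_a", "tissue_b", "log10_p", "p"]))
        assert sim.empty
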