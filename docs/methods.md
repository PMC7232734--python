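# Methods

## Scope and model

`coexatlas` compares gene coexpression structure across tissues (or any
conditions) sharing a gene universe. Each tissue gets its own weighted
network; tissues are then related only through module *membership*
overlap, never through expression values — two tissues are "similar" when
their modules are built from the same genes, even if those genes'
expression levels differ entirely between tissues.

## Normalization

All tissues are restricted to the intersection of their gene sets (rows
reordered lexicographically so matrices align). Each gene's profile is
then mapped to standard-normal quantiles of its ranks across samples:
Φ⁻¹((r − 3/8)/(n + 1/4)), the Blom variant of the rank inverse-normal
transform, with average ranks for ties. Any rank-preserving offset would
serve; Blom is the conventional choice. The transform makes each gene
marginally normal, makes downstream Pearson correlation a rank
correlation (invariant to monotone per-gene distortions such as the
FPKM scale), and is idempotent on tie-free data. Constant rows are an
error — they carry no correlation information and should be filtered
upstream.

Only per-gene normalization is performed; per-sample steps (library-size
scaling, quantile normalization across samples) are assumed already done
by whatever produced the input.

## Network construction

- **Similarity** S = |Pearson correlation|; the absolute value treats
  strongly negative coexpression as connection, giving an unsigned
  network.
- **Adjacency** A = S^β elementwise. The power β soft-thresholds weak
  correlations toward zero. Default β = 6 for every tissue — a single
  shared power keeps networks comparable across conditions; the per-tissue
  "strict" mode instead chooses the smallest β reaching scale-free fit
  R² ≥ 0.8 (reporting the full sweep either way).
- **Scale-free fit**: connectivities k_m = Σ_{u≠m} a_mu are binned into
  10 equal-width bins (empty and nonpositive-mean bins dropped); the
  statistic is sign(slope) × r² of log10(mean k) versus log10(bin
  frequency). A weighted network has continuous k, so binning stands in
  for the integer degree distribution. With fewer than two usable bins
  (e.g. a regular graph) the fit is undefined and returned as NaN, not an
  exception.
- **Topological overlap**:
  ω_mn = (ℓ_mn + a_mn)/(min(k_m, k_n) + 1 − a_mn), ℓ_mn = Σ_{u≠m,n} a_mu a_un.
  Connectivity excludes the self-term, which bounds ω in [0, 1]
  (ℓ_mn ≤ min(k_m, k_n) − a_mn since a ≤ 1). Diagonals: ω_mm = 1, so the
  clustering dissimilarity D = 1 − ω has zero diagonal. The matrix form
  (zero-diagonal A, ℓ = A₀², vectorized min) is verified against a naive
  triple loop to 1e−12.

## Module detection

Average linkage (UPGMA) over D is used — the norm for TOM dissimilarity.
Two cuts are provided:

- **Static**: connected components below a fixed height; components
  smaller than `min_module_size` become grey.
- **Dynamic** (default): a top-down walk of the dendrogram. A subtree is
  accepted as a branch when the height drop from its parent's merge to
  its own top merge is at least `gap = f(deep_split) × (height range)`,
  with f = (0.45, 0.35, 0.25, 0.15, 0.05) for `deep_split` 0–4 (default
  2). Accepted branches are recursively split while *both* children are
  themselves qualifying branches of at least `min_module_size` leaves;
  otherwise the whole branch (including small late-joining stragglers)
  is one module. Leaves never inside an accepted branch are grey. The
  root is never itself a branch; a perfectly flat tree (all merges at one
  height) is the documented degenerate case and yields a single module
  when it meets the size floor. This is a behavior-level design: tight
  low-height clusters separated from the loose background mass are found
  even when no single cut height isolates them, which is the property the
  recovery tests pin down.

Defaults `min_module_size = 30`, `deep_split = 2` (the demonstration
config lowers the size floor to 20 because its tissue-specific planted
modules have 30 genes). Modules are labeled from a fixed color palette by
decreasing size (ties broken by smallest member gene id); grey is
reserved for unassigned genes. No eigengene-based module merging is
performed.

Raising `min_module_size` can only remove or fuse modules, never create
them; this monotonicity is asserted in tests.

## Module overlap and tissue similarity

For every pair of non-grey modules from *different* tissues, the 2×2
table (both, a only, b only, neither) over the common universe is tested
with the one-sided (enrichment) Fisher exact test: p = P(X ≥ overlap)
under the hypergeometric null with the table's margins. One-sided because
only over-overlap means "related"; a two-sided test would differ and is
deliberately not used. Edges use raw p < α (default 0.05) with no
multiple-testing correction — the historical convention for this graph —
with an optional Bonferroni edge mode. The full results table retains
every tested pair regardless of significance.

Shared modules across many tissues produce overlaps whose p underflows
double precision (a 50-gene module shared by two 600-gene tissues is
already ~1e−74; real atlases reach 1e−290). The tail is therefore
accumulated as a log-sum-exp over `hypergeom.logpmf` terms; `p` may
round to 0.0 but `log10_p` is always finite, and all ranking (tissue
similarity, minimum p per tissue pair) happens on the log scale.
Tissue-level similarity is summarized as the minimum module-pair p and
the count of significant module pairs per tissue pair.

## Maximum clique

The module graph has no intra-tissue edges, so any clique picks at most
one module per tissue; the maximum clique is the largest set of modules
mutually conserved across tissues. The search is an exact
branch-and-bound on bitset adjacency with a greedy-coloring upper bound.
Pruning is strict (branches that can only tie are explored), so among
equal-size maximum cliques the lexicographically smallest node set is
returned — determinism matters more than the marginal speed here.
Branching steps are counted against a budget (default 10⁷); exhausting
it falls back to a greedy construction with swap-based local search and
the result is flagged `exact=False`. Exactness is verified against 2¹⁵
subset enumeration on random 15-node graphs at densities 0.3/0.5/0.7.

## Enrichment

Plain hypergeometric upper-tail enrichment of a gene set against a GMT
collection: terms are intersected with the universe first (empty
intersections dropped), fold enrichment = (overlap/query)/(term/universe),
and corrections are Bonferroni and Benjamini–Hochberg, with an `fdr`
column aliasing BH. The universe for module enrichment is the tissue's
network gene set — genes outside it could never have been module members.
No ontology-graph propagation is performed; annotation is whatever the
GMT says.

## Synthetic atlas

Each planted module is a single latent factor per (tissue, module):
member profile x_g = λ·e + √(1−λ²)·ε_g with e, ε standard normal, so
member pairs correlate at λ² in expectation (checked at n = 2000 samples
to ±0.03). Background genes, and module members in tissues where the
module is inactive, are i.i.d. normal scaled by `noise_sd` (default 1).
Shared modules reuse the same member-gene block in every active tissue,
while eigengenes are independent per tissue — total membership overlap,
no expression sharing, exactly what the Fisher-overlap stage can detect.
Gene/sample identifiers are deterministic (`G000001`, `T01_S001`), and
the whole atlas is reproducible bit-for-bit from its seed.

Defaults for the demonstration: 4 tissues, 600 genes, 100 samples per
tissue (toward the lower end of realistic cohort sizes for tissue
atlases), one 50-gene shared module and one 30-gene specific module per
tissue at λ = 0.9. What the generator does *not* emulate: count-scale
(FPKM-like) marginal distributions, library-size or batch effects,
overlapping module membership, correlated eigengenes between modules, or
hub-gene degree heterogeneity inside modules. Passing recovery tests
therefore demonstrates the machinery is correct, not that module
detection is robust to those real-data complications.

## Numerical choices and edge cases

- Similarity clipped to [0, 1]; all TOM denominators of 0 (isolated node
  pairs) return ω = 0.
- Tie-breaks are deterministic throughout: clusters sorted by (−size,
  smallest gene id); enrichment rows by (p, term id); clique by
  lexicographic node order; UPGMA ties follow the linkage
  implementation's fixed ordering.
- `fisher_p` of a table with an empty margin is 1 (P(X ≥ 0) = 1), never
  an error.
- Pipeline runs are deterministic given seed; TOM dissimilarity matrices
  are cached per (tissue, power) under the output directory so re-runs
  with changed downstream parameters skip network construction.

## Problem sizes used in validation

The suite validates on 600-gene, 100-sample, 4-tissue atlases (dense
600×600 matrix algebra keeps the full run a few seconds), exhaustive
Fisher tables with margins ≤ 30, 30-gene TOM oracles, and 15-node clique
enumeration; the oracles scale no further, and the implementation scales
as O(G²·samples + G³-ish TOM) per tissue.

## Known limitations

- Unsigned networks with plain Pearson only (no biweight midcorrelation,
  no signed variant).
- No PAM-like hybrid dynamic cut and no module-eigengene computation or
  merging.
- Full dense matrices: ~20k genes × 20k genes per tissue is the practical
  ceiling without block decomposition.
- The dynamic cut is a behavior-level implementation of branch-shape
  cutting, not a port of any reference code; on pathological dendrograms
  (gradual height ramps with no separated branches) it leaves genes grey
  rather than forcing modules.
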