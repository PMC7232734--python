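"""Synthetic multi-tissue expression atlas with planted coexpression modules.

The generator emulates the structure a cross-tissue coexpression analysis
is meant to detect: several tissues sharing one gene universe, a few
planted modules — some active in every tissue (the ubiquitous immune-like
module seen in real atlases), some tissue-specific — and uncorrelated
background genes.

Each planted module follows a single-factor model.  Within an active
tissue, every member gene's profile is

    x_g = lambda * e + sqrt(1 - lambda^2) * eps_g

where ``e`` is a latent per-(tissue, module) eigengene sampled once per
tissue (standard normal over samples), ``eps_g`` is i.i.d. standard normal
noise, and ``lambda`` is the factor loading.  Two member genes therefore
have expected Pearson correlation lambda^2.  Latent eigengenes are drawn
independently per tissue: what is shared across tissues is the module's
*membership*, not its expression values — exactly the signal a gene-overlap
test can see.  Background genes, and members of modules inactive in a
tissue, are i.i.d. normal scaled by ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

BACKGROUND_LABEL = "background"


@dataclass(frozen=True)
class PlantedModule:
    """One planted module: its size, factor loading, and active tissues."""

    module_id: str
    size: int
    loading: float
    tissues: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 < self.loading < 1.0:
            raise ValueError(
                f"module {self.module_id!r}: loading must be in (0, 1), got {self.loading}"
            )
        if self.size < 2:
            raise ValueError(
                f"module {self.module_id!r}: size must be >= 2, got {self.size}"
            )
        if not self.tissues:
            raise ValueError(f"module {self.module_id!r}: tissues must be nonempty")
        object.__setattr__(self, "tissues", frozenset(self.tissues))


@dataclass(frozen=True)
class AtlasSpec:
    """Full description of a synthetic atlas; deterministic given ``seed``."""

    n_tissues: int
    n_genes: int
    n_samples_per_tissue: int
    planted_modules: tuple[PlantedModule, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_modules", tuple(self.planted_modules))
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if self.n_samples_per_tissue < 3:
            raise ValueError(
                f"n_samples_per_tissue must be >= 3, got {self.n_samples_per_tissue}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        total = sum(m.size for m in self.planted_modules)
        if total > self.n_genes:
            raise ValueError(
                f"planted module sizes sum to {total} > n_genes = {self.n_genes}"
            )
        ids = [m.module_id for m in self.planted_modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module_ids must be unique")
        known = set(self.tissue_ids)
        for m in self.planted_modules:
            unknown = set(m.tissues) - known
            if unknown:
                raise ValueError(
                    f"module {m.module_id!r} references unknown tissues {sorted(unknown)}"
                )

    @property
    def tissue_ids(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:06d}" for i in range(self.n_genes)]

    def module_members(self) -> dict[str, list[str]]:
        """Disjoint member-gene blocks, assigned in declaration order."""
        genes = self.gene_ids
        out: dict[str, list[str]] = {}
        start = 0
        for m in self.planted_modules:
            out[m.module_id] = genes[start : start + m.size]
            start += m.size
        return out


def generate_atlas(spec: AtlasSpec) -> tuple[list[ExpressionMatrix], pd.DataFrame]:
    """Generate one expression matrix per tissue plus the planted truth table.

    Returns
    -------
    matrices
        One :class:`ExpressionMatrix` per tissue, all over the same gene
        universe.
    truth
        DataFrame with columns ``tissue``, ``gene``, ``module_id`` covering
        every (tissue, gene); ``module_id`` is ``"background"`` for genes
        without a planted module active in that tissue.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    members = spec.module_members()
    gene_pos = {g: i for i, g in enumerate(genes)}

    matrices: list[ExpressionMatrix] = []
    truth_rows: list[pd.DataFrame] = []
    for t_idx, tissue in enumerate(spec.tissue_ids):
        n_s = spec.n_samples_per_tissue
        x = spec.noise_sd * rng.standard_normal((spec.n_genes, n_s))
        labels = np.full(spec.n_genes, BACKGROUND_LABEL, dtype=object)
        for mod in spec.planted_modules:
            if tissue not in mod.tissues:
                continue
            eigengene = rng.standard_normal(n_s)
            eps = rng.standard_normal((mod.size, n_s))
            rows = [gene_pos[g] for g in members[mod.module_id]]
            lam = mod.loading
            x[rows] = lam * eigengene + np.sqrt(1.0 - lam * lam) * eps
            labels[rows] = mod.module_id
        samples = [f"{tissue}_S{j + 1:03d}" for j in range(n_s)]
        matrices.append(
            ExpressionMatrix(tissue, pd.DataFrame(x, index=genes, columns=samples))
        )
        truth_rows.append(
            pd.DataFrame({"tissue": tissue, "gene": genes, "module_id": labels})
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return matrices, truth


def write_atlas(
    matrices: list[ExpressionMatrix], truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-tissue TSVs and the truth table; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for m in matrices:
        p = out_dir / f"{m.tissue}.expression.tsv"
        m.to_tsv(p)
        paths[m.tissue] = p
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def demo_atlas_spec(seed: int = 0) -> AtlasSpec:
    """The bundled demonstration atlas.

    Four tissues over 600 common genes: one 50-gene module shared by all
    tissues (loading 0.9), one 30-gene tissue-specific module per tissue,
    and background noise.  The shared module makes the expected maximum
    clique span all four tissues.
    """
    tissues = [f"T{i + 1:02d}" for i in range(4)]
    mods = [PlantedModule("shared", 50, 0.9, frozenset(tissues))]
    for t in tissues:
        mods.append(PlantedModule(f"specific_{t}", 30, 0.9, frozenset([t])))
    return AtlasSpec(
        n_tissues=4,
        n_genes=600,
        n_samples_per_tissue=100,
        planted_modules=tuple(mods),
        noise_sd=1.0,
        seed=seed,
    )
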