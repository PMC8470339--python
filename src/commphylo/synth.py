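"""Synthetic fixtures: Yule trees, structured incidence tables, attributes.

Community assembly modes
------------------------
neutral        uniform sampling from the tip pool at the drawn richness
clustered      pick a random focal tip; include tip i with weight
               exp(-d(focal, i) / tau), sampled without replacement
overdispersed  same, with weight 1 - exp(-d(focal, i) / tau)

Small tau makes clustering/overdispersion strong relative to the tree's
depth. Weighted sampling without replacement is implemented by sequential
draws with renormalisation, which pins down exact reproducibility.

Everything is reproducible from the config seed, and the writer emits the
same plain-text formats the pipeline reads (Newick + CSV), so a full
end-to-end fixture is one call (or one CLI command).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .community import (
    LIFE_FORMS,
    WETLAND_TYPES,
    CommunityTable,
    SiteMetadata,
    SpeciesAttributes,
)
from .tree import Phylogeny, TreeNode, cophenetic, write_newick_file

__all__ = [
    "SynthConfig",
    "generate_tree",
    "generate_communities",
    "generate_attributes",
    "generate_metadata",
    "write_fixture",
]

AssemblyMode = Literal["neutral", "clustered", "overdispersed"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the generator; defaults give a mid-sized neutral fixture."""

    n_tips: int = 200
    n_sites: int = 28
    richness_range: tuple[int, int] = (10, 40)
    assembly: AssemblyMode = "neutral"
    tau: float = 1.0
    lifeform_mix: tuple[float, float, float, float] = (0.30, 0.60, 0.08, 0.02)
    dominant_rate: float = 0.1
    invasive_rate: float = 0.05
    flag_mode: Literal["independent", "clade"] = "independent"
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.n_tips):
            raise ValueError(
                f"richness_range {self.richness_range} infeasible for "
                f"{self.n_tips} tips"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if abs(sum(self.lifeform_mix) - 1.0) > 1e-9:
            raise ValueError("lifeform_mix must sum to 1")
        if self.assembly not in ("neutral", "clustered", "overdispersed"):
            raise ValueError(f"unknown assembly mode {self.assembly!r}")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def generate_tree(cfg: SynthConfig) -> Phylogeny:
    """Unit-rate Yule (pure-birth) tree; ultrametric by construction.

    Lineages split at exponential waiting times until ``n_tips`` are
    present, then all pending branches are extended by one final draw.
    """
    rng = _rng(cfg, 0)
    width = len(str(cfg.n_tips))
    # active lineages as nodes whose edge length is still growing
    root = TreeNode(length=None)
    active = [root]
    while len(active) < cfg.n_tips:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length = (node.length or 0.0) + wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        left, right = TreeNode(length=0.0), TreeNode(length=0.0)
        parent.children = [left, right]
        active.extend([left, right])
    final = rng.exponential(1.0 / len(active))
    for node in active:
        node.length = (node.length or 0.0) + final
    tips = [n for n in root.preorder() if n.is_tip]  # deterministic order
    for i, node in enumerate(tips):
        node.label = f"sp{i + 1:0{width}d}"
    root.length = None  # no root edge
    return Phylogeny(root)


def _weighted_sample_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted draws with renormalisation."""
    w = weights.astype(float).copy()
    chosen = np.empty(size, dtype=np.intp)
    for k in range(size):
        if w.sum() <= 0:  # degenerate weights: fall back to uniform on rest
            w = (w >= 0).astype(float)
            w[chosen[:k]] = 0.0
        p = w / w.sum()
        pick = rng.choice(len(w), p=p)
        chosen[k] = pick
        w[pick] = 0.0
    return chosen


def generate_communities(tree: Phylogeny, cfg: SynthConfig) -> CommunityTable:
    """Sites x species incidence with the configured assembly structure."""
    rng = _rng(cfg, 1)
    dist = cophenetic(tree)
    labels = list(dist.labels)
    n = len(labels)
    lo, hi = cfg.richness_range
    incidence = np.zeros((cfg.n_sites, n), dtype=np.int8)
    for s in range(cfg.n_sites):
        richness = int(rng.integers(lo, hi + 1))
        if cfg.assembly == "neutral":
            idx = rng.choice(n, size=richness, replace=False)
        else:
            focal = int(rng.integers(n))
            d = dist.values[focal]
            decay = np.exp(-d / cfg.tau)
            if cfg.assembly == "clustered":
                weights = decay
            else:
                weights = 1.0 - decay
            weights = weights.copy()
            weights[focal] = 0.0  # focal included unconditionally
            others = _weighted_sample_without_replacement(
                weights, richness - 1, rng
            )
            idx = np.concatenate([[focal], others])
        incidence[s, idx] = 1
    sites = tuple(f"site{s + 1:02d}" for s in range(cfg.n_sites))
    return CommunityTable(sites, tuple(labels), incidence)


def _clade_tips(tree: Phylogeny, target: int, rng: np.random.Generator) -> set[str]:
    """Tips of the internal clade whose size is closest to ``target``."""
    best: tuple[int, list[str]] | None = None
    candidates = []
    for node in tree.root.preorder():
        if node.is_tip or node is tree.root:
            continue
        tips = [t.label for t in node.preorder() if t.is_tip]
        gap = abs(len(tips) - target)
        candidates.append((gap, tips))
    candidates.sort(key=lambda x: x[0])
    best_gap = candidates[0][0]
    ties = [tips for gap, tips in candidates if gap == best_gap]
    return set(ties[int(rng.integers(len(ties)))])


def generate_attributes(tree: Phylogeny, cfg: SynthConfig) -> SpeciesAttributes:
    """Life forms drawn from the configured mix; flags independent or
    concentrated in one clade (``flag_mode='clade'``)."""
    rng = _rng(cfg, 2)
    species = tree.tip_labels
    forms = rng.choice(len(LIFE_FORMS), size=len(species), p=cfg.lifeform_mix)
    table = pd.DataFrame(index=pd.Index(species, name="species"))
    table["life_form"] = [LIFE_FORMS[i] for i in forms]
    for flag, rate in (
        ("dominant", cfg.dominant_rate), ("invasive", cfg.invasive_rate)
    ):
        if rate <= 0:
            table[flag] = False
        elif cfg.flag_mode == "independent":
            table[flag] = rng.random(len(species)) < rate
        else:
            target = max(2, round(rate * len(species)))
            clade = _clade_tips(tree, target, rng)
            table[flag] = [sp in clade for sp in species]
    return SpeciesAttributes(table)


def generate_metadata(cfg: SynthConfig) -> SiteMetadata:
    """Assign wetland types to sites cyclically (deterministic)."""
    sites = [f"site{s + 1:02d}" for s in range(cfg.n_sites)]
    types = [WETLAND_TYPES[s % len(WETLAND_TYPES)] for s in range(cfg.n_sites)]
    frame = pd.DataFrame(
        {"wetland_type": types}, index=pd.Index(sites, name="site")
    )
    return SiteMetadata(frame)


def write_fixture(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write tree + all three tables; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = generate_tree(cfg)
    table = generate_communities(tree, cfg)
    attrs = generate_attributes(tree, cfg)
    meta = generate_metadata(cfg)

    paths = {
        "tree": outdir / "tree.nwk",
        "community": outdir / "community.csv",
        "attributes": outdir / "attributes.csv",
        "metadata": outdir / "metadata.csv",
    }
    write_newick_file(tree, paths["tree"])
    table.to_frame().rename_axis("site").to_csv(paths["community"])
    attrs.table.rename_axis("species").to_csv(paths["attributes"])
    meta.table.rename_axis("site").to_csv(paths["metadata"])
    return paths
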