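"""Life-form composition tables and group-level phylogenetic statistics.

Group statistics treat a flagged species set (e.g. dominant or invasive
species pooled over all sites) as a single assemblage: its NTI against the
pool null, and its nearest-taxon separation from the complement set with a
seeded label-permutation reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community import (
    LIFE_FORMS,
    CommunityError,
    CommunityTable,
    SiteMetadata,
    SpeciesAttributes,
)
from .metrics import MetricError, mntd_between, tree_index
from .nullmodels import (
    NullModelConfig,
    UndefinedSESError,
    null_distribution_mntd,
    ses,
    site_rng,
)
from .tree import DistanceMatrix, Phylogeny, cophenetic

__all__ = [
    "ProportionTable",
    "GroupSeparation",
    "lifeform_proportions",
    "group_nti",
    "group_separation",
    "group_separation_permutation",
]


@dataclass(frozen=True)
class ProportionTable:
    """Per-site life-form shares (rows sum to 1) and per-type ranges."""

    per_site: pd.DataFrame          # sites x life forms, proportions
    per_type: pd.DataFrame | None   # type x (life form min/max), or None

    def __post_init__(self):
        sums = self.per_site.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("life-form proportions must sum to 1 per site")


def lifeform_proportions(
    table: CommunityTable,
    attrs: SpeciesAttributes,
    meta: SiteMetadata | None = None,
) -> ProportionTable:
    """Share of each life form among the species present at each site.

    With site metadata, also the min-max range of each life form's share
    across the sites of each wetland type.
    """
    known = set(attrs.species)
    missing = sorted(set(table.pool()) - known)
    if missing:
        raise CommunityError(f"species without attributes: {missing}")

    rows = {}
    for site in table.sites:
        species = table.site_species(site)
        forms = [attrs.life_form(sp) for sp in species]
        total = len(species)
        rows[site] = {lf: forms.count(lf) / total for lf in LIFE_FORMS}
    per_site = pd.DataFrame.from_dict(rows, orient="index")[list(LIFE_FORMS)]

    per_type = None
    if meta is not None:
        meta.check_covers(table)
        records = []
        types = sorted({meta.wetland_type(s) for s in table.sites})
        for t in types:
            sites = [s for s in table.sites if meta.wetland_type(s) == t]
            block = per_site.loc[sites]
            rec: dict[str, float | str | int] = {
                "wetland_type": t, "n_sites": len(sites)
            }
            for lf in LIFE_FORMS:
                rec[f"{lf}_min"] = float(block[lf].min())
                rec[f"{lf}_max"] = float(block[lf].max())
            records.append(rec)
        per_type = pd.DataFrame(records).set_index("wetland_type")
    return ProportionTable(per_site, per_type)


def group_nti(
    tree: Phylogeny,
    group: Iterable[str],
    pool: Sequence[str],
    cfg: NullModelConfig | None = None,
    dist: DistanceMatrix | None = None,
) -> float:
    """NTI of one species group treated as a single assemblage vs the pool.

    Raises :class:`UndefinedSESError` when the null sd is zero (e.g. the
    group *is* the pool) and :class:`MetricError` for groups of size < 2.
    """
    cfg = cfg or NullModelConfig()
    group_list = sorted(set(group))
    if len(group_list) < 2:
        raise MetricError("group_nti requires a group of >= 2 species")
    if not set(group_list).issubset(set(pool)):
        raise MetricError("group must be a subset of the pool")
    if dist is None:
        dist = cophenetic(tree)
    order = {lab: i for i, lab in enumerate(dist.labels)}
    sub = dist.values[np.ix_(
        [order[sp] for sp in group_list], [order[sp] for sp in group_list]
    )].copy()
    np.fill_diagonal(sub, np.inf)
    mntd_obs = float(sub.min(axis=1).mean())

    pool_idx = np.array([order[sp] for sp in pool], dtype=np.intp)
    rng = site_rng(cfg.seed, 0, stream=2)
    null = null_distribution_mntd(
        dist.values, pool_idx, len(group_list), cfg.replicates, rng
    )
    return ses(mntd_obs, null, negate=True)


def group_separation(
    dist: DistanceMatrix,
    group: Iterable[str],
    complement: Iterable[str],
) -> float:
    """Mean nearest-taxon distance between a group and its complement."""
    return mntd_between(dist, list(group), list(complement))


@dataclass(frozen=True)
class GroupSeparation:
    """Observed between-group MNTD with a label-permutation reference."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_greater: float  # fraction of permutations >= observed (incl. observed)
    replicates: int


def group_separation_permutation(
    dist: DistanceMatrix,
    group: Iterable[str],
    complement: Iterable[str],
    replicates: int = 999,
    seed: int = 0,
) -> GroupSeparation:
    """Calibrate group separation by shuffling group labels.

    Group/complement sizes are preserved; species are reassigned at random
    ``replicates`` times. ``p_greater`` uses the (r+1)/(n+1) convention.
    """
    group_list = sorted(set(group))
    comp_list = sorted(set(complement))
    observed = mntd_between(dist, group_list, comp_list)
    all_species = sorted(set(group_list) | set(comp_list))
    n_group = len(group_list)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    null = np.empty(replicates)
    for r in range(replicates):
        perm = rng.permutation(len(all_species))
        g = [all_species[i] for i in perm[:n_group]]
        c = [all_species[i] for i in perm[n_group:]]
        null[r] = mntd_between(dist, g, c)
    sd = float(null.std(ddof=1))
    mean = float(null.mean())
    ses_value = (observed - mean) / sd if sd > 0 else float("nan")
    p = (np.sum(null >= observed) + 1.0) / (replicates + 1.0)
    return GroupSeparation(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        ses=ses_value,
        p_greater=float(p),
        replicates=replicates,
    )
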