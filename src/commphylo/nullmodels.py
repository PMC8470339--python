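"""Richness-preserving randomisation nulls and standardised effect sizes.

For each site, ``replicates`` random assemblages of the observed richness
are drawn from the pooled species list (uniformly by default, optionally
weighted by occurrence frequency). Observed Faith's PD and MNTD are then
standardised against the null mean and standard deviation:

    PDI =  (PD_obs   - mean(PD_null))   / sd(PD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

Positive NTI means taxa are closer relatives than expected (clustering);
negative means overdispersion. Standard deviations use the n-1 denominator.

Randomness is reproducible: each site gets its own substream seeded from
(seed, site index), so adding a site never perturbs other sites' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable
from .metrics import MetricError, tree_index
from .tree import Phylogeny, cophenetic

__all__ = [
    "NullModelError",
    "UndefinedSESError",
    "NullModelConfig",
    "NullDistribution",
    "DiversityReport",
    "sample_null",
    "ses",
    "null_distribution_pd",
    "null_distribution_mntd",
    "pdi_nti_report",
]


class NullModelError(ValueError):
    """Invalid null-model configuration or inputs."""


class UndefinedSESError(NullModelError):
    """SES undefined because the null standard deviation is zero."""

    def __init__(self, observed: float, null_mean: float):
        self.observed = observed
        self.null_mean = null_mean
        super().__init__(
            f"SES undefined: null sd is 0 (observed={observed}, "
            f"null mean={null_mean})"
        )


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for the richness-preserving null.

    ``pool=None`` means the union of species observed at >= 1 site.
    ``weighting='uniform'`` draws species equiprobably; ``'occurrence'``
    weights each species by the number of sites it occupies.
    """

    replicates: int = 999
    seed: int = 0
    pool: tuple[str, ...] | None = None
    weighting: Literal["uniform", "occurrence"] = "uniform"
    include_root: bool = True

    def __post_init__(self):
        if self.replicates < 2:
            raise NullModelError("replicates must be >= 2")
        if self.weighting not in ("uniform", "occurrence"):
            raise NullModelError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Replicate values of one metric under the null, with summary stats."""

    metric: str
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise NullModelError("a null distribution needs >= 2 replicates")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mean", float(v.mean()))
        object.__setattr__(self, "sd", float(v.std(ddof=1)))


@dataclass(frozen=True)
class DiversityReport:
    """Per-site richness, observed PD/MNTD, null summaries, PDI and NTI."""

    table: pd.DataFrame
    replicates: int
    seed: int

    COLUMNS = (
        "site",
        "richness",
        "pd_obs",
        "pd_null_mean",
        "pd_null_sd",
        "pdi",
        "mntd_obs",
        "mntd_null_mean",
        "mntd_null_sd",
        "nti",
        "note",
    )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def site_rng(seed: int, site_index: int, stream: int = 0) -> np.random.Generator:
    """Deterministic substream keyed by (seed, site index, metric stream).

    Keying on the site index (not position-dependent global state) means
    adding a site leaves every other site's draws untouched.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed, site_index, stream])
    )


def sample_null(
    pool: Sequence[str],
    richness: int,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> list[str]:
    """Draw ``richness`` distinct species from ``pool`` without replacement."""
    if richness < 1 or richness > len(pool):
        raise NullModelError(
            f"richness {richness} outside [1, {len(pool)}] for this pool"
        )
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pool),) or np.any(w < 0) or w.sum() <= 0:
            raise NullModelError("invalid sampling weights")
        p = w / w.sum()
    idx = rng.choice(len(pool), size=richness, replace=False, p=p)
    return [pool[i] for i in idx]


_SD_REL_TOL = 1e-12


def ses(observed: float, null: NullDistribution, negate: bool = False) -> float:
    """Standardised effect size (observed - null mean) / null sd.

    ``negate`` flips the sign — the NTI convention for MNTD. A null sd that
    is zero up to summation round-off (e.g. every replicate draws the whole
    pool) counts as degenerate.
    """
    if null.sd <= _SD_REL_TOL * max(abs(null.mean), 1.0):
        raise UndefinedSESError(observed, null.mean)
    value = (observed - null.mean) / null.sd
    return -value if negate else value


def _null_indicator(
    pool_idx: np.ndarray,
    richness: int,
    replicates: int,
    n_tips: int,
    rng: np.random.Generator,
    p: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate tip-index draws and their (replicates, n_tips) indicator."""
    draws = np.empty((replicates, richness), dtype=np.intp)
    for r in range(replicates):
        draws[r] = pool_idx[
            rng.choice(len(pool_idx), size=richness, replace=False, p=p)
        ]
    indicator = np.zeros((replicates, n_tips))
    rows = np.repeat(np.arange(replicates), richness)
    indicator[rows, draws.ravel()] = 1.0
    return draws, indicator


def null_distribution_pd(
    tree: Phylogeny,
    pool: Sequence[str],
    richness: int,
    cfg: NullModelConfig,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> NullDistribution:
    """Null PD values for one site's richness (vectorised over replicates)."""
    index = tree_index(tree)
    pool_idx = np.array([index._tip_pos[sp] for sp in pool], dtype=np.intp)
    p = None if weights is None else np.asarray(weights) / np.sum(weights)
    _, indicator = _null_indicator(
        pool_idx, richness, cfg.replicates, len(index.tip_labels), rng, p
    )
    return NullDistribution("pd", index.pd_many(indicator, cfg.include_root))


def null_distribution_mntd(
    dist_values: np.ndarray,
    pool_idx: np.ndarray,
    richness: int,
    replicates: int,
    rng: np.random.Generator,
    p: np.ndarray | None = None,
) -> NullDistribution:
    """Null MNTD values; ``dist_values`` is the full cophenetic matrix."""
    if richness < 2:
        raise NullModelError("MNTD null requires richness >= 2")
    draws = np.empty((replicates, richness), dtype=np.intp)
    for r in range(replicates):
        draws[r] = pool_idx[
            rng.choice(len(pool_idx), size=richness, replace=False, p=p)
        ]
    sub = dist_values[draws[:, :, None], draws[:, None, :]]
    k = np.arange(richness)
    sub[:, k, k] = np.inf
    return NullDistribution("mntd", sub.min(axis=2).mean(axis=1))


def pdi_nti_report(
    tree: Phylogeny,
    table: CommunityTable,
    cfg: NullModelConfig | None = None,
) -> DiversityReport:
    """Per-site PDI and NTI under the richness-preserving pool null.

    Sites with richness < 2 get a missing NTI (MNTD undefined); a zero null
    standard deviation (e.g. a site holding the whole pool) yields missing
    PDI/NTI with an explanatory note. Results are bit-reproducible for a
    fixed config.
    """
    cfg = cfg or NullModelConfig()
    index = tree_index(tree)
    missing = [sp for sp in table.species if sp not in index._tip_pos]
    if missing:
        raise NullModelError(
            f"table species absent from tree: {sorted(missing)[:10]}"
        )
    pool = list(cfg.pool) if cfg.pool is not None else table.pool()
    richness_all = table.richness()
    if len(pool) < int(richness_all.max()):
        raise NullModelError("pool smaller than the maximum site richness")

    weights = None
    if cfg.weighting == "occurrence":
        counts = table.occurrence_counts()
        weights = np.array([counts.get(sp, 0) for sp in pool], dtype=float)
        if weights.sum() <= 0:
            raise NullModelError("occurrence weighting needs a non-empty table")
    p = None if weights is None else weights / weights.sum()

    dist = cophenetic(tree)
    tip_order = {lab: i for i, lab in enumerate(dist.labels)}
    pool_tree_idx = np.array([index._tip_pos[sp] for sp in pool], dtype=np.intp)
    pool_dist_idx = np.array([tip_order[sp] for sp in pool], dtype=np.intp)

    rows = []
    for s, site in enumerate(table.sites):
        species = table.site_species(site)
        richness = len(species)
        notes: list[str] = []
        pd_obs = float(
            index.pd_many(index.indicator([species]), cfg.include_root)[0]
        )

        rng = site_rng(cfg.seed, s)
        _, indicator = _null_indicator(
            pool_tree_idx, richness, cfg.replicates, len(index.tip_labels),
            rng, p,
        )
        pd_null = NullDistribution(
            "pd", index.pd_many(indicator, cfg.include_root)
        )
        try:
            pdi = ses(pd_obs, pd_null)
        except UndefinedSESError:
            pdi = np.nan
            notes.append("pdi undefined: null sd is 0")

        if richness >= 2:
            sub = dist.values[np.ix_(
                [tip_order[sp] for sp in species],
                [tip_order[sp] for sp in species],
            )].copy()
            np.fill_diagonal(sub, np.inf)
            mntd_obs = float(sub.min(axis=1).mean())
            rng_m = site_rng(cfg.seed, s, stream=1)
            mntd_null = null_distribution_mntd(
                dist.values, pool_dist_idx, richness, cfg.replicates, rng_m, p
            )
            try:
                nti = ses(mntd_obs, mntd_null, negate=True)
            except UndefinedSESError:
                nti = np.nan
                notes.append("nti undefined: null sd is 0")
            mntd_mean, mntd_sd = mntd_null.mean, mntd_null.sd
        else:
            mntd_obs = np.nan
            nti = np.nan
            mntd_mean = mntd_sd = np.nan
            notes.append("nti missing: richness < 2 so MNTD is undefined")

        rows.append({
            "site": site,
            "richness": richness,
            "pd_obs": pd_obs,
            "pd_null_mean": pd_null.mean,
            "pd_null_sd": pd_null.sd,
            "pdi": pdi,
            "mntd_obs": mntd_obs,
            "mntd_null_mean": mntd_mean,
            "mntd_null_sd": mntd_sd,
            "nti": nti,
            "note": "; ".join(notes),
        })
    frame = pd.DataFrame(rows, columns=list(DiversityReport.COLUMNS))
    return DiversityReport(frame, replicates=cfg.replicates, seed=cfg.seed)
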