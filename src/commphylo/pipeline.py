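"""End-to-end study runner: ingest files, per-site PDI/NTI, wetland-type
rankings, correlations, PCoA, group statistics, life-form tables.

Configured by a flat ``key = value`` text file; every key has a default and
unknown keys are errors. Two runs with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .community import (
    CommunityTable,
    SiteMetadata,
    SpeciesAttributes,
    align_to_tree,
    read_attributes,
    read_community,
    read_site_metadata,
)
from .groups import (
    GroupSeparation,
    group_nti,
    group_separation_permutation,
    lifeform_proportions,
    ProportionTable,
)
from .metrics import MetricError
from .nullmodels import (
    DiversityReport,
    NullModelConfig,
    UndefinedSESError,
    pdi_nti_report,
)
from .ordination import PCoAResult, pcoa, site_distance_matrix, variance_explained
from .tree import Phylogeny, cophenetic, read_newick_file

__all__ = [
    "PipelineError",
    "StudyConfig",
    "StudyReport",
    "pearson",
    "read_config",
    "run_study",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class CorrelationError(ValueError):
    pass


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with the standard two-tailed p (t-transform, n-2 df).

    Pairs with a missing value on either side are dropped; the count of
    complete pairs used is returned alongside (r, p).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise CorrelationError("x and y must have equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise CorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise CorrelationError("correlation undefined: zero variance")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue), n


# -- configuration -----------------------------------------------------

_CONFIG_DEFAULTS: dict[str, str] = {
    "tree": "tree.nwk",
    "community": "community.csv",
    "attributes": "attributes.csv",
    "metadata": "metadata.csv",
    "out": "results",
    "replicates": "999",
    "seed": "0",
    "include_root": "true",
    "pool": "union",            # union | weighted
    "align_policy": "strict",   # strict | drop
    "pcoa_metric": "mntd",      # mntd | mpd
    "pcoa_correction": "none",  # none | lingoes | cailliez
    "rank_stat": "mean",        # mean | median
    "plot": "false",
}


@dataclass(frozen=True)
class StudyConfig:
    tree: Path
    community: Path
    attributes: Path
    metadata: Path
    out: Path
    replicates: int
    seed: int
    include_root: bool
    pool: str
    align_policy: str
    pcoa_metric: str
    pcoa_correction: str
    rank_stat: str
    plot: bool


def _parse_bool(value: str, key: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise PipelineError(f"config key {key!r}: expected boolean, got {value!r}")


def read_config(path: str | Path) -> StudyConfig:
    """Parse the flat key=value config; unknown keys are errors."""
    raw = dict(_CONFIG_DEFAULTS)
    base = Path(path).parent
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PipelineError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_DEFAULTS:
            raise PipelineError(f"config line {lineno}: unknown key {key!r}")
        raw[key] = value

    def _path(key: str) -> Path:
        p = Path(raw[key])
        return p if p.is_absolute() else base / p

    for key, allowed in (
        ("pool", {"union", "weighted"}),
        ("align_policy", {"strict", "drop"}),
        ("pcoa_metric", {"mntd", "mpd"}),
        ("pcoa_correction", {"none", "lingoes", "cailliez"}),
        ("rank_stat", {"mean", "median"}),
    ):
        if raw[key] not in allowed:
            raise PipelineError(
                f"config key {key!r}: {raw[key]!r} not in {sorted(allowed)}"
            )
    return StudyConfig(
        tree=_path("tree"),
        community=_path("community"),
        attributes=_path("attributes"),
        metadata=_path("metadata"),
        out=_path("out"),
        replicates=int(raw["replicates"]),
        seed=int(raw["seed"]),
        include_root=_parse_bool(raw["include_root"], "include_root"),
        pool=raw["pool"],
        align_policy=raw["align_policy"],
        pcoa_metric=raw["pcoa_metric"],
        pcoa_correction=raw["pcoa_correction"],
        rank_stat=raw["rank_stat"],
        plot=_parse_bool(raw["plot"], "plot"),
    )


# -- report ------------------------------------------------------------

@dataclass(frozen=True)
class StudyReport:
    diversity: DiversityReport
    type_summary: pd.DataFrame       # per wetland type: mean/median + rank
    correlations: pd.DataFrame       # r, p, n for the three site-level pairs
    nti_positive: int                # sites with NTI > 0
    nti_total: int                   # sites with a defined NTI
    pcoa: PCoAResult
    pcoa_cumvar: pd.DataFrame
    group_stats: pd.DataFrame
    proportions: ProportionTable


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _type_summary(
    div: pd.DataFrame, meta: SiteMetadata, stat: str
) -> pd.DataFrame:
    agg = "median" if stat == "median" else "mean"
    merged = div.assign(
        wetland_type=[meta.wetland_type(s) for s in div["site"]]
    )
    grouped = merged.groupby("wetland_type").agg(
        n_sites=("site", "size"),
        richness=("richness", agg),
        pdi=("pdi", agg),
        nti=("nti", agg),
    )
    for col in ("richness", "pdi", "nti"):
        grouped[f"{col}_rank"] = grouped[col].rank(method="min").astype(int)
    return grouped.sort_index()


def _correlations(div: pd.DataFrame) -> pd.DataFrame:
    pairs = [
        ("pdi", "nti"),
        ("richness", "pdi"),
        ("richness", "nti"),
    ]
    records = []
    for xcol, ycol in pairs:
        r, p, n = pearson(div[xcol].to_numpy(float), div[ycol].to_numpy(float))
        records.append({"x": xcol, "y": ycol, "r": r, "p": p, "n": n})
    return pd.DataFrame(records)


def _group_statistics(
    tree: Phylogeny,
    table: CommunityTable,
    attrs: SpeciesAttributes,
    cfg: NullModelConfig,
) -> pd.DataFrame:
    """Pooled-species NTI and separation for dominant and invasive sets."""
    dist = cophenetic(tree)
    pool = table.pool()
    pool_set = set(pool)
    records = []
    for flag in ("dominant", "invasive"):
        group = [sp for sp in attrs.flagged(flag) if sp in pool_set]
        complement = [sp for sp in pool if sp not in set(group)]
        rec: dict[str, object] = {
            "group": flag,
            "n_group": len(group),
            "n_complement": len(complement),
        }
        if len(group) >= 2 and complement:
            try:
                rec["nti"] = group_nti(tree, group, pool, cfg, dist=dist)
            except UndefinedSESError:
                rec["nti"] = np.nan
            sep = group_separation_permutation(
                dist, group, complement,
                replicates=cfg.replicates, seed=cfg.seed,
            )
            rec.update({
                "mntd_between": sep.observed,
                "mntd_null_mean": sep.null_mean,
                "mntd_null_sd": sep.null_sd,
                "mntd_ses": sep.ses,
                "mntd_p_greater": sep.p_greater,
            })
        else:
            rec["nti"] = np.nan
            rec["mntd_between"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)


def run_study(config_path: str | Path) -> StudyReport:
    """Run the full analysis described by a config file and write outputs.

    Any stage failure aborts with the stage name; files written so far are
    removed so no partial result set is left behind.
    """
    cfg = read_config(config_path)
    tree = _stage("read_tree")(read_newick_file)(cfg.tree)
    table = _stage("read_community")(read_community)(cfg.community)
    attrs = _stage("read_attributes")(read_attributes)(cfg.attributes)
    meta = _stage("read_metadata")(read_site_metadata)(cfg.metadata)
    table = _stage("align_to_tree")(align_to_tree)(
        table, tree, cfg.align_policy
    )
    _stage("check_metadata")(meta.check_covers)(table)

    null_cfg = NullModelConfig(
        replicates=cfg.replicates,
        seed=cfg.seed,
        weighting="occurrence" if cfg.pool == "weighted" else "uniform",
        include_root=cfg.include_root,
    )
    diversity = _stage("pdi_nti")(pdi_nti_report)(tree, table, null_cfg)
    div = diversity.table

    type_summary = _stage("type_ranking")(_type_summary)(
        div, meta, cfg.rank_stat
    )
    correlations = _stage("correlations")(_correlations)(div)
    nti = div["nti"].to_numpy(float)
    defined = np.isfinite(nti)
    nti_positive = int((nti[defined] > 0).sum())

    site_dist = _stage("site_distances")(site_distance_matrix)(
        tree, table, cfg.pcoa_metric
    )
    pcoa_result = _stage("pcoa")(pcoa)(site_dist, cfg.pcoa_correction)
    cumvar = pd.DataFrame({
        "k": np.arange(1, pcoa_result.n_axes + 1),
        "cumulative_variance": [
            variance_explained(pcoa_result, k)
            for k in range(1, pcoa_result.n_axes + 1)
        ],
    })

    group_stats = _stage("group_statistics")(_group_statistics)(
        tree, table, attrs, null_cfg
    )
    proportions = _stage("lifeforms")(lifeform_proportions)(table, attrs, meta)

    report = StudyReport(
        diversity=diversity,
        type_summary=type_summary,
        correlations=correlations,
        nti_positive=nti_positive,
        nti_total=int(defined.sum()),
        pcoa=pcoa_result,
        pcoa_cumvar=cumvar,
        group_stats=group_stats,
        proportions=proportions,
    )
    _write_outputs(report, cfg, meta)
    return report


def _write_outputs(report: StudyReport, cfg: StudyConfig, meta: SiteMetadata) -> None:
    outdir = cfg.out
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    fmt = "%.10g"
    try:
        emit("diversity.csv", report.diversity.to_csv)
        emit("type_summary.csv", lambda p: report.type_summary.to_csv(p, float_format=fmt))
        emit("correlations.csv", lambda p: report.correlations.to_csv(p, index=False, float_format=fmt))
        emit("pcoa_coordinates.csv", lambda p: report.pcoa.coordinates.rename_axis("site").to_csv(p, float_format=fmt))
        emit("pcoa_eigenvalues.csv", lambda p: pd.DataFrame({
            "eigenvalue": report.pcoa.eigenvalues,
        }).to_csv(p, index_label="rank", float_format=fmt))
        emit("pcoa_cumulative_variance.csv", lambda p: report.pcoa_cumvar.to_csv(p, index=False, float_format=fmt))
        emit("group_statistics.csv", lambda p: report.group_stats.to_csv(p, index=False, float_format=fmt))
        emit("lifeform_site.csv", lambda p: report.proportions.per_site.rename_axis("site").to_csv(p, float_format=fmt))
        if report.proportions.per_type is not None:
            emit("lifeform_type_ranges.csv", lambda p: report.proportions.per_type.to_csv(p, float_format=fmt))
        emit("nti_tally.csv", lambda p: pd.DataFrame([{
            "nti_positive": report.nti_positive,
            "nti_defined": report.nti_total,
        }]).to_csv(p, index=False))
        emit("run_metadata.json", lambda p: p.write_text(
            _run_metadata_json(cfg), encoding="utf-8"
        ))
        if cfg.plot:
            from .ordination import plot_pcoa
            types = {s: meta.wetland_type(s)
                     for s in report.pcoa.coordinates.index}
            emit("pcoa.png", lambda p: plot_pcoa(report.pcoa, p, types))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage 'write_outputs' failed: {exc}") from exc


def _run_metadata_json(cfg: StudyConfig) -> str:
    meta = {
        "commphylo_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "settings": {
            "replicates": cfg.replicates,
            "seed": cfg.seed,
            "include_root": cfg.include_root,
            "pool": cfg.pool,
            "align_policy": cfg.align_policy,
            "pcoa_metric": cfg.pcoa_metric,
            "pcoa_correction": cfg.pcoa_correction,
            "rank_stat": cfg.rank_stat,
        },
    }
    return json.dumps(meta, indent=2, sort_keys=True) + "\n"
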