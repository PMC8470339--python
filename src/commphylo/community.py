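"""Ingestion and validation of incidence tables, species attributes and
site metadata.

All three tables are UTF-8 delimited text (comma or tab, auto-detected).
Species labels are trimmed and internal spaces are mapped to underscores so
that herbarium-style binomials match Newick tip labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .tree import Phylogeny

__all__ = [
    "CommunityError",
    "CommunityTable",
    "SpeciesAttributes",
    "SiteMetadata",
    "LIFE_FORMS",
    "WETLAND_TYPES",
    "read_community",
    "read_attributes",
    "read_site_metadata",
    "align_to_tree",
]

logger = logging.getLogger(__name__)

LIFE_FORMS = ("annual", "perennial", "woody", "other")
WETLAND_TYPES = ("lake", "marsh", "coastal", "river", "human-made")

_LIFE_FORM_ALIASES = {
    "annual": "annual",
    "annual herb": "annual",
    "perennial": "perennial",
    "perennial herb": "perennial",
    "biennial": "perennial",  # biennials are folded into perennials on ingest
    "biennial herb": "perennial",
    "woody": "woody",
    "tree": "woody",
    "shrub": "woody",
    "other": "other",
}


class CommunityError(ValueError):
    """Invalid community, attribute, or metadata input."""


def _norm_label(label: str) -> str:
    return str(label).strip().replace(" ", "_")


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab in seen:
            raise CommunityError(
                f"duplicate {kind} label {lab!r} (positions {seen[lab]} and {i})"
            )
        seen[lab] = i


@dataclass(frozen=True)
class CommunityTable:
    """Binary sites x species incidence matrix.

    ``empty_species`` lists columns that are all zero (flagged, not
    dropped); every site must have richness >= 1.
    """

    sites: tuple[str, ...]
    species: tuple[str, ...]
    incidence: np.ndarray  # shape (n_sites, n_species), dtype int8, 0/1

    def __post_init__(self):
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.sites), len(self.species)):
            raise CommunityError("incidence shape does not match labels")
        bad = np.argwhere((inc != 0) & (inc != 1))
        if bad.size:
            r, c = bad[0]
            raise CommunityError(
                f"non-binary incidence value {inc[r, c]!r} at "
                f"site {self.sites[r]!r}, species {self.species[c]!r}"
            )
        _check_unique(self.sites, "site")
        _check_unique(self.species, "species")
        object.__setattr__(self, "incidence", inc.astype(np.int8))
        empty_sites = [s for s, r in zip(self.sites, self.richness()) if r == 0]
        if empty_sites:
            raise CommunityError(f"sites with richness 0: {empty_sites}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def empty_species(self) -> tuple[str, ...]:
        mask = self.incidence.sum(axis=0) == 0
        return tuple(sp for sp, m in zip(self.species, mask) if m)

    def richness(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    def site_species(self, site: str) -> list[str]:
        """Species present at one site."""
        try:
            i = self.sites.index(site)
        except ValueError:
            raise CommunityError(f"unknown site {site!r}") from None
        row = self.incidence[i]
        return [sp for sp, v in zip(self.species, row) if v]

    def pool(self) -> list[str]:
        """Union of species occurring at >= 1 site, in column order."""
        occ = self.incidence.sum(axis=0) > 0
        return [sp for sp, m in zip(self.species, occ) if m]

    def occurrence_counts(self) -> dict[str, int]:
        counts = self.incidence.sum(axis=0)
        return {sp: int(c) for sp, c in zip(self.species, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=list(self.sites), columns=list(self.species)
        )

    def drop_species(self, drop: Sequence[str]) -> "CommunityTable":
        drop_set = set(drop)
        keep = [j for j, sp in enumerate(self.species) if sp not in drop_set]
        return CommunityTable(
            self.sites,
            tuple(self.species[j] for j in keep),
            self.incidence[:, keep],
        )


@dataclass(frozen=True)
class SpeciesAttributes:
    """Per-species life form plus dominant / invasive flags."""

    table: pd.DataFrame  # index: species; columns: life_form, dominant, invasive

    def __post_init__(self):
        t = self.table
        required = {"life_form", "dominant", "invasive"}
        if not required.issubset(t.columns):
            raise CommunityError(
                f"attribute table missing columns: {sorted(required - set(t.columns))}"
            )
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise CommunityError(f"duplicate species in attributes: {dups}")
        bad = sorted(set(t["life_form"]) - set(LIFE_FORMS))
        if bad:
            raise CommunityError(f"unknown life forms: {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def life_form(self, species: str) -> str:
        return str(self.table.loc[species, "life_form"])

    def flagged(self, flag: Literal["dominant", "invasive"]) -> list[str]:
        return list(self.table.index[self.table[flag].astype(bool)])


@dataclass(frozen=True)
class SiteMetadata:
    """Mapping of site label to wetland type."""

    table: pd.DataFrame  # index: site; column: wetland_type

    def __post_init__(self):
        t = self.table
        if "wetland_type" not in t.columns:
            raise CommunityError("metadata table missing 'wetland_type' column")
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise CommunityError(f"duplicate sites in metadata: {dups}")
        bad = sorted(set(t["wetland_type"]) - set(WETLAND_TYPES))
        if bad:
            raise CommunityError(f"unknown wetland types: {bad}")

    def wetland_type(self, site: str) -> str:
        return str(self.table.loc[site, "wetland_type"])

    def sites_of_type(self, wetland_type: str) -> list[str]:
        mask = self.table["wetland_type"] == wetland_type
        return list(self.table.index[mask])

    def check_covers(self, table: CommunityTable) -> None:
        missing = sorted(set(table.sites) - set(self.table.index))
        if missing:
            raise CommunityError(f"sites without metadata: {missing}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with the first column as index; delimiter sniffed."""
    first = Path(path).open(encoding="utf-8").readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, index_col=0, encoding="utf-8")
    df.index = [_norm_label(x) for x in df.index]
    df.columns = [_norm_label(x) for x in df.columns]
    return df


def read_community(path: str | Path) -> CommunityTable:
    """Read a sites x species 0/1 incidence table.

    Header row holds species labels; first column holds site labels.
    Non-binary cells are reported with their coordinates.
    """
    df = _read_delimited(path)
    sites = tuple(df.index)
    species = tuple(df.columns)
    values = np.zeros(df.shape, dtype=np.int8)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(df.iat[i, j]).strip()
            if cell == "0":
                values[i, j] = 0
            elif cell == "1":
                values[i, j] = 1
            else:
                raise CommunityError(
                    f"non-binary cell {cell!r} at site {sites[i]!r}, "
                    f"species {species[j]!r}"
                )
    return CommunityTable(sites, species, values)


def read_attributes(path: str | Path) -> SpeciesAttributes:
    """Read the species attribute table (life_form, dominant, invasive)."""
    df = _read_delimited(path)
    df.columns = [c.lower() for c in df.columns]
    if "life_form" not in df.columns:
        raise CommunityError("attribute table missing 'life_form' column")
    forms = []
    for sp, raw in df["life_form"].items():
        key = str(raw).strip().lower().replace("_", " ")
        if key not in _LIFE_FORM_ALIASES:
            raise CommunityError(f"unknown life form {raw!r} for species {sp!r}")
        forms.append(_LIFE_FORM_ALIASES[key])
    out = pd.DataFrame(index=df.index)
    out["life_form"] = forms
    for flag in ("dominant", "invasive"):
        if flag in df.columns:
            out[flag] = [
                _parse_bool(v, flag, sp) for sp, v in df[flag].items()
            ]
        else:
            out[flag] = False
    return SpeciesAttributes(out)


def _parse_bool(value, flag: str, species: str) -> bool:
    key = str(value).strip().lower()
    if key in {"1", "true", "yes"}:
        return True
    if key in {"0", "false", "no", "", "nan"}:
        return False
    raise CommunityError(f"invalid {flag} flag {value!r} for species {species!r}")


def read_site_metadata(path: str | Path) -> SiteMetadata:
    df = _read_delimited(path)
    df.columns = [c.lower() for c in df.columns]
    if "wetland_type" not in df.columns:
        raise CommunityError("metadata table missing 'wetland_type' column")
    df["wetland_type"] = [str(v).strip().lower() for v in df["wetland_type"]]
    return SiteMetadata(df[["wetland_type"]])


def align_to_tree(
    table: CommunityTable,
    tree: Phylogeny,
    policy: Literal["strict", "drop"] = "strict",
) -> CommunityTable:
    """Reconcile table species with tree tips.

    ``strict`` (default) raises if any table species is missing from the
    tree; ``drop`` removes those species and logs the removal count.
    """
    tips = set(tree.tip_labels)
    missing = [sp for sp in table.species if sp not in tips]
    if not missing:
        return table
    if policy == "strict":
        raise CommunityError(
            f"{len(missing)} species absent from tree: {sorted(missing)}"
        )
    if policy != "drop":
        raise ValueError(f"unknown policy {policy!r}")
    logger.warning(
        "align_to_tree: dropped %d species absent from tree: %s",
        len(missing),
        sorted(missing),
    )
    return table.drop_species(missing)
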