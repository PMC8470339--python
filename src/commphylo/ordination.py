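"""Principal Coordinates Analysis of between-site phylogenetic distances.

Classical Gower double-centering eigendecomposition. Negative eigenvalues
are reported, never silently dropped; Lingoes and Cailliez corrections are
available for non-Euclidean matrices. Axis signs are fixed by making the
largest-magnitude coordinate on each axis positive, for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .community import CommunityTable
from .metrics import mntd_between, mpd_between
from .tree import DistanceMatrix, Phylogeny, cophenetic

__all__ = [
    "OrdinationError",
    "PCoAResult",
    "site_distance_matrix",
    "pcoa",
    "variance_explained",
    "plot_pcoa",
]

_EIG_TOL = 1e-9


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class PCoAResult:
    """Coordinates, eigenvalues (non-increasing), per-axis variance shares."""

    coordinates: pd.DataFrame  # sites x axes, axes only for positive eigenvalues
    eigenvalues: np.ndarray    # all eigenvalues, sorted non-increasing
    proportions: np.ndarray    # variance explained per reported axis
    correction: str

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def site_distance_matrix(
    tree: Phylogeny,
    table: CommunityTable,
    metric: Literal["mpd", "mntd"] = "mntd",
) -> DistanceMatrix:
    """Square sites x sites matrix of between-community MPD or MNTD.

    The diagonal is set to 0 by convention (for MNTD this is exact: every
    taxon finds itself at distance zero).
    """
    if metric not in ("mpd", "mntd"):
        raise OrdinationError(f"unknown metric {metric!r}")
    func = mpd_between if metric == "mpd" else mntd_between
    dist = cophenetic(tree)
    members = {site: table.site_species(site) for site in table.sites}
    n = table.n_sites
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = func(dist, members[table.sites[i]], members[table.sites[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(table.sites, out)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _decompose(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = _gower_center(d ** 2)
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def _lingoes(d: np.ndarray) -> np.ndarray:
    eigvals, _ = _decompose(d)
    c1 = -eigvals[-1]
    if c1 <= _EIG_TOL:
        return d
    d2 = d ** 2 + 2.0 * c1
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _cailliez(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    b1 = _gower_center(d ** 2)
    b2 = _gower_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * b1])
    lower = np.hstack([-np.eye(n), -4.0 * b2])
    big = np.vstack([upper, lower])
    c2 = float(np.max(np.linalg.eigvals(big).real))
    if c2 <= _EIG_TOL:
        return d
    out = d + c2
    np.fill_diagonal(out, 0.0)
    return out


def pcoa(
    dist: DistanceMatrix,
    correction: Literal["none", "lingoes", "cailliez"] = "none",
) -> PCoAResult:
    """Classical PCoA of a symmetric zero-diagonal distance matrix.

    With ``correction='none'`` variance proportions use the sum of
    *positive* eigenvalues as denominator; coordinates are reported only
    for positive-eigenvalue axes, scaled by sqrt(eigenvalue).
    """
    d = np.asarray(dist.values, dtype=float)
    if correction == "lingoes":
        d = _lingoes(d)
    elif correction == "cailliez":
        d = _cailliez(d)
    elif correction != "none":
        raise OrdinationError(f"unknown correction {correction!r}")

    eigvals, eigvecs = _decompose(d)
    scale = max(abs(eigvals[0]), 1.0) if eigvals.size else 1.0
    positive = eigvals > _EIG_TOL * scale
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)

    # sign convention: largest-|coordinate| entry on each axis is positive
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]

    denom = pos_vals.sum() if pos_vals.size else 1.0
    proportions = pos_vals / denom
    frame = pd.DataFrame(
        coords,
        index=list(dist.labels),
        columns=[f"axis{k + 1}" for k in range(coords.shape[1])],
    )
    return PCoAResult(frame, eigvals, proportions, correction)


def variance_explained(result: PCoAResult, k: int) -> float:
    """Cumulative variance share of the first ``k`` axes."""
    if k <= 0:
        raise OrdinationError("k must be positive")
    if k > result.n_axes:
        raise OrdinationError(
            f"k={k} exceeds the {result.n_axes} reported axes"
        )
    return float(result.proportions[:k].sum())


def plot_pcoa(
    result: PCoAResult,
    path: str | Path,
    site_types: dict[str, str] | None = None,
) -> None:
    """Scatter of the first two axes, optionally colored by wetland type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.n_axes < 2:
        raise OrdinationError("need at least two axes to plot")
    xs = result.coordinates["axis1"]
    ys = result.coordinates["axis2"]
    fig, ax = plt.subplots(figsize=(6, 5))
    if site_types:
        types = sorted(set(site_types.values()))
        cmap = plt.get_cmap("tab10")
        for t_i, t in enumerate(types):
            sites = [s for s in result.coordinates.index if site_types.get(s) == t]
            ax.scatter(xs[sites], ys[sites], label=t, color=cmap(t_i % 10))
        ax.legend(fontsize=8)
    else:
        ax.scatter(xs, ys)
    ax.set_xlabel(f"Axis 1 ({result.proportions[0]:.1%})")
    ax.set_ylabel(f"Axis 2 ({result.proportions[1]:.1%})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
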