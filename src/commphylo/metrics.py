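"""Core diversity statistics on a reference phylogeny.

Within-assemblage: Faith's PD, mean pairwise distance (MPD), mean
nearest-taxon distance (MNTD). Between-assemblage: MPD and MNTD across two
species sets, with each taxon weighted equally.

All distances are patristic (sums of branch lengths). Incidence only — no
abundance weighting.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .tree import DistanceMatrix, Phylogeny, TreeError

__all__ = [
    "MetricError",
    "faith_pd",
    "mpd_within",
    "mntd_within",
    "mpd_between",
    "mntd_between",
    "TreeIndex",
    "tree_index",
]


class MetricError(ValueError):
    """Metric undefined for the given input (e.g. singleton sample)."""


def _as_labels(sample: Iterable[str]) -> list[str]:
    labels = list(sample)
    if len(set(labels)) != len(labels):
        raise MetricError("sample contains duplicate species labels")
    return labels


class TreeIndex:
    """Array view of a phylogeny for vectorised PD over many samples.

    ``lengths[k]`` is the branch length of non-root node k (in postorder);
    ``tip_membership`` is an (n_tips, n_edges) 0/1 matrix whose (i, k)
    entry says whether tip i lies in the subtree below edge k.
    """

    def __init__(self, tree: Phylogeny):
        nodes = [n for n in tree.root.postorder() if n is not tree.root]
        self.tip_labels: list[str] = tree.tip_labels
        tip_pos = {lab: i for i, lab in enumerate(self.tip_labels)}
        n_tips, n_edges = len(self.tip_labels), len(nodes)
        self.lengths = np.array([float(n.length) for n in nodes])
        member = np.zeros((n_tips, n_edges), dtype=np.float64)
        # postorder guarantees children appear before parents
        below: dict[int, list[int]] = {}
        for k, node in enumerate(nodes):
            if node.is_tip:
                tips_below = [tip_pos[node.label]]
            else:
                tips_below = []
                for child in node.children:
                    tips_below.extend(below[id(child)])
            below[id(node)] = tips_below
            member[tips_below, k] = 1.0
        self.tip_membership = member
        self._tip_pos = tip_pos

    def indicator(self, samples: Sequence[Sequence[str]]) -> np.ndarray:
        """Stack samples into an (n_samples, n_tips) 0/1 matrix."""
        out = np.zeros((len(samples), len(self.tip_labels)))
        for r, sample in enumerate(samples):
            for lab in sample:
                try:
                    out[r, self._tip_pos[lab]] = 1.0
                except KeyError:
                    raise MetricError(f"species {lab!r} not on tree") from None
        return out

    def pd_many(self, indicator: np.ndarray, include_root: bool = True) -> np.ndarray:
        """Faith's PD for each row of an indicator matrix."""
        counts = indicator @ self.tip_membership  # (n_samples, n_edges)
        touched = counts >= 1
        if not include_root:
            sizes = indicator.sum(axis=1, keepdims=True)
            touched &= counts < sizes
        return touched @ self.lengths


def faith_pd(
    tree: Phylogeny, sample: Iterable[str], include_root: bool = True
) -> float:
    """Total branch length of the minimal subtree spanning ``sample``.

    With ``include_root`` (the default) the path connecting that subtree to
    the root is counted too, so a monotypic sample has nonzero PD.
    """
    labels = _as_labels(sample)
    if not labels:
        raise MetricError("faith_pd requires a nonempty sample")
    index = tree_index(tree)
    return float(index.pd_many(index.indicator([labels]), include_root)[0])


def tree_index(tree: Phylogeny) -> TreeIndex:
    """Cached :class:`TreeIndex` for a tree (trees are treated as frozen)."""
    cached = getattr(tree, "_metric_index", None)
    if cached is None:
        cached = TreeIndex(tree)
        tree._metric_index = cached  # type: ignore[attr-defined]
    return cached


def _sample_index(dist: DistanceMatrix, sample: Iterable[str]) -> np.ndarray:
    labels = _as_labels(sample)
    try:
        return dist.index_of(labels)
    except KeyError as exc:
        raise MetricError(str(exc)) from None


def mpd_within(dist: DistanceMatrix, sample: Iterable[str]) -> float:
    """Mean patristic distance over all unordered pairs in the sample."""
    idx = _sample_index(dist, sample)
    if len(idx) < 2:
        raise MetricError("mpd_within is undefined for samples of size < 2")
    sub = dist.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def mntd_within(dist: DistanceMatrix, sample: Iterable[str]) -> float:
    """Mean over taxa of the distance to the nearest other taxon."""
    idx = _sample_index(dist, sample)
    if len(idx) < 2:
        raise MetricError("mntd_within is undefined for samples of size < 2")
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def mpd_between(
    dist: DistanceMatrix, a: Iterable[str], b: Iterable[str]
) -> float:
    """Mean distance over all ordered cross pairs of two assemblages.

    Shared species contribute zero-distance pairs (they are not excluded).
    """
    ia = _sample_index(dist, a)
    ib = _sample_index(dist, b)
    if len(ia) == 0 or len(ib) == 0:
        raise MetricError("mpd_between requires two nonempty assemblages")
    return float(dist.values[np.ix_(ia, ib)].mean())


def mntd_between(
    dist: DistanceMatrix, a: Iterable[str], b: Iterable[str]
) -> float:
    """Mean nearest-taxon distance across two assemblages.

    Each taxon of either assemblage contributes its distance to the nearest
    member of the *other* assemblage; the |a| + |b| values are averaged with
    equal per-taxon weight.
    """
    ia = _sample_index(dist, a)
    ib = _sample_index(dist, b)
    if len(ia) == 0 or len(ib) == 0:
        raise MetricError("mntd_between requires two nonempty assemblages")
    cross = dist.values[np.ix_(ia, ib)]
    nearest = np.concatenate([cross.min(axis=1), cross.min(axis=0)])
    return float(nearest.mean())
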