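"""Independent brute-force reference implementations.

These deliberately avoid the package's vectorised code paths: patristic
distances are computed by walking parent pointers to the root, and Faith's
PD by explicit union of root-path edge sets. Loops only, no matrices.
"""

from __future__ import annotations

from commphylo.tree import Phylogeny, TreeNode


def _tip_map(tree: Phylogeny) -> dict[str, TreeNode]:
    return {t.label: t for t in tree.tips()}


def _root_path(node: TreeNode) -> list[TreeNode]:
    """Nodes from ``node`` up to (excluding) the root."""
    path = []
    while node.parent is not None:
        path.append(node)
        node = node.parent
    return path


def patristic_oracle(tree: Phylogeny, a: str, b: str) -> float:
    """Distance via explicit root paths and shared-ancestor cancellation."""
    tips = _tip_map(tree)
    pa = _root_path(tips[a])
    pb = _root_path(tips[b])
    shared = {id(n) for n in pa} & {id(n) for n in pb}
    total = 0.0
    for node in pa + pb:
        if id(node) not in shared:
            total += float(node.length)
    return total


def faith_pd_oracle(tree: Phylogeny, sample, include_root: bool = True) -> float:
    """PD via union of per-tip root-path edge sets."""
    tips = _tip_map(tree)
    paths = [ _root_path(tips[sp]) for sp in sample ]
    union: dict[int, TreeNode] = {}
    for path in paths:
        for node in path:
            union[id(node)] = node
    if not include_root:
        common = set.intersection(*({id(n) for n in p} for p in paths))
        for key in common:
            union.pop(key, None)
    return sum(float(n.length) for n in union.values())


class TreeOracle:
    """Per-tree precomputation for exhaustive sweeps.

    Root paths and pairwise distances are derived once with the loop-based
    logic above, then subset statistics are explicit loops over them —
    still fully independent of the package's vectorised implementations.
    """

    def __init__(self, tree: Phylogeny):
        tips = _tip_map(tree)
        self.labels = list(tips)
        self.paths = {lab: _root_path(tips[lab]) for lab in self.labels}
        self.path_ids = {
            lab: frozenset(id(n) for n in path)
            for lab, path in self.paths.items()
        }
        self.edge_length = {
            id(n): float(n.length)
            for path in self.paths.values() for n in path
        }
        self.dist = {}
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                d = patristic_oracle(tree, a, b)
                self.dist[(a, b)] = self.dist[(b, a)] = d

    def faith_pd(self, sample, include_root: bool = True) -> float:
        union = set()
        for sp in sample:
            union |= self.path_ids[sp]
        if not include_root:
            common = frozenset.intersection(
                *(self.path_ids[sp] for sp in sample)
            )
            union -= common
        return sum(self.edge_length[k] for k in union)

    def mpd_within(self, sample) -> float:
        sample = list(sample)
        total, count = 0.0, 0
        for i in range(len(sample)):
            for j in range(i + 1, len(sample)):
                total += self.dist[(sample[i], sample[j])]
                count += 1
        return total / count

    def mntd_within(self, sample) -> float:
        sample = list(sample)
        total = 0.0
        for i, sp in enumerate(sample):
            total += min(
                self.dist[(sp, other)]
                for j, other in enumerate(sample) if j != i
            )
        return total / len(sample)

    def _d(self, a, b) -> float:
        return 0.0 if a == b else self.dist[(a, b)]

    def mpd_between(self, a, b) -> float:
        total = 0.0
        for sa in a:
            for sb in b:
                total += self._d(sa, sb)
        return total / (len(a) * len(b))

    def mntd_between(self, a, b) -> float:
        values = [min(self._d(sa, sb) for sb in b) for sa in a]
        values += [min(self._d(sa, sb) for sa in a) for sb in b]
        return sum(values) / len(values)


def mpd_within_oracle(tree: Phylogeny, sample) -> float:
    sample = list(sample)
    total, count = 0.0, 0
    for i in range(len(sample)):
        for j in range(i + 1, len(sample)):
            total += patristic_oracle(tree, sample[i], sample[j])
            count += 1
    return total / count


def mntd_within_oracle(tree: Phylogeny, sample) -> float:
    sample = list(sample)
    total = 0.0
    for i, sp in enumerate(sample):
        nearest = min(
            patristic_oracle(tree, sp, other)
            for j, other in enumerate(sample) if j != i
        )
        total += nearest
    return total / len(sample)


def mpd_between_oracle(tree: Phylogeny, a, b) -> float:
    a, b = list(a), list(b)
    total = 0.0
    for sa in a:
        for sb in b:
            total += patristic_oracle(tree, sa, sb)
    return total / (len(a) * len(b))


def mntd_between_oracle(tree: Phylogeny, a, b) -> float:
    a, b = list(a), list(b)
    values = []
    for sa in a:
        values.append(min(patristic_oracle(tree, sa, sb) for sb in b))
    for sb in b:
        values.append(min(patristic_oracle(tree, sa, sb) for sa in a))
    return sum(values) / len(values)
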