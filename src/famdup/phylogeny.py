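"""Distance matrices, neighbour-joining trees, bootstrap support, subgroups.

The NJ agglomeration follows Saitou–Nei with deterministic tie-breaking
(lexicographically smallest label pair on equal Q).  Negative branch lengths
are clamped to zero with the deficit moved to the sister branch, so path
lengths on additive inputs are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "pdistance",
    "nj",
    "bootstrap",
    "cut_subgroups",
    "read_alignment_fasta",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


class _Node:
    __slots__ = ("node_id", "label")

    def __init__(self, node_id: int, label: str | None = None):
        self.node_id = node_id
        self.label = label


class PhyloTree:
    """Unrooted tree stored as an adjacency map with branch lengths.

    Internal edges may carry bootstrap support (0–100), keyed by the
    bipartition (canonical frozenset of leaf labels) the edge induces.
    """

    def __init__(self) -> None:
        self._nodes: dict[int, _Node] = {}
        self._adj: dict[int, dict[int, float]] = {}
        self.supports: dict[frozenset[str], float] = {}
        self._next_id = 0

    # -- construction ---------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._nodes[nid] = _Node(nid, label)
        self._adj[nid] = {}
        return nid

    def add_edge(self, a: int, b: int, length: float) -> None:
        self._adj[a][b] = length
        self._adj[b][a] = length

    # -- queries ----------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self._nodes.values() if n.label is not None)

    def neighbors(self, nid: int) -> dict[int, float]:
        return dict(self._adj[nid])

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for a, nbrs in self._adj.items():
            for b, ln in nbrs.items():
                if a < b:
                    out.append((a, b, ln))
        return out

    def is_leaf(self, nid: int) -> bool:
        return self._nodes[nid].label is not None

    def label_of(self, nid: int) -> str | None:
        return self._nodes[nid].label

    def _leaves_beyond(self, frm: int, to: int) -> set[str]:
        """Leaf labels on the `to` side of edge (frm, to)."""
        seen, stack, labels = {frm, to}, [to], set()
        while stack:
            cur = stack.pop()
            lab = self._nodes[cur].label
            if lab is not None:
                labels.add(lab)
            for nxt in self._adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return labels

    def bipartition(self, a: int, b: int) -> frozenset[str]:
        """Canonical bipartition of edge (a, b): the side not holding the
        lexicographically smallest leaf."""
        all_leaves = set(self.leaf_labels)
        side = self._leaves_beyond(a, b)
        anchor = min(all_leaves)
        return frozenset(side if anchor not in side else all_leaves - side)

    def internal_edges(self) -> list[tuple[int, int, float]]:
        return [
            (a, b, ln)
            for a, b, ln in self.edges()
            if not self.is_leaf(a) and not self.is_leaf(b)
        ]

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions (one per internal edge)."""
        return {self.bipartition(a, b) for a, b, _ in self.internal_edges()}

    def path_length(self, label_a: str, label_b: str) -> float:
        ids = {n.label: n.node_id for n in self._nodes.values() if n.label}
        start, goal = ids[label_a], ids[label_b]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur == goal:
                return dist[cur]
            for nxt, ln in self._adj[cur].items():
                if nxt not in dist:
                    dist[nxt] = dist[cur] + ln
                    stack.append(nxt)
        raise ValueError("labels not connected")

    # -- output -----------------------------------------------------------
    def to_newick(self, with_support: bool = False) -> str:
        # root the traversal at an internal node (or the only edge's end)
        internal = [nid for nid in self._nodes if not self.is_leaf(nid)]
        root = internal[0] if internal else next(iter(self._nodes))

        def fmt(nid: int, parent: int | None) -> str:
            children = [c for c in self._adj[nid] if c != parent]
            lab = self._nodes[nid].label or ""
            if not children:
                body = lab
            else:
                inner = ",".join(
                    f"{fmt(c, nid)}:{self._adj[nid][c]:.6f}" for c in children
                )
                body = f"({inner})"
                if with_support and parent is not None and not self.is_leaf(nid):
                    bip = self.bipartition(parent, nid)
                    sup = self.supports.get(bip)
                    if sup is not None:
                        body += f"{sup:g}"
            return body

        return fmt(root, None) + ";"


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    from .annotation_io import read_fasta

    aln = read_fasta(path)
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: alignment rows differ in length")
    return aln


def pdistance(alignment: Mapping[str, str], correction: str = "poisson") -> DistanceMatrix:
    """Pairwise mismatch proportion over mutually ungapped columns.

    ``correction='poisson'`` applies -ln(1 - p); ``'none'`` returns p.
    """
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("alignment needs at least 2 rows")
    rows = [alignment[l].upper() for l in labels]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows differ in length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mism = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                comparable += 1
                if x != y:
                    mism += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = mism / comparable
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {labels[i]!r}/{labels[j]!r}: p-distance 1.0"
                    )
                p = -math.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, values=d)


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining; returns an unrooted tree."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tree = PhyloTree()
    # active cluster list: (sort_key, node_id); sort_key = min leaf label under
    # the cluster, used for deterministic tie-breaking
    active: list[tuple[str, int]] = []
    for lab in dm.labels:
        nid = tree.add_node(lab)
        active.append((lab, nid))
    # distance dict keyed by node_id pairs
    dist: dict[tuple[int, int], float] = {}
    ids = {lab: nid for lab, nid in active}
    for i, la in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            lb = dm.labels[j]
            a, b = ids[la], ids[lb]
            dist[(min(a, b), max(a, b))] = float(dm.values[i, j])

    def d(a: int, b: int) -> float:
        return dist[(min(a, b), max(a, b))]

    while len(active) > 3:
        m = len(active)
        r = {nid: sum(d(nid, other) for _, other in active if other != nid)
             for _, nid in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                ka, a = active[i]
                kb, b = active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                tie = tuple(sorted((ka, kb)))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and tie < best[1]
                ):
                    best = (q, tie, i, j)
        _, _, i, j = best
        (ka, a), (kb, b) = active[i], active[j]
        u = tree.add_node()
        dab = d(a, b)
        ba = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        bb = dab - ba
        # clamp negatives, moving the deficit to the sister branch
        if ba < 0:
            bb += ba
            ba = 0.0
        if bb < 0:
            ba += bb
            bb = 0.0
        tree.add_edge(a, u, max(ba, 0.0))
        tree.add_edge(b, u, max(bb, 0.0))
        new_active = [(k, nid) for k, nid in active if nid not in (a, b)]
        for _, c in new_active:
            duc = 0.5 * (d(a, c) + d(b, c) - dab)
            dist[(min(u, c), max(u, c))] = max(duc, 0.0)
        new_active.append((min(ka, kb), u))
        new_active.sort()
        active = new_active

    # join the final three clusters on one internal node
    (k1, x), (k2, y), (k3, z) = active
    u = tree.add_node()
    bx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
    by = 0.5 * (d(x, y) + d(y, z) - d(x, z))
    bz = 0.5 * (d(x, z) + d(y, z) - d(x, y))
    for nid, bl in ((x, bx), (y, by), (z, bz)):
        tree.add_edge(nid, u, max(bl, 0.0))
    return tree


def bootstrap(
    alignment: Mapping[str, str],
    replicates: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate (seeded NumPy
    generator); support is the percentage of replicate trees containing each
    internal bipartition of the full-data tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels = sorted(alignment)
    rows = {l: alignment[l] for l in labels}
    tree = nj(pdistance(rows, correction=correction))
    target = {
        (a, b): tree.bipartition(a, b) for a, b, _ in tree.internal_edges()
    }
    hits = {bip: 0 for bip in target.values()}
    ncol = len(next(iter(rows.values())))
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {
            l: "".join(rows[l][c] for c in cols) for l in labels
        }
        try:
            rep_bips = nj(pdistance(resampled, correction=correction)).bipartitions()
        except ValueError:  # saturated / incomparable resample: counts as no support
            continue
        for bip in hits:
            if bip in rep_bips:
                hits[bip] += 1
    tree.supports = {
        bip: 100.0 * k / replicates for bip, k in hits.items()
    }
    return tree


def cut_subgroups(tree: PhyloTree, k: int) -> dict[str, int]:
    """Partition leaves into k subgroups by removing the k-1 longest internal
    edges (ties broken by a canonical bipartition ordering).

    Subgroup ids are assigned in order of each group's smallest leaf label.
    """
    leaves = tree.leaf_labels
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k must lie in [1, {len(leaves)}]")

    def edge_rank(edge: tuple[int, int, float]) -> tuple:
        a, b, ln = edge
        internal = not tree.is_leaf(a) and not tree.is_leaf(b)
        if internal:
            tie = tuple(sorted(tree.bipartition(a, b)))
        else:
            tie = (tree.label_of(a) or tree.label_of(b),)
        return (0 if internal else 1, -ln, tie)

    ranked = sorted(tree.edges(), key=edge_rank)

    def leaf_groups(removed: set[tuple[int, int]]) -> list[list[str]]:
        comp: dict[int, int] = {}
        cid = 0
        for nid in tree._nodes:
            if nid in comp:
                continue
            stack = [nid]
            comp[nid] = cid
            while stack:
                cur = stack.pop()
                for nxt in tree._adj[cur]:
                    if (min(cur, nxt), max(cur, nxt)) in removed:
                        continue
                    if nxt not in comp:
                        comp[nxt] = cid
                        stack.append(nxt)
            cid += 1
        groups: dict[int, list[str]] = {}
        for nid, c in comp.items():
            lab = tree.label_of(nid)
            if lab is not None:
                groups.setdefault(c, []).append(lab)
        return list(groups.values())

    # remove ranked edges one at a time until k leaf-bearing components exist;
    # internal edges rank ahead of pendant ones, longest first
    removed: set[tuple[int, int]] = set()
    groups = leaf_groups(removed)
    for a, b, _ in ranked:
        if len(groups) >= k:
            break
        removed.add((min(a, b), max(a, b)))
        groups = leaf_groups(removed)
    if len(groups) != k:
        raise ValueError(f"could not split tree into {k} leaf groups")
    ordered = sorted(groups, key=lambda g: min(g))
    return {lab: gid for gid, group in enumerate(ordered) for lab in group}
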