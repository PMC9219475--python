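"""Allele-sharing distances and neighbour-joining trees.

The per-locus allele-sharing kernel between dosage calls ci, cj is
``1 - |ci - cj| / 2`` (identical genotypes share 1, het vs. hom 0.5,
opposite homozygotes 0); ASD(i, j) is one minus the mean sharing over
loci genotyped in both individuals.  Trees are built with the classic
Saitou-Nei agglomeration using the Studier-Keppler Q-criterion and
serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpdiv.genotype_io import MISSING, GenotypeMatrix, PathOrStream, _as_writer


class OverlapError(ValueError):
    """A pair of individuals shares fewer genotyped loci than required."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair locus-overlap counts."""

    labels: list[str]
    populations: list[str]
    values: np.ndarray
    n_overlap: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_overlap = np.asarray(self.n_overlap, dtype=np.int64)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape does not match labels")
        if self.values.size and np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self, sink: PathOrStream) -> None:
        fh, close = _as_writer(sink)
        try:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")
        finally:
            if close:
                fh.close()


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves are numbered ``0..n_leaves-1`` (indices into ``leaf_labels``);
    internal nodes continue the numbering.  ``root`` is the arbitrary
    trifurcating node used for serialization.
    """

    leaf_labels: list[str]
    adjacency: dict[int, list[tuple[int, float]]]
    root: int

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def validate(self) -> None:
        for node, nbrs in self.adjacency.items():
            degree = len(nbrs)
            if node < self.n_leaves:
                assert degree == 1, f"leaf {node} has degree {degree}"
            elif self.n_leaves > 2:
                assert degree == 3, f"internal node {node} has degree {degree}"
            for _, length in nbrs:
                assert length >= 0.0

    def path_lengths(self) -> np.ndarray:
        """Leaf-to-leaf path-length matrix (order of ``leaf_labels``)."""
        n = self.n_leaves
        out = np.zeros((n, n))
        for start in range(n):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for leaf in range(n):
                out[start, leaf] = dist[leaf]
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf splits induced by internal edges.

        Each split is represented by the smaller side's label set (ties
        by sorted order), so topologies can be compared directly.
        """
        splits: set[frozenset[str]] = set()
        seen_edges: set[tuple[int, int]] = set()
        for u, nbrs in self.adjacency.items():
            for v, _ in nbrs:
                edge = (min(u, v), max(u, v))
                if edge in seen_edges:
                    continue
                seen_edges.add(edge)
                side = self._leaves_beyond(v, u)
                if 1 < len(side) < self.n_leaves - 1:
                    other = frozenset(self.leaf_labels) - side
                    splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def _leaves_beyond(self, node: int, blocked: int) -> frozenset[str]:
        found: list[str] = []
        stack = [(node, blocked)]
        while stack:
            u, prev = stack.pop()
            if u < self.n_leaves:
                found.append(self.leaf_labels[u])
            for v, _ in self.adjacency[u]:
                if v != prev:
                    stack.append((v, u))
        return frozenset(found)


def asd_matrix(gm: GenotypeMatrix, min_overlap: int = 100) -> DistanceMatrix:
    """Allele-sharing distance between every pair of individuals.

    Loci are used pairwise-complete: each pair is averaged over the
    loci genotyped in both.  Raises :class:`OverlapError` if any pair
    shares fewer than ``min_overlap`` loci.
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    values = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(overlap, gm.n_markers)
    for i in range(n):
        diff = np.abs(calls[i + 1 :] - calls[i])  # (n-i-1, m), nan where either missing
        shared = (~np.isnan(diff)).sum(axis=1)
        too_few = np.flatnonzero(shared < min_overlap)
        if too_few.size:
            j = i + 1 + too_few[0]
            raise OverlapError(
                f"pair ({gm.sample_ids[i]!r}, {gm.sample_ids[j]!r}) shares "
                f"{shared[too_few[0]]} loci < minimum {min_overlap}"
            )
        with np.errstate(invalid="ignore"):
            d = np.nanmean(diff, axis=1) / 2.0
        values[i, i + 1 :] = values[i + 1 :, i] = d
        overlap[i, i + 1 :] = overlap[i + 1 :, i] = shared
    return DistanceMatrix(
        labels=list(gm.sample_ids),
        populations=list(gm.population_labels),
        values=values,
        n_overlap=overlap,
    )


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Neighbour-joining tree from a distance matrix.

    Deterministic: exact Q-ties are broken by the lowest (row, column)
    index pair.  Negative branch lengths are clamped to zero with the
    deficit transferred to the sister branch, preserving path lengths.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels for a tree")
    d = np.asarray(dm.values, dtype=float)
    if (d < 0).any():
        raise ValueError("negative distances")
    if np.abs(d - d.T).max() > 1e-12:
        raise ValueError("distance matrix not symmetric")

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    active = list(range(n))  # node ids, parallel to rows of `d`
    d = d.copy()
    next_id = n

    def connect(u: int, v: int, length: float) -> None:
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2.0) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) pair wins ties: argmin scans row-major
        flat = int(np.argmin(np.round(q, 12)))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2.0))
        lj = d[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        new = next_id
        next_id += 1
        connect(active[i], new, li)
        connect(active[j], new, lj)

        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new]

    # final 3-star: three-point formulas are exact
    i, j, k = 0, 1, 2
    center = next_id
    lengths = (
        0.5 * (d[i, j] + d[i, k] - d[j, k]),
        0.5 * (d[i, j] + d[j, k] - d[i, k]),
        0.5 * (d[i, k] + d[j, k] - d[i, j]),
    )
    for idx, length in zip((i, j, k), lengths):
        connect(active[idx], center, max(length, 0.0))

    tree = UnrootedTree(leaf_labels=list(dm.labels), adjacency=adjacency, root=center)
    tree.validate()
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: UnrootedTree) -> str:
    """Serialize as Newick, rooted trifurcating at the last-joined node.

    Branch lengths are written with 6 significant digits; labels
    containing whitespace or Newick metacharacters are quoted.
    """

    def render(node: int, parent: int) -> str:
        children = [(v, w) for v, w in tree.adjacency[node] if v != parent]
        if not children:
            return _quote_label(tree.leaf_labels[node])
        inner = ",".join(f"{render(v, node)}:{w:.6g}" for v, w in children)
        return f"({inner})"

    return render(tree.root, -1) + ";"
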