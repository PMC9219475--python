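"""Shared test helpers and independent oracles.

The oracles here are deliberately naive re-derivations (enumeration,
closed forms, scalar transcriptions) kept independent of the package
implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np

from snpdiv.genotype_io import MISSING, GenotypeMatrix


def make_gm(calls, pops, allele_pairs=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a call array and population labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        population_labels=np.array(list(pops), dtype=object),
        marker_ids=np.array([f"M{j}" for j in range(m)], dtype=object),
        chromosomes=np.array(["1"] * m, dtype=object),
        positions_bp=np.arange(1, m + 1) * 1000,
        allele_pairs=allele_pairs or [("A", "C")] * m,
        calls=calls,
    )


def flip_loci(gm: GenotypeMatrix, loci) -> GenotypeMatrix:
    """Relabel alleles (c -> 2-c, missing preserved) at the given loci."""
    calls = gm.calls.copy()
    for j in loci:
        col = calls[:, j]
        mask = col != MISSING
        col[mask] = 2 - col[mask]
    pairs = list(gm.allele_pairs)
    for j in loci:
        a1, a2 = pairs[j]
        pairs[j] = (a2, a1)
    return GenotypeMatrix(
        sample_ids=gm.sample_ids.copy(),
        population_labels=gm.population_labels.copy(),
        marker_ids=gm.marker_ids.copy(),
        chromosomes=gm.chromosomes.copy(),
        positions_bp=gm.positions_bp.copy(),
        allele_pairs=pairs,
        calls=calls,
    )


def dm_labels_stub(values, labels):
    """DistanceMatrix from raw values (overlap counts filled arbitrarily)."""
    from snpdiv.distance_nj import DistanceMatrix

    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return DistanceMatrix(
        labels=list(labels),
        populations=["P"] * n,
        values=values,
        n_overlap=np.full((n, n), 100),
    )


# ---------------------------------------------------------------- HWE oracle


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the Levene conditional p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0

    def weight(h: int) -> int:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return factorial(n) * 2**h // (factorial(hom_c) * factorial(h) * factorial(hom_r))

    hs = list(range(rare % 2, rare + 1, 2))
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    probs = {h: Fraction(w, total) for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hwe_conditional_probs(n_hom_ref: int, n_het: int, n_hom_alt: int) -> list[Fraction]:
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return [Fraction(1)]
    weights = []
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        weights.append(
            factorial(n) * 2**h // (factorial(hom_c) * factorial(h) * factorial(hom_r))
        )
    total = sum(weights)
    return [Fraction(w, total) for w in weights]


# --------------------------------------------------- Weir-Cockerham oracles


def wc_theta_single_locus_oracle(genos_a, genos_b) -> tuple[float, float, float]:
    """Naive scalar transcription of the two-population a, b, c components.

    Complete data assumed (no missing calls).
    """
    r = 2
    n_i = [len(genos_a), len(genos_b)]
    p_i = [sum(g) / (2 * len(g)) for g in (genos_a, genos_b)]
    h_i = [sum(1 for c in g if c == 1) / len(g) for g in (genos_a, genos_b)]

    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n**2 for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n_i[k] * p_i[k] for k in range(r)) / (r * n_bar)
    s2 = sum(n_i[k] * (p_i[k] - p_bar) ** 2 for k in range(r)) / ((r - 1) * n_bar)
    h_bar = sum(n_i[k] * h_i[k] for k in range(r)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def theta_from_true_freqs(p1: np.ndarray, p2: np.ndarray) -> float:
    """Infinite-sample two-population theta from true allele frequencies.

    Limit of the variance-component ratio-of-sums as both sample sizes
    grow, assuming Hardy-Weinberg within each population.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p_bar = (p1 + p2) / 2.0
    s2 = (p1 - p2) ** 2 / 2.0
    num = s2.sum()
    den = (p_bar * (1.0 - p_bar) + s2 / 2.0).sum()
    return float(num / den)


# ------------------------------------------------------ additive tree oracle


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with edge lengths uniform in [0.5, 2].

    Returns (adjacency dict node -> [(nbr, length), ...], n_leaves).
    Leaves are nodes 0..n_leaves-1.
    """
    assert n_leaves >= 3
    edges: list[list[int]] = [[0, n_leaves], [1, n_leaves], [2, n_leaves]]
    next_node = n_leaves + 1
    for leaf in range(3, n_leaves):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = next_node
        next_node += 1
        edges.extend([[u, w], [w, v], [leaf, w]])
    adjacency: dict[int, list[tuple[int, float]]] = {}
    for u, v in edges:
        length = float(rng.uniform(0.5, 2.0))
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))
    return adjacency, n_leaves


def tree_path_lengths(adjacency, n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf path lengths by graph traversal (independent of NJ)."""
    out = np.zeros((n_leaves, n_leaves))
    for start in range(n_leaves):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for leaf in range(n_leaves):
            out[start, leaf] = dist[leaf]
    return out


def tree_bipartitions(adjacency, n_leaves: int, labels) -> set[frozenset]:
    """Non-trivial splits of a tree given as an adjacency dict."""
    splits = set()
    seen = set()
    all_labels = frozenset(labels)
    for u, nbrs in adjacency.items():
        for v, _ in nbrs:
            edge = (min(u, v), max(u, v))
            if edge in seen:
                continue
            seen.add(edge)
            side = set()
            stack = [(v, u)]
            while stack:
                x, prev = stack.pop()
                if x < n_leaves:
                    side.add(labels[x])
                for y, _w in adjacency[x]:
                    if y != prev:
                        stack.append((y, x))
            side = frozenset(side)
            if 1 < len(side) < n_leaves - 1:
                other = all_labels - side
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits
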