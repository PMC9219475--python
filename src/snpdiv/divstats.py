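"""Per-population diversity and between-population differentiation.

Observed/expected heterozygosity use Nei's small-sample-corrected gene
diversity.  Fis and pairwise Fst are the Weir & Cockerham (1984)
variance-component estimators, combined across loci as a ratio of sums.
The gene-flow transform is Wright's island-model Nm = (1-Fst)/(4*Fst).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from snpdiv.genotype_io import MISSING, GenotypeMatrix, PathOrStream, _as_writer


class MonomorphicError(ValueError):
    """All usable loci are monomorphic; the requested statistic is undefined."""


@dataclass
class DiversityTable:
    """Per-population n, Ho, He, Fis (one row per population)."""

    populations: list[str]
    n: list[int]
    ho: list[float]
    he: list[float]
    fis: list[float]
    n_loci_used: list[int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Breed": self.populations,
                "Nb": self.n,
                "Ho": self.ho,
                "He": self.he,
                "Fis": self.fis,
                "n_loci_used": self.n_loci_used,
            }
        )

    def to_tsv(self, sink: PathOrStream) -> None:
        fh, close = _as_writer(sink)
        try:
            self.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.6f")
        finally:
            if close:
                fh.close()


@dataclass
class PairwiseMatrices:
    """Symmetric pairwise Fst and the derived Nm matrix.

    ``nm`` entries are NaN wherever Fst <= 0 (gene flow undefined).
    """

    populations: list[str]
    fst: np.ndarray
    nm: np.ndarray

    def __post_init__(self) -> None:
        self.fst = np.asarray(self.fst, dtype=float)
        self.nm = np.asarray(self.nm, dtype=float)
        assert np.allclose(self.fst, self.fst.T, equal_nan=True)
        assert np.all(np.diag(self.fst) == 0.0)

    def to_mixed_triangle_tsv(self, sink: PathOrStream) -> None:
        """Fst below the diagonal, Nm above, '-' on the diagonal."""
        fh, close = _as_writer(sink)
        try:
            k = len(self.populations)
            fh.write("\t" + "\t".join(self.populations) + "\n")
            for i in range(k):
                row = [self.populations[i]]
                for j in range(k):
                    if i == j:
                        row.append("-")
                    elif i < j:
                        v = self.nm[i, j]
                        row.append("NA" if np.isnan(v) else f"{v:.3f}")
                    else:
                        row.append(f"{self.fst[i, j]:.4f}")
                fh.write("\t".join(row) + "\n")
        finally:
            if close:
                fh.close()

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        k = len(self.populations)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "pop_a": self.populations[i],
                        "pop_b": self.populations[j],
                        "fst": self.fst[i, j],
                        "nm": self.nm[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _pop_block(gm: GenotypeMatrix, population: str) -> np.ndarray:
    block = gm.population_calls(population)
    if block.shape[0] < 2:
        raise ValueError(f"population {population!r} has fewer than 2 individuals")
    return block


def heterozygosity(gm: GenotypeMatrix, population: str) -> tuple[float, float, int]:
    """Mean observed and Nei-unbiased expected heterozygosity for one population.

    Per locus with >= 2 genotyped individuals: ho is the heterozygote
    fraction, he = 2n/(2n-1) * 2*p*(1-p).  Returns unweighted means
    over qualifying loci and the number of loci used.
    """
    block = _pop_block(gm, population)
    obs = block != MISSING
    n = obs.sum(axis=0).astype(float)
    use = n >= 2
    if not use.any():
        raise ValueError(f"no locus with >=2 genotyped individuals in {population!r}")
    n = n[use]
    calls = block[:, use]
    obs = obs[:, use]
    het = (calls == 1).sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    p = alt / (2.0 * n)
    ho = het / n
    he = (2.0 * n / (2.0 * n - 1.0)) * 2.0 * p * (1.0 - p)
    return float(ho.mean()), float(he.mean()), int(use.sum())


def _wc_single_pop_components(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham b and c components for one population.

    Loci with <2 genotyped individuals are dropped.
    """
    obs = block != MISSING
    n = obs.sum(axis=0).astype(float)
    use = n >= 2
    n = n[use]
    calls = block[:, use]
    obs = obs[:, use]
    h = (calls == 1).sum(axis=0) / n
    p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
    b = (n / (n - 1.0)) * (p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h)
    c = h / 2.0
    return b, c


def fis_within(gm: GenotypeMatrix, population: str) -> float:
    """Weir-Cockerham within-population f, ratio-of-sums across loci."""
    block = _pop_block(gm, population)
    b, c = _wc_single_pop_components(block)
    denom = (b + c).sum()
    if denom == 0.0:
        raise MonomorphicError(
            f"population {population!r} monomorphic at all usable loci; Fis undefined"
        )
    return float(1.0 - c.sum() / denom)


def fis_simple(gm: GenotypeMatrix, population: str) -> float:
    """Diagnostic 1 - Ho/He alternative to the variance-component Fis."""
    ho, he, _ = heterozygosity(gm, population)
    if he == 0.0:
        raise MonomorphicError(f"He is zero for {population!r}")
    return 1.0 - ho / he


def _wc_pair_components(
    block_a: np.ndarray, block_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham a, b, c components for two populations.

    Only loci with >= 2 genotyped individuals in both populations and
    polymorphic across the pooled pair are returned.
    """
    r = 2.0
    parts = []
    for block in (block_a, block_b):
        obs = block != MISSING
        n = obs.sum(axis=0).astype(float)
        het = (block == 1).sum(axis=0).astype(float)
        alt = np.where(obs, block, 0).sum(axis=0).astype(float)
        parts.append((n, het, alt))
    n1, het1, alt1 = parts[0]
    n2, het2, alt2 = parts[1]

    use = (n1 >= 2) & (n2 >= 2)
    pooled_p = np.divide(
        alt1 + alt2, 2.0 * (n1 + n2), out=np.zeros_like(n1), where=(n1 + n2) > 0
    )
    use &= (pooled_p > 0.0) & (pooled_p < 1.0)
    n1, het1, alt1 = n1[use], het1[use], alt1[use]
    n2, het2, alt2 = n2[use], het2[use], alt2[use]

    p1, p2 = alt1 / (2.0 * n1), alt2 / (2.0 * n2)
    h1, h2 = het1 / n1, het2 / n2

    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    theta-hat = sum(a) / sum(a+b+c) over loci polymorphic in the pooled
    pair; may be slightly negative and is not truncated.
    """
    a, b, c = _wc_pair_components(_pop_block(gm, pop_a), _pop_block(gm, pop_b))
    denom = (a + b + c).sum()
    if a.size == 0 or denom == 0.0:
        raise MonomorphicError(
            f"theta undefined for pair ({pop_a!r}, {pop_b!r}): no usable polymorphic loci"
        )
    return float(a.sum() / denom)


def gene_flow_nm(fst: float) -> float:
    """Wright's island-model migrant number, Nm = (1 - Fst) / (4 * Fst).

    Defined only for Fst in (0, 1]; NaN otherwise.
    """
    if not np.isfinite(fst) or fst <= 0.0 or fst > 1.0:
        return float("nan")
    return (1.0 - fst) / (4.0 * fst)


def diversity_table(gm: GenotypeMatrix) -> DiversityTable:
    """Table of n, Ho, He, Fis for every population in the matrix."""
    pops = gm.populations
    n, ho, he, fis, used = [], [], [], [], []
    for pop in pops:
        block = gm.population_calls(pop)
        n.append(block.shape[0])
        h_o, h_e, n_used = heterozygosity(gm, pop)
        ho.append(h_o)
        he.append(h_e)
        fis.append(fis_within(gm, pop))
        used.append(n_used)
    return DiversityTable(populations=pops, n=n, ho=ho, he=he, fis=fis, n_loci_used=used)


def pairwise_matrices(gm: GenotypeMatrix) -> PairwiseMatrices:
    """Symmetric pairwise Fst and Nm over all populations in the matrix."""
    pops = gm.populations
    k = len(pops)
    fst = np.zeros((k, k))
    nm = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            theta = pairwise_fst(gm, pops[i], pops[j])
            fst[i, j] = fst[j, i] = theta
            nm[i, j] = nm[j, i] = gene_flow_nm(theta)
    return PairwiseMatrices(populations=pops, fst=fst, nm=nm)
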