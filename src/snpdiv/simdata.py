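"""Synthetic multi-population SNP genotype data with known truth.

Per-population allele frequencies are drawn around a shared ancestral
frequency with a Beta distribution whose variance is controlled by a
per-population differentiation parameter F (the Balding-Nichols model),
so that the differentiation estimated downstream has a known target.

Draw order (fixed so reruns are bit-identical for a given seed):

1. ancestral frequencies, one uniform draw per locus;
2. for each population in order: its frequency vector (one Beta draw
   per locus, skipped entirely when its F is 0);
3. for each population in order: IBD indicators, then allele draws,
   then the missingness masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from snpdiv.genotype_io import MISSING, GenotypeMatrix, PathOrStream, _as_writer


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a multi-population genotype simulation.

    ``bn_F`` and ``fis`` are per-population: the Beta-variance
    differentiation parameter and the probability that an individual's
    two alleles at a locus are identical by descent.
    """

    n_pops: int
    pop_sizes: tuple[int, ...]
    n_loci: int
    bn_F: tuple[float, ...]
    fis: tuple[float, ...]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate_snp: float = 0.0
    missing_rate_indiv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pop_sizes", tuple(int(x) for x in self.pop_sizes))
        object.__setattr__(self, "bn_F", tuple(float(x) for x in self.bn_F))
        object.__setattr__(self, "fis", tuple(float(x) for x in self.fis))
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        for name in ("pop_sizes", "bn_F", "fis"):
            if len(getattr(self, name)) != self.n_pops:
                raise ValueError(f"{name} must have length n_pops={self.n_pops}")
        if any(s < 2 for s in self.pop_sizes):
            raise ValueError("every pop_size must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(not (0.0 <= f < 1.0) for f in self.bn_F):
            raise ValueError("bn_F values must lie in [0, 1)")
        if any(not (0.0 <= f < 1.0) for f in self.fis):
            raise ValueError("fis values must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must be within (0, 0.5]")
        for name in ("missing_rate_snp", "missing_rate_indiv"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class TruthRecord:
    """True frequencies and parameters behind a simulated dataset."""

    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray  # (n_pops, n_loci)
    bn_F: tuple[float, ...]
    fis: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.pop_freqs = np.asarray(self.pop_freqs, dtype=float)
        if ((self.ancestral_freqs < 0) | (self.ancestral_freqs > 1)).any():
            raise ValueError("ancestral frequencies outside [0, 1]")
        if ((self.pop_freqs < 0) | (self.pop_freqs > 1)).any():
            raise ValueError("population frequencies outside [0, 1]")


def draw_population_freqs(
    ancestral_freqs: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one population's allele frequencies around the ancestral ones.

    For ``F > 0`` each frequency is Beta-distributed with mean ``p`` and
    variance ``F * p * (1 - p)``, i.e. shape parameters
    ``p(1-F)/F`` and ``(1-p)(1-F)/F``.  For ``F == 0`` the ancestral
    vector is returned unchanged (no Beta draw is consumed).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not (0.0 <= F < 1.0):
        raise ValueError("F must lie in [0, 1)")
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_genotypes(
    pop_freqs: np.ndarray,
    n_indiv: int,
    fis: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate dosage calls for one population.

    Per individual and locus: with probability ``fis`` the two alleles
    are identical by descent (a single Bernoulli draw counted twice),
    otherwise two independent Bernoulli draws at the population
    frequency.  Calls are then masked missing independently at
    ``missing_rate``.  Returns an ``(n_indiv, n_loci)`` int8 matrix
    with values in ``{0, 1, 2, MISSING}``.
    """
    q = np.asarray(pop_freqs, dtype=float)
    if ((q < 0.0) | (q > 1.0)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if n_indiv < 1:
        raise ValueError("n_indiv must be >= 1")
    shape = (n_indiv, q.size)
    ibd = rng.random(shape) < fis
    a1 = (rng.random(shape) < q).astype(np.int8)
    a2 = (rng.random(shape) < q).astype(np.int8)
    calls = np.where(ibd, 2 * a1, a1 + a2).astype(np.int8)
    if missing_rate > 0.0:
        calls[rng.random(shape) < missing_rate] = MISSING
    return calls


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a complete labelled multi-population dataset.

    Deterministic for a fixed seed.  Populations are labelled
    ``POP1..POPk``, individuals ``POP1_001`` etc.  Markers are named
    ``SNP000001..`` on chromosomes cycling 1-26 with positions spaced
    10 kb apart.  The per-call missing probability combines the SNP and
    individual rates independently:
    ``1 - (1-missing_rate_snp) * (1-missing_rate_indiv)``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=config.n_loci)

    pop_freqs = np.empty((config.n_pops, config.n_loci))
    for k in range(config.n_pops):
        pop_freqs[k] = draw_population_freqs(anc, config.bn_F[k], rng)

    miss = 1.0 - (1.0 - config.missing_rate_snp) * (1.0 - config.missing_rate_indiv)
    blocks = []
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    for k in range(config.n_pops):
        label = f"POP{k + 1}"
        blocks.append(
            simulate_genotypes(pop_freqs[k], config.pop_sizes[k], config.fis[k], miss, rng)
        )
        for i in range(config.pop_sizes[k]):
            sample_ids.append(f"{label}_{i + 1:03d}")
            pop_labels.append(label)

    n_loci = config.n_loci
    gm = GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        population_labels=np.array(pop_labels, dtype=object),
        marker_ids=np.array([f"SNP{j + 1:06d}" for j in range(n_loci)], dtype=object),
        chromosomes=np.array([str(j % 26 + 1) for j in range(n_loci)], dtype=object),
        positions_bp=np.array([(j // 26 + 1) * 10_000 for j in range(n_loci)]),
        allele_pairs=[("A", "G")] * n_loci,
        calls=np.vstack(blocks),
    )
    truth = TruthRecord(
        ancestral_freqs=anc,
        pop_freqs=pop_freqs,
        bn_F=config.bn_F,
        fis=config.fis,
        seed=config.seed,
    )
    return gm, truth


def write_truth(truth: TruthRecord, sink: PathOrStream) -> None:
    """Write the truth sidecar as TSV with a commented parameter header."""
    fh, close = _as_writer(sink)
    try:
        fh.write(f"# bn_F={','.join(str(f) for f in truth.bn_F)}")
        fh.write(f" fis={','.join(str(f) for f in truth.fis)} seed={truth.seed}\n")
        n_pops = truth.pop_freqs.shape[0]
        cols = ["locus", "ancestral_freq"] + [f"POP{k + 1}_freq" for k in range(n_pops)]
        fh.write("\t".join(cols) + "\n")
        for j in range(truth.ancestral_freqs.size):
            row = [str(j + 1), f"{truth.ancestral_freqs[j]:.8g}"]
            row += [f"{truth.pop_freqs[k, j]:.8g}" for k in range(n_pops)]
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()
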