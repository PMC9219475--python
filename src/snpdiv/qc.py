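"""Quality-control cascade for SNP genotype matrices.

Stage order: (optional) individual call-rate pre-filter, individual
call rate, per-population SNP call rate, pooled minor allele frequency,
per-population Hardy-Weinberg exact test.  All filters use a strict
``<`` comparison against their threshold, and marker metrics are
recomputed on the samples surviving the individual filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Literal

import numpy as np

from snpdiv.genotype_io import MISSING, GenotypeMatrix, PathOrStream, _as_writer


class QcError(ValueError):
    """QC removed all samples or all markers; carries the partial report."""

    def __init__(self, message: str, report: "QcReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds (defaults follow common SNP-chip practice).

    ``indiv_call_rate_prefilter`` is an optional looser individual
    filter applied before everything else; disabled (``None``) by
    default.
    """

    snp_call_rate_per_pop: float = 0.75
    indiv_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    indiv_call_rate_prefilter: float | None = None

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_per_pop", "indiv_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.indiv_call_rate_prefilter is not None and not (
            0.0 <= self.indiv_call_rate_prefilter <= 1.0
        ):
            raise ValueError("indiv_call_rate_prefilter outside [0, 1]")


@dataclass
class QcReport:
    """Audit trail of one QC run: what was removed, at which stage, and why."""

    n_samples_in: int
    n_samples_out: int
    n_markers_in: int
    n_markers_out: int
    removed_individuals: dict[str, float]
    removed_markers_by_stage: dict[str, list[str]]
    thresholds: QcThresholds

    def __post_init__(self) -> None:
        assert self.n_samples_out == self.n_samples_in - len(self.removed_individuals)
        total_removed = sum(len(v) for v in self.removed_markers_by_stage.values())
        assert self.n_markers_out == self.n_markers_in - total_removed
        seen: set[str] = set()
        for ids in self.removed_markers_by_stage.values():
            overlap = seen & set(ids)
            assert not overlap, f"marker(s) attributed to two stages: {overlap}"
            seen |= set(ids)

    def to_tsv(self, sink: PathOrStream) -> None:
        fh, close = _as_writer(sink)
        try:
            fh.write("section\tkey\tvalue\n")
            fh.write(f"counts\tn_samples_in\t{self.n_samples_in}\n")
            fh.write(f"counts\tn_samples_out\t{self.n_samples_out}\n")
            fh.write(f"counts\tn_markers_in\t{self.n_markers_in}\n")
            fh.write(f"counts\tn_markers_out\t{self.n_markers_out}\n")
            t = self.thresholds
            fh.write(f"thresholds\tsnp_call_rate_per_pop\t{t.snp_call_rate_per_pop}\n")
            fh.write(f"thresholds\tindiv_call_rate\t{t.indiv_call_rate}\n")
            fh.write(f"thresholds\tmaf_min\t{t.maf_min}\n")
            fh.write(f"thresholds\thwe_p_min\t{t.hwe_p_min}\n")
            for sid, rate in self.removed_individuals.items():
                fh.write(f"removed_individual\t{sid}\t{rate:.6g}\n")
            for stage, ids in self.removed_markers_by_stage.items():
                for mid in ids:
                    fh.write(f"removed_marker\t{mid}\t{stage}\n")
        finally:
            if close:
                fh.close()


@lru_cache(maxsize=200_000)
def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts (Levene's distribution of
    the heterozygote count) and sums the probabilities of all
    heterozygote counts at most as probable as the observed one.
    Monomorphic input returns 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0

    # log P(het = h | allele counts), unnormalized:
    #   log[ n! / (hom_c! h! hom_r!) * 2^h ]  with hom_r=(rare-h)/2
    def logprob(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_c + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_r + 1)
            + h * math.log(2.0)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    logs = [logprob(h) for h in hs]
    m = max(logs)
    probs = [math.exp(lg - m) for lg in logs]
    total = sum(probs)
    probs = [p / total for p in probs]
    p_obs = probs[hs.index(n_het)]
    # tolerance guards against ties broken by roundoff
    return min(1.0, sum(p for p in probs if p <= p_obs * (1.0 + 1e-12)))


def _levene_probs(n_ref: int, n_alt: int) -> np.ndarray:
    """Full conditional distribution of the heterozygote count; sums to 1."""
    n = (n_ref + n_alt) // 2
    rare = min(n_ref, n_alt)
    hs = np.arange(rare % 2, rare + 1, 2)
    logs = np.array(
        [
            math.lgamma(n + 1)
            - math.lgamma(n - h - (rare - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((rare - h) // 2 + 1)
            + h * math.log(2.0)
            for h in hs
        ]
    )
    p = np.exp(logs - logs.max())
    return p / p.sum()


@dataclass
class QcMetrics:
    """Per-sample and per-marker QC metrics.

    ``snp_pop_call_rate`` and ``hwe_p`` are ``(n_pops, n_markers)``
    arrays in ``population_order``; markers with no data in a
    population get call rate 0 and HWE p-value 1 there.
    """

    indiv_call_rate: np.ndarray
    population_order: list[str]
    snp_pop_call_rate: np.ndarray
    maf: np.ndarray
    hwe_p: np.ndarray


def compute_qc_metrics(gm: GenotypeMatrix) -> QcMetrics:
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("need at least one sample and one marker")
    observed = gm.calls != MISSING
    indiv_cr = observed.mean(axis=1)

    pops = gm.populations
    n_pops, m = len(pops), gm.n_markers
    pop_cr = np.zeros((n_pops, m))
    hwe_p = np.ones((n_pops, m))
    for k, pop in enumerate(pops):
        block = gm.population_calls(pop)
        obs = block != MISSING
        pop_cr[k] = obs.mean(axis=0)
        n_hom_ref = ((block == 0) & obs).sum(axis=0)
        n_het = (block == 1).sum(axis=0)
        n_hom_alt = (block == 2).sum(axis=0)
        for j in range(m):
            total = n_hom_ref[j] + n_het[j] + n_hom_alt[j]
            if total > 0:
                hwe_p[k, j] = hwe_exact_test(
                    int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j])
                )

    with np.errstate(invalid="ignore"):
        alt = np.where(observed, gm.calls, 0).sum(axis=0).astype(float)
        tot = 2.0 * observed.sum(axis=0)
        p_hat = np.divide(alt, tot, out=np.full(m, np.nan), where=tot > 0)
    maf = np.fmin(p_hat, 1.0 - p_hat)
    maf = np.where(np.isnan(maf), 0.0, maf)

    return QcMetrics(
        indiv_call_rate=indiv_cr,
        population_order=pops,
        snp_pop_call_rate=pop_cr,
        maf=maf,
        hwe_p=hwe_p,
    )


def apply_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    hwe_scope: Literal["per-pop", "pooled"] = "per-pop",
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full filter cascade; returns the filtered matrix and report.

    A marker is attributed to the first stage that removes it.  With
    ``hwe_scope="pooled"`` the exact test uses genotype counts pooled
    over populations instead of testing each population separately.
    """
    n_samples_in, n_markers_in = gm.n_samples, gm.n_markers
    removed_individuals: dict[str, float] = {}

    current = gm
    for thresh in (thresholds.indiv_call_rate_prefilter, thresholds.indiv_call_rate):
        if thresh is None:
            continue
        observed = current.calls != MISSING
        rates = observed.mean(axis=1)
        drop = rates < thresh
        for i in np.flatnonzero(drop):
            removed_individuals[current.sample_ids[i]] = float(rates[i])
        if drop.all():
            report = QcReport(
                n_samples_in,
                0,
                n_markers_in,
                n_markers_in,
                removed_individuals,
                {"pop_call_rate": [], "maf": [], "hwe": []},
                thresholds,
            )
            raise QcError("all samples removed by individual call-rate filter", report)
        if drop.any():
            current = current.subset_samples(np.flatnonzero(~drop))

    removed_by_stage: dict[str, list[str]] = {"pop_call_rate": [], "maf": [], "hwe": []}

    metrics = compute_qc_metrics(current)
    bad_cr = (metrics.snp_pop_call_rate < thresholds.snp_call_rate_per_pop).any(axis=0)
    removed_by_stage["pop_call_rate"] = list(current.marker_ids[bad_cr])
    current = current.subset_markers(~bad_cr) if bad_cr.any() else current

    if current.n_markers > 0:
        metrics = compute_qc_metrics(current)
        bad_maf = metrics.maf < thresholds.maf_min
        removed_by_stage["maf"] = list(current.marker_ids[bad_maf])
        current = current.subset_markers(~bad_maf) if bad_maf.any() else current

    if current.n_markers > 0:
        if hwe_scope == "per-pop":
            metrics = compute_qc_metrics(current)
            bad_hwe = (metrics.hwe_p < thresholds.hwe_p_min).any(axis=0)
        else:
            obs = current.calls != MISSING
            bad_hwe = np.zeros(current.n_markers, dtype=bool)
            for j in range(current.n_markers):
                col = current.calls[:, j][obs[:, j]]
                if col.size == 0:
                    continue
                p = hwe_exact_test(
                    int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
                )
                bad_hwe[j] = p < thresholds.hwe_p_min
        removed_by_stage["hwe"] = list(current.marker_ids[bad_hwe])
        current = current.subset_markers(~bad_hwe) if bad_hwe.any() else current

    report = QcReport(
        n_samples_in=n_samples_in,
        n_samples_out=current.n_samples,
        n_markers_in=n_markers_in,
        n_markers_out=current.n_markers,
        removed_individuals=removed_individuals,
        removed_markers_by_stage=removed_by_stage,
        thresholds=thresholds,
    )
    if current.n_markers == 0:
        raise QcError("all markers removed by QC", report)
    return current, report
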