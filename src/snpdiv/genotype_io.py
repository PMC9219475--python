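"""PLINK-style text PED/MAP genotype I/O.

Genotypes are stored as alternate-allele dosage: 0, 1, or 2 copies of
``allele2`` per call, with :data:`MISSING` (-1) marking missing calls.
Population membership is carried in the PED family-ID column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

#: Sentinel for a missing diploid call in :attr:`GenotypeMatrix.calls`.
MISSING: int = -1

PathOrStream = Union[str, Path, IO[str]]


class PedMapError(ValueError):
    """Malformed or inconsistent PED/MAP input."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for samples grouped into populations.

    Parameters
    ----------
    sample_ids
        Unique individual identifiers, one per row of ``calls``.
    population_labels
        Population (breed) label per sample.
    marker_ids
        Unique marker identifiers, one per column of ``calls``.
    chromosomes
        Chromosome name per marker (opaque strings).
    positions_bp
        1-based physical position per marker.
    allele_pairs
        ``(allele1, allele2)`` per marker; calls count copies of
        ``allele2``.  ``"0"`` marks an allele never observed.
    calls
        ``(n_samples, n_markers)`` integer matrix with values in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: np.ndarray
    population_labels: np.ndarray
    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    allele_pairs: list[tuple[str, str]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.calls.shape
        if len(self.sample_ids) != n or len(self.population_labels) != n:
            raise PedMapError("sample metadata length does not match calls rows")
        if (
            len(self.marker_ids) != m
            or len(self.chromosomes) != m
            or len(self.positions_bp) != m
            or len(self.allele_pairs) != m
        ):
            raise PedMapError("marker metadata length does not match calls columns")
        if len(set(self.sample_ids)) != n:
            raise PedMapError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise PedMapError("duplicate marker ids")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise PedMapError(f"invalid call codes {bad.tolist()}; expected 0/1/2/{MISSING}")
        if (self.positions_bp < 0).any():
            raise PedMapError("negative bp position")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.population_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids[index],
            population_labels=self.population_labels[index],
            marker_ids=self.marker_ids,
            chromosomes=self.chromosomes,
            positions_bp=self.positions_bp,
            allele_pairs=list(self.allele_pairs),
            calls=self.calls[index, :],
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            population_labels=self.population_labels,
            marker_ids=self.marker_ids[idx],
            chromosomes=self.chromosomes[idx],
            positions_bp=self.positions_bp[idx],
            allele_pairs=[self.allele_pairs[i] for i in idx],
            calls=self.calls[:, idx],
        )

    def subset_populations(self, labels: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(labels)
        missing = wanted - set(self.populations)
        if missing:
            raise KeyError(f"populations not present: {sorted(missing)}")
        keep = np.array([lab in wanted for lab in self.population_labels])
        return self.subset_samples(np.flatnonzero(keep))

    def population_calls(self, label: str) -> np.ndarray:
        """Calls submatrix for one population (rows = its samples)."""
        mask = self.population_labels == label
        if not mask.any():
            raise KeyError(f"population {label!r} not present")
        return self.calls[mask, :]


def _as_reader(source: PathOrStream) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _as_writer(sink: PathOrStream) -> tuple[IO[str], bool]:
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8"), True
    return sink, False


def read_ped_map(ped_source: PathOrStream, map_source: PathOrStream) -> GenotypeMatrix:
    """Read whitespace-delimited PED and MAP text into a GenotypeMatrix.

    The PED family-ID column becomes the population label.  Per marker,
    ``allele2`` is the lexicographically larger observed allele; a
    genotype with one missing allele ("half-missing") is treated as
    fully missing.

    Raises
    ------
    PedMapError
        On PED/MAP marker-count mismatch, more than two alleles at a
        marker, or duplicate sample/marker ids.
    """
    map_fh = _as_reader(map_source)
    try:
        marker_ids: list[str] = []
        chromosomes: list[str] = []
        positions: list[int] = []
        for lineno, line in enumerate(map_fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedMapError(f"MAP line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, mid, _gd, pos = fields
            chromosomes.append(chrom)
            marker_ids.append(mid)
            positions.append(int(pos))
    finally:
        if isinstance(map_source, (str, Path)):
            map_fh.close()

    n_markers = len(marker_ids)
    if len(set(marker_ids)) != n_markers:
        raise PedMapError("duplicate marker id in MAP")

    sample_ids: list[str] = []
    pop_labels: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    ped_fh = _as_reader(ped_source)
    try:
        for lineno, line in enumerate(ped_fh, 1):
            fields = line.split()
            if not fields:
                continue
            expected = 6 + 2 * n_markers
            if len(fields) != expected:
                got = (len(fields) - 6) // 2
                raise PedMapError(
                    f"PED line {lineno}: {got} markers but MAP lists {n_markers}"
                )
            fam, iid = fields[0], fields[1]
            pop_labels.append(fam)
            sample_ids.append(iid)
            alleles = fields[6:]
            rows.append([(alleles[2 * k], alleles[2 * k + 1]) for k in range(n_markers)])
    finally:
        if isinstance(ped_source, (str, Path)):
            ped_fh.close()

    if len(set(sample_ids)) != len(sample_ids):
        raise PedMapError("duplicate sample id in PED")

    n_samples = len(sample_ids)
    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_pairs: list[tuple[str, str]] = []
    for j in range(n_markers):
        observed: set[str] = set()
        for i in range(n_samples):
            a, b = rows[i][j]
            if a != "0":
                observed.add(a)
            if b != "0":
                observed.add(b)
        if len(observed) > 2:
            raise PedMapError(
                f"marker {marker_ids[j]!r} has >2 alleles: {sorted(observed)}"
            )
        if len(observed) == 2:
            a1, a2 = sorted(observed)
        elif len(observed) == 1:
            a1, a2 = "0", observed.pop()
        else:
            a1, a2 = "0", "0"
        allele_pairs.append((a1, a2))
        for i in range(n_samples):
            a, b = rows[i][j]
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == a2) + (b == a2)

    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        population_labels=np.array(pop_labels, dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        chromosomes=np.array(chromosomes, dtype=object),
        positions_bp=np.array(positions, dtype=np.int64),
        allele_pairs=allele_pairs,
        calls=calls,
    )


def write_ped_map(gm: GenotypeMatrix, ped_sink: PathOrStream, map_sink: PathOrStream) -> None:
    """Write a GenotypeMatrix as PED/MAP text re-readable by :func:`read_ped_map`.

    Father/mother/sex/phenotype columns are emitted as ``0 0 0 -9``;
    genetic distance in the MAP is emitted as 0.
    """
    map_fh, close_map = _as_writer(map_sink)
    try:
        for j in range(gm.n_markers):
            map_fh.write(
                f"{gm.chromosomes[j]}\t{gm.marker_ids[j]}\t0\t{gm.positions_bp[j]}\n"
            )
    finally:
        if close_map:
            map_fh.close()

    ped_fh, close_ped = _as_writer(ped_sink)
    try:
        for i in range(gm.n_samples):
            parts = [
                str(gm.population_labels[i]),
                str(gm.sample_ids[i]),
                "0",
                "0",
                "0",
                "-9",
            ]
            row = gm.calls[i]
            for j in range(gm.n_markers):
                a1, a2 = gm.allele_pairs[j]
                c = row[j]
                if c == MISSING:
                    parts.extend(("0", "0"))
                elif c == 0:
                    parts.extend((a1, a1))
                elif c == 1:
                    parts.extend((a1, a2))
                else:
                    parts.extend((a2, a2))
            ped_fh.write(" ".join(parts))
            ped_fh.write("\n")
    finally:
        if close_ped:
            ped_fh.close()
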