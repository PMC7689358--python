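"""Core genotype containers.

A :class:`MarkerMap` describes an ordered biallelic SNP panel (chromosome,
genetic position in Morgans, 0-based column index).  Haplotypes are stored as
binary ``h x p`` matrices (:class:`HaplotypeSet`); diploid individuals as
``n x p`` allele-dosage matrices with entries in ``{0, 1, 2}``
(:class:`GenotypePanel`), the coding used as network/model input throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map.

    Markers are stored in column order: all markers of chromosome c precede
    those of chromosome c+1, and genetic positions are non-decreasing within
    a chromosome.  The implicit column index 0..p-1 is the marker "index"
    used by trait architectures and window layers.
    """

    marker_ids: np.ndarray
    chromosome: np.ndarray
    genetic_position: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.marker_ids, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.genetic_position, dtype=np.float64)
        if not (ids.shape == chrom.shape == pos.shape) or ids.ndim != 1:
            raise ValueError("marker_ids, chromosome and genetic_position must be 1-D and aligned")
        if ids.size < 1:
            raise ValueError("empty marker map")
        if np.any(chrom < 1):
            raise ValueError("chromosome numbers must be positive")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be grouped by chromosome in increasing order")
        if np.any(pos < 0):
            raise ValueError("genetic positions must be non-negative (Morgans)")
        for _, sl in _chrom_slices(chrom).items():
            if np.any(np.diff(pos[sl]) < 0):
                raise ValueError("genetic positions must be non-decreasing within a chromosome")
        object.__setattr__(self, "marker_ids", ids)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "genetic_position", pos)

    @property
    def n_markers(self) -> int:
        return int(self.marker_ids.size)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome numbers, in map order."""
        return np.unique(self.chromosome)

    def chrom_slices(self) -> dict[int, slice]:
        """Mapping chromosome -> contiguous column slice."""
        return _chrom_slices(self.chromosome)

    @classmethod
    def equidistant(cls, n_markers: int, n_chromosomes: int = 10,
                    chrom_length: float = 1.0, prefix: str = "snp") -> "MarkerMap":
        """Equidistant map: markers split as evenly as possible across
        ``n_chromosomes`` chromosomes of ``chrom_length`` Morgans each."""
        if n_markers < n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        counts = np.full(n_chromosomes, n_markers // n_chromosomes, dtype=int)
        counts[: n_markers % n_chromosomes] += 1
        chrom, pos = [], []
        for c, m in enumerate(counts, start=1):
            chrom.append(np.full(m, c))
            pos.append(np.linspace(0.0, chrom_length, m))
        ids = np.array([f"{prefix}{j + 1}" for j in range(n_markers)], dtype=object)
        return cls(ids, np.concatenate(chrom), np.concatenate(pos))


def _chrom_slices(chrom: np.ndarray) -> dict[int, slice]:
    out: dict[int, slice] = {}
    boundaries = np.flatnonzero(np.diff(chrom)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [chrom.size]])
    for a, b in zip(starts, stops):
        out[int(chrom[a])] = slice(int(a), int(b))
    return out


@dataclass(frozen=True)
class HaplotypeSet:
    """``h x p`` binary haplotype matrix plus its marker map.

    Haplotypes are paired into individuals (2i, 2i+1) when an even number is
    present; pairing order is decided by whoever constructed the set.
    """

    haplotypes: np.ndarray
    map: MarkerMap

    def __post_init__(self):
        hap = np.asarray(self.haplotypes)
        if hap.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if hap.shape[1] != self.map.n_markers:
            raise ValueError("haplotype column count does not match the marker map")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        object.__setattr__(self, "haplotypes", hap.astype(np.uint8, copy=False))

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class GenotypePanel:
    """``n x p`` diploid dosage matrix (entries 0/1/2) with map and sample ids."""

    dosages: np.ndarray
    map: MarkerMap
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        M = np.asarray(self.dosages)
        if M.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if M.shape[1] != self.map.n_markers:
            raise ValueError("dosage column count does not match the marker map")
        if not np.isin(M, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2 (no missing values)")
        object.__setattr__(self, "dosages", M.astype(np.int8, copy=False))
        if self.sample_ids is None:
            ids = np.array([f"id{i + 1}" for i in range(M.shape[0])], dtype=object)
        else:
            ids = np.asarray(self.sample_ids, dtype=object)
            if ids.shape != (M.shape[0],):
                raise ValueError("sample_ids length does not match the dosage row count")
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.dosages.shape[1])

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, mean dosage / 2."""
        return self.dosages.mean(axis=0, dtype=np.float64) / 2.0

    @classmethod
    def from_haplotypes(cls, haps: HaplotypeSet,
                        sample_ids: np.ndarray | None = None) -> "GenotypePanel":
        """Pair haplotypes (2i, 2i+1) into diploid individuals."""
        h = haps.n_haplotypes
        if h % 2 != 0:
            raise ValueError("need an even number of haplotypes to form individuals")
        dos = haps.haplotypes[0::2].astype(np.int8) + haps.haplotypes[1::2].astype(np.int8)
        return cls(dos, haps.map, sample_ids)
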