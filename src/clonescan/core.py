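"""Shared data containers for genotype, haplotype and phased-block data.

Allele values are small integer codes (0-3, mapped to A/C/G/T at the I/O
boundary); missing genotypes are coded -1.  Positions are 1-based within
their contig, and physical distance is only defined between sites on the
same contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotypes with up to 4 alleles per site.

    Attributes
    ----------
    contigs : array of str, shape (n_sites,)
    positions : int array, shape (n_sites,); 1-based, strictly increasing
        within each contig.
    genotypes : int8 array, shape (n_sites, n_individuals, 2); unordered
        allele pairs stored sorted (g[..., 0] <= g[..., 1]); -1 = missing.
    individuals : list of sample labels.
    """

    contigs: np.ndarray
    positions: np.ndarray
    genotypes: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_individuals, 2)")
        if len(self.contigs) != self.n_sites or len(self.positions) != self.n_sites:
            raise ValueError("site annotation length mismatch")
        for contig in np.unique(self.contigs.astype(str)):
            pos = self.positions[self.contigs.astype(str) == contig]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
        # canonical unordered representation
        self.genotypes = np.sort(self.genotypes, axis=2)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def site_alleles(self, i: int) -> np.ndarray:
        """Distinct non-missing allele codes observed at site ``i``."""
        g = self.genotypes[i]
        return np.unique(g[g >= 0])

    def n_alleles(self) -> np.ndarray:
        """Number of distinct observed alleles at each site."""
        out = np.empty(self.n_sites, dtype=np.int64)
        for i in range(self.n_sites):
            out[i] = len(self.site_alleles(i))
        return out

    def is_biallelic(self) -> np.ndarray:
        return self.n_alleles() == 2

    def has_missing(self) -> np.ndarray:
        return (self.genotypes < 0).any(axis=(1, 2))

    def dosage(self, i: int) -> np.ndarray:
        """Minor-allele dosage vector (0/1/2 per individual) at biallelic site i."""
        alleles = self.site_alleles(i)
        if len(alleles) != 2:
            raise ValueError("dosage defined for biallelic sites only")
        counts = [(self.genotypes[i] == a).sum() for a in alleles]
        minor = alleles[int(np.argmin(counts))]
        return (self.genotypes[i] == minor).sum(axis=1)

    def take_sites(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.contigs[idx], self.positions[idx], self.genotypes[idx], list(self.individuals)
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.contigs,
            self.positions,
            self.genotypes[:, idx, :],
            [self.individuals[i] for i in idx],
        )


@dataclass
class SegmentHaplotypes:
    """Two phased haplotype allele sequences per individual over one segment.

    Rows 2*i and 2*i+1 of ``haplotypes`` are the two haplotypes of
    ``individuals[i]``; columns follow ``positions`` (1-based, on ``contig``).
    """

    contig: str
    start: int
    end: int
    positions: np.ndarray
    individuals: list[str]
    haplotypes: np.ndarray  # (2*n_individuals, n_snps) int8
    origins: list[str] | None = None  # optional per-haplotype provenance labels

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.individuals), len(self.positions)):
            raise ValueError("haplotype matrix shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def labels(self) -> list[str]:
        """Leaf labels 'individual.1' / 'individual.2' in row order."""
        out = []
        for ind in self.individuals:
            out.extend([f"{ind}.1", f"{ind}.2"])
        return out

    def individual_haplotypes(self, ind: str) -> np.ndarray:
        i = self.individuals.index(ind)
        return self.haplotypes[2 * i : 2 * i + 2]


@dataclass
class PhasedBlock:
    """One read-based phasing block: an ordered run of heterozygous SNPs
    with a joint haplotype assignment for a single individual.

    ``hap1``/``hap2`` hold allele codes; ``switch_qual``/``mismatch_qual``
    are phred-like per-SNP confidence scores.
    """

    individual: str
    contig: str
    positions: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray
    switch_qual: np.ndarray | None = None
    mismatch_qual: np.ndarray | None = None
    homozygous: np.ndarray = field(default=None)  # bool mask: SNP added to both haplotypes

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("block positions must be strictly increasing")
        if not (len(self.hap1) == len(self.hap2) == len(self.positions)):
            raise ValueError("block array length mismatch")
        for name in ("switch_qual", "mismatch_qual"):
            q = getattr(self, name)
            if q is not None:
                setattr(self, name, np.asarray(q, dtype=float))
        if self.homozygous is None:
            self.homozygous = self.hap1 == self.hap2
        else:
            self.homozygous = np.asarray(self.homozygous, dtype=bool)

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def het_mask(self) -> np.ndarray:
        return self.hap1 != self.hap2

    def subset(self, mask_or_idx) -> "PhasedBlock":
        idx = np.asarray(mask_or_idx)
        return PhasedBlock(
            self.individual,
            self.contig,
            self.positions[idx],
            self.hap1[idx],
            self.hap2[idx],
            None if self.switch_qual is None else self.switch_qual[idx],
            None if self.mismatch_qual is None else self.mismatch_qual[idx],
            self.homozygous[idx],
        )


def genotypes_from_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Unordered genotype array (n_sites, n_ind, 2) from a (2n, n_sites)
    haplotype matrix with rows 2i, 2i+1 belonging to individual i."""
    n2, s = haplotypes.shape
    g = np.stack([haplotypes[0::2].T, haplotypes[1::2].T], axis=2)
    return np.sort(g, axis=2).astype(np.int8)
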