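"""Marker maps for the simulated bovine genome.

The simulated genome mirrors the bovine autosomes: a configurable number of
chromosomes whose genetic lengths sum to a configurable total (default
24.71 Morgans over 29 autosomes, proportioned like the ARS-UCD1.2 assembly).
The map-distance convention throughout the package is 1 cM = 1 Mbp, so
physical positions are derived from genetic positions as bp = Morgans * 1e8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Approximate ARS-UCD1.2 autosome physical lengths (Mbp), BTA1..BTA29.
# Used only as proportions when distributing the total genetic length.
ARS_UCD_AUTOSOME_MBP = np.array([
    158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
    107.0, 87.2, 83.5, 82.4, 85.0, 81.0, 73.2, 65.8, 63.4, 72.0,
    69.9, 60.8, 52.5, 62.3, 42.4, 52.0, 45.6, 45.9, 51.1,
])

#: Total autosomal genome length used for ROH-based inbreeding (bp),
#: from the ARS-UCD1.2 reference assembly.
CATTLE_AUTOSOME_BP = 2_489_385_000

MORGAN_TO_BP = 100_000_000  # 1 cM = 1 Mbp


@dataclass
class MarkerMap:
    """Ordered loci on a multi-chromosome genetic map.

    Attributes
    ----------
    chrom : (m,) int array, 1-based chromosome index, nondecreasing.
    pos_bp : (m,) int array, physical position, strictly increasing within
        a chromosome.
    gen_pos : (m,) float array, genetic position in Morgans from the start
        of the chromosome, nondecreasing within a chromosome.
    is_qtl : (m,) bool array, True for QTL, False for SNP.
    alleles : pair of allele labels shared by all loci (biallelic genome).
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    gen_pos: np.ndarray
    is_qtl: np.ndarray
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.gen_pos = np.asarray(self.gen_pos, dtype=np.float64)
        self.is_qtl = np.asarray(self.is_qtl, dtype=bool)
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        n_loci: int,
        n_chromosomes: int = 29,
        total_morgans: float = 24.71,
        proportional_lengths: bool = True,
    ) -> "MarkerMap":
        """Lay out ``n_loci`` evenly spaced loci over the genome.

        Loci counts per chromosome are proportional to chromosome length so
        the marker density is uniform genome-wide. With
        ``proportional_lengths`` chromosome lengths follow the ARS-UCD1.2
        autosome proportions; otherwise all chromosomes are equal.
        """
        if n_loci <= 0 or n_chromosomes <= 0 or total_morgans <= 0:
            raise ValueError("n_loci, n_chromosomes and total_morgans must be positive")
        if proportional_lengths:
            w = ARS_UCD_AUTOSOME_MBP[:n_chromosomes].astype(float)
            if n_chromosomes > len(ARS_UCD_AUTOSOME_MBP):
                raise ValueError("proportional lengths defined for at most 29 chromosomes")
        else:
            w = np.ones(n_chromosomes)
        lengths = total_morgans * w / w.sum()

        # largest-remainder apportionment of loci to chromosomes
        exact = n_loci * lengths / total_morgans
        counts = np.floor(exact).astype(int)
        remainder = n_loci - counts.sum()
        order = np.argsort(exact - counts)[::-1]
        counts[order[:remainder]] += 1
        if np.any(counts < 1):
            raise ValueError("too few loci for the number of chromosomes")

        chrom, gpos = [], []
        for c in range(n_chromosomes):
            k = counts[c]
            # evenly spaced, offset half a spacing from the chromosome ends
            gpos.append((np.arange(k) + 0.5) / k * lengths[c])
            chrom.append(np.full(k, c + 1, dtype=np.int32))
        chrom = np.concatenate(chrom)
        gpos = np.concatenate(gpos)
        pos_bp = np.round(gpos * MORGAN_TO_BP).astype(np.int64)
        return cls(chrom, pos_bp, gpos, np.zeros(n_loci, dtype=bool))

    # -- basic queries -----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slices(self) -> list[slice]:
        """Contiguous index slice of each chromosome, in order."""
        bounds = np.flatnonzero(np.diff(self.chrom)) + 1
        edges = np.concatenate([[0], bounds, [self.n_loci]])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def chrom_starts(self) -> np.ndarray:
        """Boolean mask: True at the first locus of each chromosome."""
        mask = np.zeros(self.n_loci, dtype=bool)
        mask[0] = True
        mask[1:] = np.diff(self.chrom) != 0
        return mask

    def switch_probabilities(self) -> np.ndarray:
        """Per-locus probability of switching source haplotype in meiosis.

        Haldane model: between adjacent loci d Morgans apart the gamete
        switches parental haplotype with probability (1 - e^{-2d})/2; at the
        first locus of each chromosome the source haplotype is drawn fresh,
        encoded as a switch probability of 0.5.
        """
        p = np.empty(self.n_loci)
        d = np.diff(self.gen_pos)
        p[1:] = 0.5 * (1.0 - np.exp(-2.0 * np.abs(d)))
        p[self.chrom_starts()] = 0.5
        return p

    def subset(self, index: np.ndarray) -> "MarkerMap":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.sort(index)
        return MarkerMap(
            self.chrom[index], self.pos_bp[index], self.gen_pos[index],
            self.is_qtl[index], self.alleles,
        )

    def validate(self) -> None:
        if not (len(self.chrom) == len(self.pos_bp) == len(self.gen_pos) == len(self.is_qtl)):
            raise ValueError("marker map arrays must share a length")
        for sl in self.chrom_slices():
            if np.any(np.diff(self.pos_bp[sl]) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
            if np.any(np.diff(self.gen_pos[sl]) < 0):
                raise ValueError("genetic positions must be nondecreasing within a chromosome")
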