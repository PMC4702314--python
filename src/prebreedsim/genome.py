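"""Genome map, founder haplotype panel, and individuals with origin tracking.

Coordinates are genetic (centimorgan) throughout; there is no physical map.
Every haplotype carried by an individual is annotated with a piecewise-constant
*origin track*: which founder haplotype each genome segment descends from.
Origin tracks are what make exact identity-by-descent kinship computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeParams",
    "GenomeMap",
    "HaplotypePanel",
    "OriginTrack",
    "Individual",
    "single_segment_track",
    "reconstruct_alleles",
]


@dataclass(frozen=True)
class GenomeParams:
    """Parameters of the simulated genome (maize-like defaults).

    ``loci_per_chromosome`` is the locus budget retained after thinning the
    coalescent segregating sites; QTL and candidate markers are carved out of
    this shared set, so it must cover the largest marker panel plus the QTL.
    """

    n_chromosomes: int = 10
    chrom_length_cm: float = 200.0
    loci_per_chromosome: int = 2000
    maf_min: float = 0.05
    bp_per_chromosome: int = 1_000_000
    #: per-bp mutation rate; ``None`` -> chosen so the locus budget is met
    mutation_rate: float | None = None

    @property
    def chrom_lengths_cm(self) -> np.ndarray:
        return np.full(self.n_chromosomes, self.chrom_length_cm)


@dataclass
class GenomeMap:
    """Locus positions (cM) per chromosome plus QTL / candidate-marker sets.

    Loci are indexed globally in chromosome-concatenation order;
    ``qtl_index`` and ``candidate_marker_index`` are disjoint global indices.
    """

    chrom_lengths_cm: np.ndarray
    positions_cm: list[np.ndarray]
    qtl_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    candidate_marker_index: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        for c, pos in enumerate(self.positions_cm):
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on chromosome {c} not strictly increasing")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_lengths_cm[c]):
                raise ValueError(f"positions on chromosome {c} outside [0, length]")
        if np.intersect1d(self.qtl_index, self.candidate_marker_index).size:
            raise ValueError("qtl_index and candidate_marker_index overlap")

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions_cm)

    @property
    def n_loci(self) -> int:
        return int(sum(p.size for p in self.positions_cm))

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global index of the first locus of each chromosome (plus total)."""
        return np.concatenate([[0], np.cumsum([p.size for p in self.positions_cm])])

    def chrom_slice(self, c: int) -> slice:
        off = self.chrom_offsets
        return slice(int(off[c]), int(off[c + 1]))

    def locus_chromosome(self) -> np.ndarray:
        """Chromosome id of every global locus index."""
        return np.repeat(
            np.arange(self.n_chromosomes), [p.size for p in self.positions_cm]
        )

    def global_positions(self) -> np.ndarray:
        """Per-locus genetic position (cM, within its own chromosome)."""
        return np.concatenate(self.positions_cm)


@dataclass
class HaplotypePanel:
    """Founder haplotypes: biallelic 0/1 arrays with one founder id each."""

    haplotypes: np.ndarray  # (n_haplotypes, n_loci) int8, 0 = ancestral
    founder_ids: np.ndarray  # (n_haplotypes,) unique int labels
    Ne: float
    #: usable segregating sites per chromosome before thinning to the budget
    n_source_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(np.unique(self.founder_ids)) != len(self.founder_ids):
            raise ValueError("founder_ids must be unique")
        if self.haplotypes.shape[0] != self.founder_ids.shape[0]:
            raise ValueError("one founder_id per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


#: (segment start positions in cM beginning at 0.0, founder id per segment)
OriginTrack = tuple[np.ndarray, np.ndarray]


def single_segment_track(founder_id: int, n_chromosomes: int) -> list[OriginTrack]:
    """Origin of an intact founder haplotype: one segment per chromosome."""
    return [
        (np.zeros(1), np.array([founder_id], dtype=np.int32))
        for _ in range(n_chromosomes)
    ]


def canonical_track(starts: np.ndarray, ids: np.ndarray) -> OriginTrack:
    """Merge adjacent segments with identical founder ids."""
    if ids.size <= 1:
        return starts, ids
    keep = np.concatenate([[True], ids[1:] != ids[:-1]])
    return starts[keep], ids[keep]


class Individual:
    """A diploid plant: two haplotypes over all loci plus origin tracks.

    ``origins[h][c]`` is the :data:`OriginTrack` of haplotype ``h`` on
    chromosome ``c``. ``haplotypes[0]`` is maternal, ``haplotypes[1]`` paternal.
    """

    __slots__ = ("haplotypes", "origins", "role", "id", "mother_id", "father_id")

    def __init__(
        self,
        haplotypes: np.ndarray,
        origins: Sequence[list[OriginTrack]],
        role: str = "",
        id: int | str | None = None,
        mother_id: int | str | None = None,
        father_id: int | str | None = None,
    ) -> None:
        self.haplotypes = haplotypes
        self.origins = list(origins)
        self.role = role
        self.id = id
        self.mother_id = mother_id
        self.father_id = father_id

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        if loci is None:
            return self.haplotypes[0].astype(np.int16) + self.haplotypes[1]
        return self.haplotypes[0, loci].astype(np.int16) + self.haplotypes[1, loci]

    def heterozygosity(self, loci: np.ndarray | None = None) -> float:
        h0, h1 = self.haplotypes
        if loci is not None:
            h0, h1 = h0[loci], h1[loci]
        return float(np.mean(h0 != h1)) if h0.size else 0.0

    def is_fully_homozygous(self) -> bool:
        return bool(np.all(self.haplotypes[0] == self.haplotypes[1]))


def track_ids_at(track: OriginTrack, positions: np.ndarray) -> np.ndarray:
    """Founder id of a track at each query position (cM)."""
    starts, ids = track
    seg = np.searchsorted(starts, positions, side="right") - 1
    return ids[seg]


def reconstruct_alleles(
    individual: Individual, panel: HaplotypePanel, gmap: GenomeMap
) -> np.ndarray:
    """Rebuild the individual's alleles purely from origin tracks + panel.

    Exactness of this reconstruction is the core bookkeeping invariant of the
    simulator: alleles and origin tracks must never drift apart.
    """
    id_to_row = {int(f): r for r, f in enumerate(panel.founder_ids)}
    out = np.empty_like(individual.haplotypes)
    for h in range(2):
        for c in range(gmap.n_chromosomes):
            sl = gmap.chrom_slice(c)
            fids = track_ids_at(individual.origins[h][c], gmap.positions_cm[c])
            rows = np.array([id_to_row[int(f)] for f in fids])
            out[h, sl] = panel.haplotypes[rows, np.arange(sl.start, sl.stop)]
    return out
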