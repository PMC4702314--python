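"""Gamete formation, crossing, doubled haploids, and random mating.

Recombination follows the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the genetic length in Morgans, crossover positions
are uniform, and there is no interference and no obligate chiasma. Origin
tracks are spliced through every meiosis so identity by descent stays exact.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .genome import GenomeMap, Individual, OriginTrack, canonical_track

__all__ = ["Gamete", "make_gamete", "cross", "make_dh", "random_mate"]


class Gamete:
    """One haplotype over all loci plus its origin track per chromosome."""

    __slots__ = ("haplotype", "origins")

    def __init__(self, haplotype: np.ndarray, origins: list[OriginTrack]) -> None:
        self.haplotype = haplotype
        self.origins = origins


def _splice_tracks(
    track_a: OriginTrack,
    track_b: OriginTrack,
    xpos: np.ndarray,
    start_strand: int,
    length_cm: float,
) -> OriginTrack:
    """Origin track of a recombinant strand: pieces of a/b between crossovers."""
    if xpos.size == 0:
        src = track_a if start_strand == 0 else track_b
        return src[0].copy(), src[1].copy()
    bounds = np.concatenate([[0.0], xpos, [length_cm]])
    starts_out: list[np.ndarray] = []
    ids_out: list[np.ndarray] = []
    for k in range(bounds.size - 1):
        lo, hi = bounds[k], bounds[k + 1]
        starts, ids = track_a if (start_strand + k) % 2 == 0 else track_b
        i = np.searchsorted(starts, lo, side="right") - 1
        j = np.searchsorted(starts, hi, side="left")
        seg_starts = starts[i:j].copy()
        seg_starts[0] = lo
        starts_out.append(seg_starts)
        ids_out.append(ids[i:j])
    return canonical_track(np.concatenate(starts_out), np.concatenate(ids_out))


def make_gamete(
    parent: Individual, gmap: GenomeMap, rng: np.random.Generator
) -> Gamete:
    """Sample one recombinant gamete from a parent."""
    hap = np.empty(parent.n_loci, dtype=parent.haplotypes.dtype)
    origins: list[OriginTrack] = []
    h0, h1 = parent.haplotypes
    for c in range(gmap.n_chromosomes):
        length = float(gmap.chrom_lengths_cm[c])
        sl = gmap.chrom_slice(c)
        n_x = rng.poisson(length / 100.0)
        start = int(rng.integers(2))
        if n_x == 0:
            hap[sl] = h0[sl] if start == 0 else h1[sl]
            src = parent.origins[start][c]
            origins.append((src[0].copy(), src[1].copy()))
            continue
        xpos = np.sort(rng.uniform(0.0, length, n_x))
        parity = (np.searchsorted(xpos, gmap.positions_cm[c], side="right") + start) % 2
        seg = np.where(parity == 0, h0[sl], h1[sl])
        hap[sl] = seg
        origins.append(
            _splice_tracks(
                parent.origins[0][c], parent.origins[1][c], xpos, start, length
            )
        )
    return Gamete(hap, origins)


def cross(
    mother: Individual,
    father: Individual,
    gmap: GenomeMap,
    rng: np.random.Generator,
    role: str = "",
    id: int | str | None = None,
) -> Individual:
    """One offspring: one gamete from each parent (maternal first)."""
    gm = make_gamete(mother, gmap, rng)
    gf = make_gamete(father, gmap, rng)
    return Individual(
        haplotypes=np.stack([gm.haplotype, gf.haplotype]),
        origins=[gm.origins, gf.origins],
        role=role,
        id=id,
        mother_id=mother.id,
        father_id=father.id,
    )


def make_dh(
    parent: Individual,
    gmap: GenomeMap,
    rng: np.random.Generator,
    role: str = "DH",
    id: int | str | None = None,
) -> Individual:
    """Doubled haploid: one gamete duplicated into both haplotypes."""
    g = make_gamete(parent, gmap, rng)
    origins_copy = [(s.copy(), i.copy()) for s, i in g.origins]
    return Individual(
        haplotypes=np.stack([g.haplotype, g.haplotype.copy()]),
        origins=[g.origins, origins_copy],
        role=role,
        id=id,
        mother_id=parent.id,
        father_id=parent.id,
    )


def random_mate(
    plants: Sequence[Individual],
    n_seeds_per_plant: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
    role: str = "synthetic",
) -> list[Individual]:
    """Random mating without selfing: each plant mothers ``n_seeds_per_plant``
    seeds, the father drawn uniformly from the *other* plants."""
    if len(plants) < 2:
        raise ValueError("random mating requires at least 2 plants (selfing not modeled)")
    offspring: list[Individual] = []
    n = len(plants)
    for i, mother in enumerate(plants):
        mates = rng.integers(0, n - 1, n_seeds_per_plant)
        mates = np.where(mates >= i, mates + 1, mates)  # skip self
        for j in mates:
            offspring.append(cross(mother, plants[int(j)], gmap, rng, role=role))
    return offspring
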