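"""Genotyping-by-sequencing: marker panels and coverage-dependent dosages.

Read depth per locus per individual is Poisson at the platform's mean
coverage; reads miscall the allele with a small error probability. Genotypes
are reported as continuous dosages: the posterior mean of the genotype given
the reads under a Hardy-Weinberg prior at the current-population allele
frequency. Zero-read entries are flagged missing and mean-imputed, which keeps
the ridge design matrix complete - the only way a 1x platform is usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import GenomeMap, Individual

__all__ = ["Platform", "GenotypeMatrix", "PLATFORM_PRESETS", "select_marker_panel", "genotype"]


@dataclass(frozen=True)
class Platform:
    name: str
    n_markers: int
    coverage: float  # mean reads per locus per individual
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


#: the two platforms of the factorial design, at full scale
PLATFORM_PRESETS = {
    "GBS10x@10K": dict(n_markers=10_000, coverage=10.0),
    "GBS1x@100K": dict(n_markers=100_000, coverage=1.0),
}


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosages in [0, 2] with an explicit missing mask."""

    dosages: np.ndarray
    missing: np.ndarray
    marker_index: np.ndarray  # global locus indices of the panel
    platform: Platform

    def __post_init__(self) -> None:
        if np.any((self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def to_csv(self, path, sample_names=None) -> None:
        """Dosage matrix as CSV (rows = individuals, columns = marker loci);
        missing entries written empty."""
        import pandas as pd

        df = pd.DataFrame(
            np.where(self.missing, np.nan, self.dosages),
            index=list(sample_names or (f"IND{i}" for i in range(self.n_individuals))),
            columns=[f"L{int(j)}" for j in self.marker_index],
        )
        df.to_csv(path, index_label="sample")


def select_marker_panel(
    gmap: GenomeMap, panel_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a marker panel approximately uniform on the genetic map.

    Markers come only from the candidate set (never QTL); per-chromosome
    counts are proportional to genetic length, and within a chromosome the
    candidates nearest an evenly spaced grid are taken.
    """
    candidates = gmap.candidate_marker_index
    if panel_size > candidates.size:
        raise ValueError(
            f"panel_size={panel_size} exceeds {candidates.size} candidate markers"
        )
    if panel_size == candidates.size:
        return candidates.copy()
    lengths = np.asarray(gmap.chrom_lengths_cm, dtype=float)
    raw = panel_size * lengths / lengths.sum()
    alloc = np.floor(raw).astype(int)
    remainder = np.argsort(-(raw - alloc), kind="stable")
    for i in range(panel_size - alloc.sum()):
        alloc[remainder[i % len(remainder)]] += 1
    chrom_of = gmap.locus_chromosome()
    pos_global = gmap.global_positions()
    chosen: list[np.ndarray] = []
    for c in range(gmap.n_chromosomes):
        cand_c = candidates[chrom_of[candidates] == c]
        k = min(alloc[c], cand_c.size)
        if k == 0:
            continue
        pos_c = pos_global[cand_c]
        grid = (np.arange(k) + rng.uniform()) / k * lengths[c]
        nearest = np.searchsorted(pos_c, grid)
        nearest = np.clip(nearest, 0, pos_c.size - 1)
        left = np.clip(nearest - 1, 0, pos_c.size - 1)
        nearest = np.where(
            np.abs(pos_c[left] - grid) < np.abs(pos_c[nearest] - grid), left, nearest
        )
        picked = np.unique(nearest)
        if picked.size < k:  # grid collisions: fill with random unused candidates
            unused = np.setdiff1d(np.arange(cand_c.size), picked)
            fill = rng.choice(unused, size=k - picked.size, replace=False)
            picked = np.sort(np.concatenate([picked, fill]))
        chosen.append(cand_c[picked])
    return np.sort(np.concatenate(chosen))


def genotype(
    individuals: Sequence[Individual],
    marker_index: np.ndarray,
    platform: Platform,
    rng: np.random.Generator,
    prior: str = "hw",
) -> GenotypeMatrix:
    """Simulate GBS reads and return posterior-mean dosages.

    ``prior='hw'`` uses Hardy-Weinberg at the current-population allele
    frequency (the default, and what the pipeline uses); ``prior='flat'``
    weights the three genotypes equally, useful for depth-model diagnostics.
    """
    if not individuals:
        raise ValueError("cannot genotype an empty individual list")
    true_g = np.stack([ind.dosage(marker_index) for ind in individuals]).astype(np.int8)
    n, m = true_g.shape
    q = true_g.mean(axis=0) / 2.0  # allele-1 frequency in this population
    e = max(platform.error_rate, 1e-12)
    p_read = np.array([e, 0.5, 1.0 - e])  # P(read allele 1 | genotype)
    reads = rng.poisson(platform.coverage, size=(n, m))
    alt = rng.binomial(reads, p_read[true_g])
    ref = reads - alt
    log_p = np.log(p_read)
    log_q = np.log1p(-p_read)
    # log-likelihood of each genotype class, (n, m, 3)
    loglik = alt[..., None] * log_p + ref[..., None] * log_q
    if prior == "hw":
        pri = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
        pri = np.broadcast_to(pri, (n, m, 3))
    elif prior == "flat":
        pri = np.full((n, m, 3), 1.0 / 3.0)
    else:
        raise ValueError(f"unknown prior {prior!r}")
    loglik -= loglik.max(axis=-1, keepdims=True)
    w = np.exp(loglik) * pri
    wsum = w.sum(axis=-1)
    # monomorphic loci with a zero-prior truth class cannot occur: the prior
    # comes from the same population as the reads
    dos = (w[..., 1] + 2.0 * w[..., 2]) / wsum
    missing = reads == 0
    dos[missing] = np.broadcast_to(2.0 * q, (n, m))[missing]
    return GenotypeMatrix(
        dosages=dos, missing=missing, marker_index=marker_index, platform=platform
    )
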