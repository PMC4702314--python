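"""Stage metrics: normalized merit, prediction accuracy, segment kinship with
the elite hybrid, heterozygosity, and response in genetic standard deviations.

Merit is on the landrace-to-elite scale: the landrace population mean maps to
0 and the elite hybrid to 1. Kinship is the proportion of 1 cM genome bins
whose founder-origin labels are identical between a germplasm haplotype and an
elite-hybrid haplotype, averaged over the four haplotype pairs, all bins, and
all individuals - exact identity by descent, computed from origin tracks. A
sequence-identity (IBS) mode is available for comparison; IBS inflates kinship
when the founder population is small because unrelated copies of the same
haplotype look identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import GenomeMap, Individual, OriginTrack

__all__ = [
    "MeritScale",
    "normalized_merit",
    "accuracy",
    "accession_accuracy",
    "segment_kinship",
    "heterozygosity",
    "response_in_gsd",
    "DEFAULT_SEASONS",
]

#: seasons to complete discovery + improvement with each approach, used only
#: by the reporting helper (two extra seasons for the doubled-haploid step)
DEFAULT_SEASONS = {"Landrace": 6, "LandraceDH": 9, "LandraceElite": 6}


@dataclass(frozen=True)
class MeritScale:
    landrace_mean_tbv: float
    elite_tbv: float

    def __post_init__(self) -> None:
        if self.elite_tbv == self.landrace_mean_tbv:
            raise ValueError("elite TBV equals landrace mean: merit scale undefined")


def normalized_merit(tbvs: np.ndarray | float, scale: MeritScale) -> float:
    """(mean TBV - landrace mean) / (elite TBV - landrace mean)."""
    mean_tbv = float(np.mean(tbvs))
    return (mean_tbv - scale.landrace_mean_tbv) / (
        scale.elite_tbv - scale.landrace_mean_tbv
    )


def accuracy(ebvs: np.ndarray, tbvs: np.ndarray) -> float:
    """Pearson correlation between EBV and TBV; NaN when undefined."""
    ebvs = np.asarray(ebvs, dtype=float)
    tbvs = np.asarray(tbvs, dtype=float)
    if ebvs.size < 3 or np.std(ebvs) == 0 or np.std(tbvs) == 0:
        return float("nan")
    return float(np.corrcoef(ebvs, tbvs)[0, 1])


def accession_accuracy(
    mean_ebv_per_accession: np.ndarray, mean_tbv_per_accession: np.ndarray
) -> float:
    """Correlation across accessions between mean EBV of the training seeds
    and mean TBV of the accession's seed pool."""
    return accuracy(mean_ebv_per_accession, mean_tbv_per_accession)


def _bin_identity(
    track_a: OriginTrack, track_b: OriginTrack, length_cm: float, segment_cm: float
) -> np.ndarray:
    """Per-bin flag: founder-origin labels identical across the *whole* bin."""
    n_bins = int(np.ceil(length_cm / segment_cm))
    s_a, i_a = track_a
    s_b, i_b = track_b
    if i_a.size == 1 and i_b.size == 1:
        return np.full(n_bins, i_a[0] == i_b[0])
    bp = np.union1d(s_a, s_b)
    a = i_a[np.searchsorted(s_a, bp, side="right") - 1]
    b = i_b[np.searchsorted(s_b, bp, side="right") - 1]
    bad = a != b
    if not bad.any():
        return np.ones(n_bins, dtype=bool)
    starts = bp[bad]
    ends = np.append(bp[1:], length_cm)[bad]
    lo = np.floor(starts / segment_cm).astype(np.int64)
    hi = np.minimum(np.ceil(ends / segment_cm).astype(np.int64), n_bins)
    cover = np.zeros(n_bins + 1, dtype=np.int64)
    np.add.at(cover, lo, 1)
    np.add.at(cover, hi, -1)
    return np.cumsum(cover[:-1]) == 0


def _ibs_bin_identity(
    hap_a: np.ndarray, hap_b: np.ndarray, bin_of_locus: np.ndarray, n_bins: int
) -> np.ndarray:
    ok = np.ones(n_bins, dtype=bool)
    diff = hap_a != hap_b
    if diff.any():
        ok[np.unique(bin_of_locus[diff])] = False
    return ok


def segment_kinship(
    germplasm: Sequence[Individual],
    elite_hybrid: Individual,
    gmap: GenomeMap,
    segment_cm: float = 1.0,
    mode: str = "ibd",
) -> float:
    """Proportion of ``segment_cm`` genome bins identical with the elite hybrid.

    Averages the identity indicator over all four (germplasm haplotype, elite
    haplotype) pairs, all bins of all chromosomes, and all individuals.
    """
    if segment_cm <= 0:
        raise ValueError("segment_cm must be positive")
    if mode not in ("ibd", "ibs"):
        raise ValueError("mode must be 'ibd' or 'ibs'")
    if not germplasm:
        raise ValueError("empty germplasm")
    lengths = np.asarray(gmap.chrom_lengths_cm, dtype=float)
    if mode == "ibs":
        bins_per_chrom = np.ceil(lengths / segment_cm).astype(int)
        bin_of = [
            np.minimum(
                (gmap.positions_cm[c] / segment_cm).astype(int), bins_per_chrom[c] - 1
            )
            for c in range(gmap.n_chromosomes)
        ]
    total = 0.0
    count = 0
    for ind in germplasm:
        for h in range(2):
            for he in range(2):
                for c in range(gmap.n_chromosomes):
                    if mode == "ibd":
                        ok = _bin_identity(
                            ind.origins[h][c],
                            elite_hybrid.origins[he][c],
                            lengths[c],
                            segment_cm,
                        )
                    else:
                        sl = gmap.chrom_slice(c)
                        ok = _ibs_bin_identity(
                            ind.haplotypes[h, sl],
                            elite_hybrid.haplotypes[he, sl],
                            bin_of[c],
                            int(np.ceil(lengths[c] / segment_cm)),
                        )
                    total += ok.sum()
                    count += ok.size
    return total / count


def heterozygosity(
    germplasm: Sequence[Individual], segregating_sites: np.ndarray
) -> float:
    """Mean heterozygosity over individuals at the frozen segregating-site set."""
    if not germplasm:
        raise ValueError("empty germplasm")
    if segregating_sites.size == 0:
        raise ValueError("empty segregating-site set")
    return float(
        np.mean([ind.heterozygosity(segregating_sites) for ind in germplasm])
    )


def response_in_gsd(
    final_mean_tbv: float,
    landrace_mean_tbv: float,
    landrace_sd_tbv: float,
    n_seasons: float,
) -> tuple[float, float]:
    """Response to selection in landrace genetic standard deviations, total
    and per season."""
    if landrace_sd_tbv <= 0:
        raise ValueError("landrace genetic SD must be positive")
    if n_seasons <= 0:
        raise ValueError("n_seasons must be positive")
    total = (final_mean_tbv - landrace_mean_tbv) / landrace_sd_tbv
    return total, total / n_seasons
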