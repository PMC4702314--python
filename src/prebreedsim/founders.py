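"""Founder diversity, landrace accessions, and the elite hybrid.

Founder haplotypes come from a neutral coalescent with recombination (one
independent msprime simulation per chromosome) at the scenario's effective
population size. Landrace accessions are founded from small random subsets of
founder haplotypes and brought to a target inbreeding coefficient by partial
selfing. The elite hybrid is the F1 of two inbreds produced by truncation
selection on TBV inside two separate closed sub-populations, so its genome is
enriched for favorable QTL alleles in its own marker phase - the feature that
drives prediction-accuracy breakdown when elite and landrace genomes mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .genome import (
    GenomeMap,
    GenomeParams,
    HaplotypePanel,
    Individual,
    single_segment_track,
)
from .meiosis import cross, make_dh
from .trait import TraitArchitecture, tbv, tbv_many

__all__ = [
    "LandraceAccession",
    "ElitePackage",
    "simulate_founders",
    "assign_qtl",
    "found_landraces",
    "breed_elite",
    "estimate_inbreeding",
    "panel_individuals",
]

_HARMONIC_CACHE: dict[int, float] = {}


def _harmonic(n: int) -> float:
    if n not in _HARMONIC_CACHE:
        _HARMONIC_CACHE[n] = float(np.sum(1.0 / np.arange(1, n)))
    return _HARMONIC_CACHE[n]


@dataclass
class LandraceAccession:
    """An open-pollinated accession: a seed pool with realized inbreeding."""

    accession_id: int
    members: list[Individual]
    realized_F: float
    founder_rows: np.ndarray  # rows of the panel this accession was founded from


@dataclass
class ElitePackage:
    """Two fully homozygous elite inbreds and their F1 hybrid."""

    elite_inbred_a: Individual
    elite_inbred_b: Individual
    elite_hybrid: Individual


def simulate_founders(
    genome: GenomeParams,
    Ne: float,
    n_haplotypes: int,
    rng_seed: int,
) -> tuple[GenomeMap, HaplotypePanel]:
    """Coalescent-with-recombination founder sample, thinned to the locus budget.

    Returns the genome map (locus positions are the retained segregating
    sites) together with the haplotype panel; allele 0 is ancestral.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 founder haplotypes")
    L_bp = genome.bp_per_chromosome
    budget = genome.loci_per_chromosome
    positions: list[np.ndarray] = []
    columns: list[np.ndarray] = []
    source_sites: list[int] = []
    for c in range(genome.n_chromosomes):
        length_m = genome.chrom_length_cm / 100.0
        r_bp = length_m / L_bp
        if genome.mutation_rate is not None:
            mu = genome.mutation_rate
        else:
            # expected sites passing the MAF filter ~ theta * ln((1-maf)/maf)
            # (frequency-spectrum tail sum); oversample ~2x for safety
            if genome.maf_min > 0:
                a_eff = float(np.log((1.0 - genome.maf_min) / genome.maf_min))
            else:
                a_eff = _harmonic(n_haplotypes)
            # theta = 2*Ne*mu per bp: Ne counts haploid founder lineages here
            mu = 2.0 * budget / (2.0 * Ne * L_bp * a_eff)
        child = np.random.SeedSequence([rng_seed, c])
        s_anc, s_mut = (int(v % (2**31 - 2)) + 1 for v in child.generate_state(2))
        ts = msprime.sim_ancestry(
            samples=n_haplotypes,
            ploidy=1,
            population_size=Ne,
            recombination_rate=r_bp,
            sequence_length=L_bp,
            random_seed=s_anc,
        )
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=s_mut, discrete_genome=False
        )
        geno = mts.genotype_matrix()  # sites x haplotypes
        pos_bp = np.array([s.position for s in mts.sites()])
        biallelic = np.all((geno == 0) | (geno == 1), axis=1)
        freq = geno.mean(axis=1)
        keep = biallelic & (freq >= genome.maf_min) & (freq <= 1.0 - genome.maf_min)
        geno, pos_bp = geno[keep], pos_bp[keep]
        n_sites = geno.shape[0]
        source_sites.append(n_sites)
        if n_sites < budget:
            raise RuntimeError(
                f"chromosome {c}: only {n_sites} usable segregating sites for a "
                f"budget of {budget} (Ne={Ne}, mu={mu:.3g}); raise the mutation "
                "rate or lower the locus budget"
            )
        idx = np.unique(np.round(np.linspace(0, n_sites - 1, budget)).astype(int))
        if idx.size < budget:  # fill rounding collisions from unused sites
            extra = np.setdiff1d(np.arange(n_sites), idx)[: budget - idx.size]
            idx = np.sort(np.concatenate([idx, extra]))
        positions.append(pos_bp[idx] / L_bp * genome.chrom_length_cm)
        columns.append(geno[idx].T.astype(np.int8))
    gmap = GenomeMap(
        chrom_lengths_cm=genome.chrom_lengths_cm, positions_cm=positions
    )
    panel = HaplotypePanel(
        haplotypes=np.concatenate(columns, axis=1),
        founder_ids=np.arange(n_haplotypes, dtype=np.int32),
        Ne=float(Ne),
        n_source_sites=tuple(source_sites),
    )
    return gmap, panel


def assign_qtl(gmap: GenomeMap, n_qtl: int, rng: np.random.Generator) -> GenomeMap:
    """Designate a random subset of loci as QTL-eligible; the rest become
    candidate markers. Mutates and returns the map."""
    n_loci = gmap.n_loci
    if n_qtl >= n_loci:
        raise ValueError("n_qtl must leave room for candidate markers")
    qtl = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
    gmap.qtl_index = qtl
    gmap.candidate_marker_index = np.setdiff1d(np.arange(n_loci), qtl)
    return gmap


def _panel_individual(
    panel: HaplotypePanel, rows: np.ndarray, gmap: GenomeMap, role: str
) -> Individual:
    return Individual(
        haplotypes=panel.haplotypes[rows].copy(),
        origins=[
            single_segment_track(int(panel.founder_ids[rows[0]]), gmap.n_chromosomes),
            single_segment_track(int(panel.founder_ids[rows[1]]), gmap.n_chromosomes),
        ],
        role=role,
    )


def panel_individuals(
    panel: HaplotypePanel, gmap: GenomeMap, rng: np.random.Generator, n: int
) -> list[Individual]:
    """Random diploids assembled from distinct panel haplotypes."""
    out = []
    for _ in range(n):
        rows = rng.choice(panel.n_haplotypes, size=2, replace=False)
        out.append(_panel_individual(panel, rows, gmap, role="founder"))
    return out


def estimate_inbreeding(members: list[Individual]) -> float:
    """F-hat = 1 - Hobs/Hexp from excess homozygosity over within-pool
    allele frequencies (small-sample corrected expected heterozygosity)."""
    haps = np.concatenate([m.haplotypes for m in members], axis=0).astype(np.float64)
    n2 = haps.shape[0]
    p = haps.mean(axis=0)
    seg = (p > 0) & (p < 1)
    if not np.any(seg):
        return 1.0
    h_exp = 2.0 * p[seg] * (1.0 - p[seg]) * n2 / (n2 - 1)
    het = np.stack([m.haplotypes[0][seg] != m.haplotypes[1][seg] for m in members])
    h_obs = het.mean(axis=0)
    return float(1.0 - h_obs.sum() / h_exp.sum())


def _generations_to_target(target_F: float, f0: float, s: float, cap: int) -> int:
    """Smallest g with |F_g - target| <= 0.01 under F_{t+1} = s/2 (1 + F_t)."""
    f = f0
    for g in range(cap + 1):
        if abs(f - target_F) <= 0.01:
            return g
        f = s / 2.0 * (1.0 + f)
    raise RuntimeError(
        f"target F={target_F} unreachable within {cap} generations "
        f"(analytic F after cap: {f:.3f})"
    )


def found_landraces(
    panel: HaplotypePanel,
    gmap: GenomeMap,
    n_landraces: int,
    target_F: float,
    pool_size: int,
    rng_seed_or_rng: int | np.random.Generator,
    n_founder_haplotypes: int = 4,
    max_generations: int = 20,
) -> list[LandraceAccession]:
    """Found accessions from small founder subsets, then partially self to F.

    The per-generation selfing probability s = 2F/(1+F) gives equilibrium
    inbreeding F; the number of generations is the analytic requirement to get
    within 0.01 of the target, capped at ``max_generations``.
    """
    if n_landraces < 1:
        raise ValueError("n_landraces must be >= 1")
    if not 0.0 <= target_F < 1.0:
        raise ValueError("target_F must be in [0, 1)")
    rng = (
        rng_seed_or_rng
        if isinstance(rng_seed_or_rng, np.random.Generator)
        else np.random.default_rng(rng_seed_or_rng)
    )
    s = 2.0 * target_F / (1.0 + target_F)
    f0 = -1.0 / (n_founder_haplotypes - 1)  # distinct-pair founding excess het
    n_gen = _generations_to_target(target_F, f0, s, max_generations)
    if target_F == 0.0:
        n_gen = max(n_gen, 1)  # one round of outcrossing mixes the founders
    accessions = []
    for a in range(n_landraces):
        rows = rng.choice(panel.n_haplotypes, size=n_founder_haplotypes, replace=False)
        pool = []
        for _ in range(pool_size):
            pair = rng.choice(rows, size=2, replace=False)
            pool.append(_panel_individual(panel, pair, gmap, role="landrace seed"))
        for _ in range(n_gen):
            nxt = []
            for _ in range(pool_size):
                if rng.random() < s:
                    p = pool[int(rng.integers(len(pool)))]
                    nxt.append(cross(p, p, gmap, rng, role="landrace seed"))
                else:
                    i, j = rng.choice(len(pool), size=2, replace=False)
                    nxt.append(cross(pool[i], pool[j], gmap, rng, role="landrace seed"))
            pool = nxt
        accessions.append(
            LandraceAccession(
                accession_id=a,
                members=pool,
                realized_F=estimate_inbreeding(pool),
                founder_rows=rows,
            )
        )
    return accessions


def breed_elite(
    panel: HaplotypePanel,
    gmap: GenomeMap,
    trait: TraitArchitecture,
    rng_seed_or_rng: int | np.random.Generator,
    subpop_size: int = 50,
    n_selection_generations: int = 5,
    top_fraction: float = 0.1,
    n_dh_candidates: int = 10,
    reference_mean_tbv: float | None = None,
    reference_sd_tbv: float | None = None,
    target_gap_sd: float | None = 16.8,
    max_generations: int = 60,
) -> ElitePackage:
    """Breed the elite hybrid by truncation selection on TBV in two closed
    sub-populations, fixed via doubled haploids and crossed.

    ``n_selection_generations`` is the minimum; selection continues until the
    prospective hybrid sits ``target_gap_sd`` landrace genetic standard
    deviations above the landrace mean (or ``max_generations`` is hit). The
    default gap of 16.8 SD is the superiority a landrace-normalized merit of
    1 corresponds to on the genetic-standard-deviation scale of this design.
    Raises if the hybrid's TBV fails to exceed the landrace reference mean.
    """
    rng = (
        rng_seed_or_rng
        if isinstance(rng_seed_or_rng, np.random.Generator)
        else np.random.default_rng(rng_seed_or_rng)
    )
    all_rows = rng.permutation(panel.n_haplotypes)
    if panel.n_haplotypes < 4 * subpop_size:
        raise ValueError("panel too small for two closed elite sub-populations")
    if reference_mean_tbv is None or reference_sd_tbv is None:
        ref_inds = panel_individuals(panel, gmap, rng, 200)
        ref_tbvs = tbv_many(ref_inds, trait)
        if reference_mean_tbv is None:
            reference_mean_tbv = float(ref_tbvs.mean())
        if reference_sd_tbv is None:
            reference_sd_tbv = float(ref_tbvs.std())
    target = (
        reference_mean_tbv + target_gap_sd * reference_sd_tbv
        if target_gap_sd is not None
        else None
    )

    def init_subpop(rows: np.ndarray) -> list[Individual]:
        return [
            _panel_individual(panel, rows[2 * i : 2 * i + 2], gmap, role="elite")
            for i in range(subpop_size)
        ]

    def advance(pop: list[Individual]) -> list[Individual]:
        tbvs = tbv_many(pop, trait)
        k = max(2, int(round(top_fraction * len(pop))))
        parents = [pop[i] for i in np.argsort(-tbvs, kind="stable")[:k]]
        nxt = []
        for _ in range(subpop_size):
            i, j = rng.choice(k, size=2, replace=False)
            nxt.append(cross(parents[i], parents[j], gmap, rng, role="elite"))
        return nxt

    pop_a = init_subpop(all_rows[: 2 * subpop_size])
    pop_b = init_subpop(all_rows[2 * subpop_size : 4 * subpop_size])
    gen = 0
    while True:
        pop_a, pop_b = advance(pop_a), advance(pop_b)
        gen += 1
        if gen < n_selection_generations:
            continue
        if target is None or gen >= max_generations:
            break
        # prospective hybrid ~ mid-parent of the two sub-population leaders
        best = 0.5 * (max(tbv_many(pop_a, trait)) + max(tbv_many(pop_b, trait)))
        if best >= target:
            break

    def fix(pop: list[Individual]) -> Individual:
        best = pop[int(np.argmax(tbv_many(pop, trait)))]
        dhs = [
            make_dh(best, gmap, rng, role="elite inbred")
            for _ in range(n_dh_candidates)
        ]
        return dhs[int(np.argmax(tbv_many(dhs, trait)))]

    inbred_a, inbred_b = fix(pop_a), fix(pop_b)
    hybrid = cross(inbred_a, inbred_b, gmap, rng, role="elite hybrid")
    if tbv(hybrid, trait) <= reference_mean_tbv:
        raise RuntimeError(
            "elite selection failed to exceed the landrace mean TBV; raise "
            "selection intensity or the number of generations"
        )
    return ElitePackage(inbred_a, inbred_b, hybrid)
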