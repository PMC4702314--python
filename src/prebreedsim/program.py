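"""The pre-breeding program: discovery (stages T, A, S) and improvement (C1-C4).

Discovery trains a genomic prediction equation on a landrace x elite testcross
population (stage T), selects the best accessions by mean EBV (stage A), and
selects the 10 best seeds from fresh seeds of the selected accessions with at
most one seed per accession (stage S), under one of three initiation
approaches: keep the selected landrace seeds (Landrace), their best doubled
haploids (LandraceDH), or the selected landrace x elite testcross seeds
(LandraceElite). Improvement random-mates the 10 plants into a synthetic
population for four cycles, selecting the 10 best of 100 genotyped seeds per
cycle by EBV; optionally a sample of the remaining seeds is testcrossed and
phenotyped to retrain the equation, which becomes usable only in the next
cycle (testcross phenotypes take two seasons to collect).

``run_grid`` executes any subset of the 3,456-scenario factorial with
replication, sharing the simulated world across scenarios that only differ in
logistics, and returns a tidy stage-record table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .founders import (
    ElitePackage,
    LandraceAccession,
    assign_qtl,
    breed_elite,
    found_landraces,
    simulate_founders,
)
from .gbs import PLATFORM_PRESETS, GenotypeMatrix, Platform, genotype, select_marker_panel
from .genome import GenomeMap, GenomeParams, HaplotypePanel, Individual
from .meiosis import cross, make_dh, random_mate
from .metrics import (
    MeritScale,
    accession_accuracy,
    accuracy,
    heterozygosity,
    normalized_merit,
    segment_kinship,
)
from .prediction import PredictionEquation, predict_ebv, retrain_on_cycle, train_ridge
from .trait import TraitArchitecture, sample_trait, tbv, tbv_many, testcross_phenotypes

__all__ = [
    "APPROACHES",
    "FACTOR_LEVELS",
    "STAGES",
    "Scenario",
    "StageRecord",
    "SimSettings",
    "World",
    "full_grid",
    "build_world",
    "run_discovery",
    "run_improvement",
    "run_grid",
]

APPROACHES = ("Landrace", "LandraceDH", "LandraceElite")
STAGES = ("T", "A", "S", "C1", "C2", "C3", "C4")

#: the full-scale factorial: 3 x 2 x 2 x 2 x 2 x 3 x 2 x 3 x 4 = 3,456
FACTOR_LEVELS = {
    "approach": list(APPROACHES),
    "Ne": [1000, 100_000],
    "F": [0.3, 0.9],
    "h2": [0.25, 0.50],
    "platform": ["GBS10x@10K", "GBS1x@100K"],
    "seeds_per_landrace": [1, 3, 5],
    "n_selected_landraces": [40, 80],
    "tested_seeds_per_landrace": [10, 20, 40],
    "n_synthetic_phenotypes": [0, 20, 40, 60],
}


@dataclass(frozen=True)
class Scenario:
    approach: str
    Ne: int
    F: float
    h2: float
    platform: str
    seeds_per_landrace: int
    n_selected_landraces: int
    tested_seeds_per_landrace: int
    n_synthetic_phenotypes: int

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if not 0 <= self.F < 1:
            raise ValueError("F must be in [0, 1)")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        for f in (
            "seeds_per_landrace",
            "n_selected_landraces",
            "tested_seeds_per_landrace",
        ):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.n_synthetic_phenotypes < 0:
            raise ValueError("n_synthetic_phenotypes must be >= 0")

    @property
    def scenario_id(self) -> str:
        return (
            f"{self.approach}|Ne{self.Ne}|F{self.F}|h{self.h2}|{self.platform}"
            f"|s{self.seeds_per_landrace}|L{self.n_selected_landraces}"
            f"|t{self.tested_seeds_per_landrace}|p{self.n_synthetic_phenotypes}"
        )


def full_grid(levels: dict | None = None) -> list[Scenario]:
    """Enumerate the factorial grid (the full-scale grid by default)."""
    lv = dict(FACTOR_LEVELS)
    if levels:
        lv.update(levels)
    keys = list(FACTOR_LEVELS)
    return [
        Scenario(**dict(zip(keys, combo)))
        for combo in itertools.product(*(lv[k] for k in keys))
    ]


@dataclass(frozen=True)
class SimSettings:
    """Everything about the simulated world that is not a design factor.

    Field values are *effective* sizes, defaulting to the full-scale study
    conditions. :meth:`at_scale` derives desk-scale settings that shrink
    population sizes (accessions, marker panels, founder panel, QTL count)
    proportionally while preserving every ratio and factor level.
    """

    n_accessions: int = 3000
    pool_size: int = 50
    n_founder_haplotypes: int = 4
    max_landrace_generations: int = 20
    panel_haplotypes: int = 1000
    n_qtl: int = 1000
    n_chromosomes: int = 10
    chrom_length_cm: float = 200.0
    maf_min: float = 0.05
    mutation_rate: float | None = None
    loci_per_chromosome: int | None = None  # None -> computed from panels + QTL
    platform_markers: tuple[tuple[str, int], ...] = (
        ("GBS10x@10K", 10_000),
        ("GBS1x@100K", 100_000),
    )
    gbs_error_rate: float = 0.005
    dh_candidates: int = 10
    elite_subpop_size: int = 50
    elite_generations: int = 5
    elite_top_fraction: float = 0.1
    elite_gap_sd: float | None = 16.8
    kinship_mode: str = "ibd"
    segment_cm: float = 1.0
    n_final_selected: int = 10
    n_cycles: int = 4
    synthetic_seeds_per_plant: int = 10
    scale: float = 1.0  # provenance: the scale these settings were derived at

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    @classmethod
    def at_scale(cls, scale: float, **overrides) -> "SimSettings":
        """Full-scale study conditions shrunk by ``scale`` (with small floors
        so toy runs stay well-defined); explicit overrides win."""
        base = cls()
        derived = dict(
            n_accessions=max(20, round(base.n_accessions * scale)),
            n_qtl=max(20, round(base.n_qtl * scale)),
            panel_haplotypes=max(200, round(base.panel_haplotypes * scale)),
            platform_markers=tuple(
                (name, max(40, round(m * scale))) for name, m in base.platform_markers
            ),
            scale=scale,
        )
        derived.update(overrides)
        return cls(**derived)

    def platform(self, name: str) -> Platform:
        markers = dict(self.platform_markers)
        if name not in PLATFORM_PRESETS or name not in markers:
            raise ValueError(f"unknown platform {name!r}")
        return Platform(
            name=name,
            n_markers=markers[name],
            coverage=PLATFORM_PRESETS[name]["coverage"],
            error_rate=self.gbs_error_rate,
        )

    def genome_params(self) -> GenomeParams:
        if self.loci_per_chromosome is not None:
            budget = self.loci_per_chromosome
        else:
            max_markers = max(m for _, m in self.platform_markers)
            budget = int(
                np.ceil((1.25 * max_markers + self.n_qtl) / self.n_chromosomes)
            )
        return GenomeParams(
            n_chromosomes=self.n_chromosomes,
            chrom_length_cm=self.chrom_length_cm,
            loci_per_chromosome=budget,
            maf_min=self.maf_min,
            bp_per_chromosome=1_000_000,
            mutation_rate=self.mutation_rate,
        )

    def validate_scenario(self, scenario: Scenario) -> None:
        """Fail before simulation on inconsistent factor levels."""
        self.platform(scenario.platform)
        need = scenario.seeds_per_landrace + scenario.tested_seeds_per_landrace
        if need > self.pool_size:
            raise ValueError(
                f"pool_size={self.pool_size} cannot supply "
                f"{scenario.seeds_per_landrace} training + "
                f"{scenario.tested_seeds_per_landrace} tested seeds per accession"
            )
        if scenario.n_selected_landraces > self.n_accessions:
            raise ValueError("more selected landraces than accessions")
        if scenario.n_selected_landraces < self.n_final_selected:
            raise ValueError(
                "need at least n_final_selected accessions to place one seed each"
            )


@dataclass
class World:
    """One replicate's simulated universe, shared across design scenarios."""

    settings: SimSettings
    Ne: int
    F: float
    gmap: GenomeMap
    panel: HaplotypePanel
    accessions: list[LandraceAccession]
    elite: ElitePackage
    trait: TraitArchitecture
    merit_scale: MeritScale
    segregating_sites: np.ndarray
    landrace_mean_tbv: float
    landrace_sd_tbv: float
    marker_panels: dict = field(default_factory=dict)

    def marker_panel(self, platform_name: str) -> np.ndarray:
        if platform_name not in self.marker_panels:
            plat = self.settings.platform(platform_name)
            rng = np.random.default_rng(
                np.random.SeedSequence([self.Ne, int(self.F * 1000), plat.n_markers])
            )
            self.marker_panels[platform_name] = select_marker_panel(
                self.gmap, plat.n_markers, rng
            )
        return self.marker_panels[platform_name]


def _seed(*ints: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(i) for i in ints])


def build_world(settings: SimSettings, Ne: int, F: float, seed: int) -> World:
    """Simulate founders, landrace accessions, trait, and the elite hybrid."""
    base = _seed(seed, Ne, int(F * 1000))
    s_found, s_qtl, s_trait, s_land, s_elite = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in base.spawn(5)
    )
    gmap, panel = simulate_founders(
        settings.genome_params(), Ne, settings.panel_haplotypes, s_found
    )
    assign_qtl(gmap, settings.n_qtl, np.random.default_rng(s_qtl))
    trait = sample_trait(gmap, settings.n_qtl, np.random.default_rng(s_trait))
    accessions = found_landraces(
        panel,
        gmap,
        settings.n_accessions,
        F,
        settings.pool_size,
        np.random.default_rng(s_land),
        n_founder_haplotypes=settings.n_founder_haplotypes,
        max_generations=settings.max_landrace_generations,
    )
    all_members = [m for a in accessions for m in a.members]
    tbvs = tbv_many(all_members, trait)
    landrace_mean = float(tbvs.mean())
    landrace_sd = float(tbvs.std())
    elite = breed_elite(
        panel,
        gmap,
        trait,
        np.random.default_rng(s_elite),
        subpop_size=settings.elite_subpop_size,
        n_selection_generations=settings.elite_generations,
        top_fraction=settings.elite_top_fraction,
        n_dh_candidates=settings.dh_candidates,
        reference_mean_tbv=landrace_mean,
        reference_sd_tbv=landrace_sd,
        target_gap_sd=settings.elite_gap_sd,
    )
    # segregating sites are frozen at simulation start: polymorphic across the
    # initial landrace accessions
    counts = np.zeros(gmap.n_loci, dtype=np.int64)
    n_haps = 0
    for m in all_members:
        counts += m.haplotypes[0]
        counts += m.haplotypes[1]
        n_haps += 2
    seg = np.flatnonzero((counts > 0) & (counts < n_haps))
    return World(
        settings=settings,
        Ne=Ne,
        F=F,
        gmap=gmap,
        panel=panel,
        accessions=accessions,
        elite=elite,
        trait=trait,
        merit_scale=MeritScale(landrace_mean, tbv(elite.elite_hybrid, trait)),
        segregating_sites=seg,
        landrace_mean_tbv=landrace_mean,
        landrace_sd_tbv=landrace_sd,
    )


@dataclass
class StageRecord:
    scenario_id: str
    replicate: int
    stage: str
    merit: float
    accuracy: float
    kinship_with_elite: float
    heterozygosity: float

    def to_row(self, scenario: Scenario) -> dict:
        row = {
            "scenario_id": self.scenario_id,
            "replicate": self.replicate,
            "stage": self.stage,
            **{k: getattr(scenario, k) for k in FACTOR_LEVELS},
            "merit": self.merit,
            "accuracy": self.accuracy,
            "kinship_with_elite": self.kinship_with_elite,
            "heterozygosity": self.heterozygosity,
        }
        return row


def _metrics(
    world: World,
    germplasm: Sequence[Individual],
    acc_value: float,
) -> tuple[float, float, float, float]:
    s = world.settings
    return (
        normalized_merit(tbv_many(germplasm, world.trait), world.merit_scale),
        acc_value,
        segment_kinship(
            germplasm,
            world.elite.elite_hybrid,
            world.gmap,
            segment_cm=s.segment_cm,
            mode=s.kinship_mode,
        ),
        heterozygosity(germplasm, world.segregating_sites),
    )


@dataclass
class _DiscoveryCore:
    """Approach-independent part of discovery: stages T and A."""

    eq: PredictionEquation
    sigma2_e: float
    platform: Platform
    panel_idx: np.ndarray
    training_idx: list[np.ndarray]  # per accession, member indices used in training
    selected_accessions: list[int]
    record_T: tuple[float, float, float, float]
    record_A: tuple[float, float, float, float]


def _discovery_core(
    world: World,
    h2: float,
    platform_name: str,
    seeds_per: int,
    n_selected: int,
    rng: np.random.Generator,
) -> _DiscoveryCore:
    s = world.settings
    plat = s.platform(platform_name)
    panel_idx = world.marker_panel(platform_name)
    training_idx: list[np.ndarray] = []
    training_seeds: list[Individual] = []
    for acc in world.accessions:
        idx = rng.choice(len(acc.members), size=seeds_per, replace=False)
        training_idx.append(idx)
        training_seeds.extend(acc.members[i] for i in idx)
    G = genotype(training_seeds, panel_idx, plat, rng)
    _, phen_records, sigma2_e = testcross_phenotypes(
        training_seeds, world.elite.elite_hybrid, world.trait, h2, world.gmap, rng,
        stage="T",
    )
    y = np.array([r.value for r in phen_records])
    eq = train_ridge(G, y, h2)
    ebv_train = predict_ebv(eq, G)
    tbv_train = tbv_many(training_seeds, world.trait)
    rec_T = _metrics(world, training_seeds, accuracy(ebv_train, tbv_train))

    # stage A: rank accessions by mean EBV of their training seeds
    n_acc = len(world.accessions)
    mean_ebv = ebv_train.reshape(n_acc, seeds_per).mean(axis=1)
    mean_tbv_members = np.array(
        [np.mean(tbv_many(a.members, world.trait)) for a in world.accessions]
    )
    acc_accuracy = accession_accuracy(mean_ebv, mean_tbv_members)
    selected = np.argsort(-mean_ebv, kind="stable")[:n_selected]
    selected_members = [
        m for i in selected for m in world.accessions[int(i)].members
    ]
    rec_A = _metrics(world, selected_members, acc_accuracy)
    return _DiscoveryCore(
        eq=eq,
        sigma2_e=sigma2_e,
        platform=plat,
        panel_idx=panel_idx,
        training_idx=training_idx,
        selected_accessions=[int(i) for i in selected],
        record_T=rec_T,
        record_A=rec_A,
    )


def _select_top_distinct(
    ebvs: np.ndarray, accession_of: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k best by EBV with at most one per accession
    (ties broken by stable index order)."""
    order = np.argsort(-ebvs, kind="stable")
    chosen: list[int] = []
    used: set[int] = set()
    for i in order:
        a = int(accession_of[i])
        if a not in used:
            chosen.append(int(i))
            used.add(a)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise RuntimeError("not enough distinct accessions to select from")
    return np.array(chosen)


def _stage3(
    world: World,
    core: _DiscoveryCore,
    approach: str,
    tested_per: int,
    rng: np.random.Generator,
) -> tuple[list[Individual], tuple[float, float, float, float]]:
    """Stage S: fresh seeds of the selected accessions, best 10 selected with
    at most one per accession, materialized per the initiation approach."""
    s = world.settings
    seeds: list[Individual] = []
    accession_of: list[int] = []
    for rank, ai in enumerate(core.selected_accessions):
        acc = world.accessions[ai]
        unused = np.setdiff1d(
            np.arange(len(acc.members)), core.training_idx[ai]
        )
        pick = rng.choice(unused, size=tested_per, replace=False)
        seeds.extend(acc.members[i] for i in pick)
        accession_of.extend([ai] * tested_per)
    accession_of = np.array(accession_of)

    if approach == "LandraceElite":
        candidates = [
            cross(seed, world.elite.elite_hybrid, world.gmap, rng, role="testcross")
            for seed in seeds
        ]
    else:
        candidates = seeds
    G = genotype(candidates, core.panel_idx, core.platform, rng)
    ebvs = predict_ebv(core.eq, G)
    tbvs = tbv_many(candidates, world.trait)
    sel = _select_top_distinct(ebvs, accession_of, s.n_final_selected)
    units = [candidates[i] for i in sel]
    if approach == "LandraceDH":
        dh_units = []
        for i in sel:
            dhs = [
                make_dh(candidates[i], world.gmap, rng) for _ in range(s.dh_candidates)
            ]
            Gdh = genotype(dhs, core.panel_idx, core.platform, rng)
            dh_units.append(dhs[int(np.argmax(predict_ebv(core.eq, Gdh)))])
        units = dh_units
    rec_S = _metrics(world, units, accuracy(ebvs, tbvs))
    return units, rec_S


def _improvement(
    world: World,
    scenario: Scenario,
    units: list[Individual],
    eq0: PredictionEquation,
    sigma2_e: float,
    core_platform: Platform,
    panel_idx: np.ndarray,
    rng: np.random.Generator,
    equation_trace: list | None = None,
) -> list[tuple[str, tuple[float, float, float, float]]]:
    s = world.settings
    eq = eq0
    plants = units
    out = []
    for cyc in range(1, s.n_cycles + 1):
        if equation_trace is not None:
            equation_trace.append(eq.training_id)
        seeds = random_mate(plants, s.synthetic_seeds_per_plant, world.gmap, rng)
        G = genotype(seeds, panel_idx, core_platform, rng)
        ebvs = predict_ebv(eq, G)
        tbvs = tbv_many(seeds, world.trait)
        order = np.argsort(-ebvs, kind="stable")
        sel = order[: s.n_final_selected]
        selected = [seeds[int(i)] for i in sel]
        out.append((f"C{cyc}", _metrics(world, selected, accuracy(ebvs, tbvs))))
        if scenario.n_synthetic_phenotypes > 0:
            remaining = order[s.n_final_selected :]
            chosen = rng.choice(
                remaining,
                size=min(scenario.n_synthetic_phenotypes, remaining.size),
                replace=False,
            )
            parents = [seeds[int(i)] for i in chosen]
            _, phen_records, _ = testcross_phenotypes(
                parents,
                world.elite.elite_hybrid,
                world.trait,
                scenario.h2,
                world.gmap,
                rng,
                sigma2_e=sigma2_e,
                stage=f"C{cyc}",
            )
            y = np.array([r.value for r in phen_records])
            new_eq = retrain_on_cycle(G.dosages[chosen], y, scenario.h2, cyc)
            if new_eq is not None:
                eq = new_eq  # usable from the next cycle only
        plants = selected
    return out


def run_discovery(
    scenario: Scenario, world: World, rng: np.random.Generator
) -> tuple[list[Individual], PredictionEquation, list[StageRecord], dict]:
    """Run stages T, A, S for one scenario; returns the selected units, the
    discovery prediction equation, the stage records, and run context
    (``sigma2_e``, platform, marker panel) needed by the improvement phase."""
    world.settings.validate_scenario(scenario)
    core = _discovery_core(
        world,
        scenario.h2,
        scenario.platform,
        scenario.seeds_per_landrace,
        scenario.n_selected_landraces,
        rng,
    )
    units, rec_S = _stage3(
        world, core, scenario.approach, scenario.tested_seeds_per_landrace, rng
    )
    records = [
        StageRecord(scenario.scenario_id, 0, st, *rec)
        for st, rec in zip(("T", "A", "S"), (core.record_T, core.record_A, rec_S))
    ]
    context = {
        "sigma2_e": core.sigma2_e,
        "platform": core.platform,
        "panel_idx": core.panel_idx,
    }
    return units, core.eq, records, context


def run_improvement(
    scenario: Scenario,
    starting: list[Individual],
    eq0: PredictionEquation,
    world: World,
    rng: np.random.Generator,
    sigma2_e: float,
    platform: Platform | None = None,
    panel_idx: np.ndarray | None = None,
    equation_trace: list | None = None,
) -> list[StageRecord]:
    """Run cycles C1..C4 from the selected units.

    ``equation_trace``, if given, collects the training_id of the equation
    used for selection in each cycle (shows the one-cycle retraining lag).
    """
    if len(starting) != world.settings.n_final_selected:
        raise ValueError(
            f"improvement starts from exactly {world.settings.n_final_selected} plants"
        )
    plat = platform or world.settings.platform(scenario.platform)
    pidx = panel_idx if panel_idx is not None else world.marker_panel(scenario.platform)
    recs = _improvement(
        world, scenario, starting, eq0, sigma2_e, plat, pidx, rng,
        equation_trace=equation_trace,
    )
    return [
        StageRecord(scenario.scenario_id, 0, st, *rec) for st, rec in recs
    ]


def _rng_from(*ints: int) -> np.random.Generator:
    return np.random.default_rng(_seed(*ints))


def run_grid(
    scenarios: Iterable[Scenario],
    n_replicates: int,
    master_seed: int,
    settings: SimSettings | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run scenarios x replicates and return the tidy stage-record table.

    The world (founders, landraces, trait, elite) is shared across scenarios
    with the same genetic parameters (Ne, F) within a replicate, and the
    training/selection stages are shared where scenarios differ only by
    approach or by the retraining factor. Seeding is value-based, so a
    scenario's records do not depend on which other scenarios are in the grid.
    """
    settings = settings or SimSettings()
    scenarios = list(scenarios)
    ids = [sc.scenario_id for sc in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario ids in grid")
    for sc in scenarios:
        settings.validate_scenario(sc)

    def fkey(F: float) -> int:
        return int(round(F * 1000))

    def hkey(h2: float) -> int:
        return int(round(h2 * 1000))

    rows: list[dict] = []
    world_groups: dict[tuple, list[Scenario]] = {}
    for sc in scenarios:
        world_groups.setdefault((sc.Ne, sc.F), []).append(sc)

    for rep in range(n_replicates):
        for (Ne, F), group in world_groups.items():
            world = build_world(settings, Ne, F, seed=int(_seed(master_seed, 101, rep, Ne, fkey(F)).generate_state(1)[0] % (2**31 - 1)))
            core_groups: dict[tuple, list[Scenario]] = {}
            for sc in group:
                key = (
                    hkey(sc.h2),
                    sc.platform,
                    sc.seeds_per_landrace,
                    sc.n_selected_landraces,
                )
                core_groups.setdefault(key, []).append(sc)
            for (h2k, plat_name, seeds_per, n_sel), sub in core_groups.items():
                core = _discovery_core(
                    world,
                    sub[0].h2,
                    plat_name,
                    seeds_per,
                    n_sel,
                    _rng_from(master_seed, 202, rep, Ne, fkey(F), h2k,
                              PLATFORM_PRESETS[plat_name]['n_markers'], seeds_per, n_sel),
                )
                stage3_groups: dict[tuple, list[Scenario]] = {}
                for sc in sub:
                    stage3_groups.setdefault(
                        (sc.approach, sc.tested_seeds_per_landrace), []
                    ).append(sc)
                for (approach, tested), sub3 in stage3_groups.items():
                    a_idx = APPROACHES.index(approach)
                    units, rec_S = _stage3(
                        world,
                        core,
                        approach,
                        tested,
                        _rng_from(master_seed, 303, rep, Ne, fkey(F), h2k,
                                  PLATFORM_PRESETS[plat_name]['n_markers'], seeds_per, n_sel, a_idx, tested),
                    )
                    for sc in sub3:
                        for st, rec in zip(
                            ("T", "A", "S"),
                            (core.record_T, core.record_A, rec_S),
                        ):
                            rows.append(
                                StageRecord(sc.scenario_id, rep, st, *rec).to_row(sc)
                            )
                        imp = _improvement(
                            world,
                            sc,
                            units,
                            core.eq,
                            core.sigma2_e,
                            core.platform,
                            core.panel_idx,
                            _rng_from(master_seed, 404, rep, Ne, fkey(F), h2k,
                                      PLATFORM_PRESETS[plat_name]['n_markers'], seeds_per, n_sel, a_idx,
                                      tested, sc.n_synthetic_phenotypes),
                        )
                        for st, rec in imp:
                            rows.append(
                                StageRecord(sc.scenario_id, rep, st, *rec).to_row(sc)
                            )
                if progress:
                    print(
                        f"rep {rep} Ne={Ne} F={F} core {plat_name} s{seeds_per} "
                        f"L{n_sel} done",
                        flush=True,
                    )
            del world
    df = pd.DataFrame(rows)
    stage_order = {s: i for i, s in enumerate(STAGES)}
    df = df.sort_values(
        ["scenario_id", "replicate", "stage"],
        key=lambda col: col.map(stage_order) if col.name == "stage" else col,
        kind="stable",
    ).reset_index(drop=True)
    return df
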