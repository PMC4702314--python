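"""Desk-scale study conditions: the scaled-down analogue of the full design.

The full-scale design (3,000 accessions, up to 100,000 markers, founder Ne up
to 100,000) is far beyond a single-CPU session, chiefly because coalescent
cost grows steeply in Ne x map length. These conditions shrink the world by
about one order of magnitude while preserving the design's structure and
ratios:

* 300 accessions, marker panels of 200 (10x) / 2,000 (1x), 100 QTL;
* 10 chromosomes of 0.25 Morgan;
* founder Ne of 1,000 (low diversity) and 10,000 standing in for the
  high-diversity level - the Ne = 100,000 coalescent is intractable at any
  sample size. Ne and chromosome length trade off in coalescent cost, and the
  prediction-breakdown phenomenon needs low marker-QTL linkage (high Ne) more
  than it needs map length, so the desk genome keeps Ne as high as the budget
  allows and shortens the chromosomes instead.

The design-comparison bundle fixes the genetic parameters at the combination
where prediction-accuracy breakdown after elite x landrace mixing is most
pronounced (high founder diversity, F = 0.9, h2 = 0.25) and uses five seeds
per landrace, giving a 1,500-testcross training population (the mid/full
factor level). All scripts, tests, and the acceptance run draw these
conditions from here so they cannot drift apart.
"""

from __future__ import annotations

from dataclasses import replace

from .program import Scenario, SimSettings

__all__ = [
    "DESK_SETTINGS",
    "DESK_NE_LOW",
    "DESK_NE_HIGH",
    "design_bundle",
    "seed_world_settings",
]

DESK_NE_LOW = 1000
DESK_NE_HIGH = 10_000

DESK_SETTINGS = SimSettings(
    n_accessions=300,
    pool_size=16,
    panel_haplotypes=400,
    n_qtl=100,
    n_chromosomes=10,
    chrom_length_cm=25.0,
    platform_markers=(("GBS10x@10K", 200), ("GBS1x@100K", 2000)),
    elite_subpop_size=100,
    elite_top_fraction=0.15,
    scale=0.1,
)

#: genetic parameters of the design-comparison bundle
BUNDLE_GENETICS = dict(Ne=DESK_NE_HIGH, F=0.9, h2=0.25)


def design_bundle() -> list[Scenario]:
    """The approach-comparison scenarios: all three initiation approaches,
    with the full retraining-level range for LandraceElite (its first-cycle
    behavior is the headline phenomenon, and the four retraining arms give
    four independent first-cycle draws per replicate, mirroring how the
    full design averages each approach over its scenarios)."""
    common = dict(
        **BUNDLE_GENETICS,
        platform="GBS1x@100K",
        seeds_per_landrace=5,
        n_selected_landraces=40,
        tested_seeds_per_landrace=10,
    )
    scenarios = [
        Scenario(approach="Landrace", n_synthetic_phenotypes=0, **common),
        Scenario(approach="Landrace", n_synthetic_phenotypes=60, **common),
        Scenario(approach="LandraceDH", n_synthetic_phenotypes=60, **common),
    ]
    scenarios += [
        Scenario(approach="LandraceElite", n_synthetic_phenotypes=n, **common)
        for n in (0, 20, 40, 60)
    ]
    return scenarios


def seed_world_settings() -> SimSettings:
    """Settings for single-world analyses (kinship anchors, F recovery):
    the desk conditions at the cheap low-diversity founder level."""
    return replace(DESK_SETTINGS)
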