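"""Shared fixtures: small simulated worlds, reused across the suite.

Worlds are session-scoped because the founder coalescent is the expensive
step; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from prebreedsim.program import SimSettings, build_world

TINY_SETTINGS = SimSettings(
    n_accessions=40,
    pool_size=40,
    panel_haplotypes=200,
    n_qtl=30,
    n_chromosomes=3,
    chrom_length_cm=80.0,
    loci_per_chromosome=80,
    platform_markers=(("GBS10x@10K", 60), ("GBS1x@100K", 120)),
    elite_subpop_size=25,
    scale=1.0,
)


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete world: 40 accessions (F=0.3), Ne=500 founders,
    3 chromosomes of 0.8 Morgan, 240 loci, elite package, additive trait."""
    return build_world(TINY_SETTINGS, Ne=500, F=0.3, seed=20250901)


@pytest.fixture(scope="session")
def tiny_world_f9():
    """Same conditions with high within-accession inbreeding (F=0.9)."""
    from dataclasses import replace

    settings = replace(TINY_SETTINGS, n_accessions=25)
    return build_world(settings, Ne=500, F=0.9, seed=20250902)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
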