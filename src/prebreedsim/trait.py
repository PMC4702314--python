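"""Polygenic trait: QTL effects, true breeding values, testcross phenotypes.

The trait is strictly additive. Heritability is defined on the testcross
phenotype in the initial training population: the environmental variance is
calibrated there once per replicate so that Var(TBV)/(Var(TBV)+sigma2_e) = h2,
and then held fixed for all later phenotyping (including retraining cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import GenomeMap, Individual
from .meiosis import cross

__all__ = [
    "TraitArchitecture",
    "PhenotypeRecord",
    "sample_trait",
    "tbv",
    "tbv_many",
    "calibrate_error_variance",
    "testcross_phenotypes",
]


@dataclass
class TraitArchitecture:
    """Additive architecture: QTL loci and allele-substitution effects."""

    qtl: np.ndarray  # global locus indices, sorted
    effects: np.ndarray  # effect of allele 1 at each QTL

    def __post_init__(self) -> None:
        if self.qtl.shape != self.effects.shape:
            raise ValueError("one effect per QTL required")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("QTL effects must be finite")


@dataclass
class PhenotypeRecord:
    """One testcross phenotype, linked to the parent seed that was genotyped."""

    testcross_id: int | str | None
    parent_id: int | str | None
    value: float
    stage: str = ""


def sample_trait(gmap: GenomeMap, n_qtl: int, rng: np.random.Generator) -> TraitArchitecture:
    """Draw QTL from the map's QTL-eligible loci with iid standard-normal effects."""
    if n_qtl > gmap.qtl_index.size:
        raise ValueError(
            f"n_qtl={n_qtl} exceeds the {gmap.qtl_index.size} QTL-eligible loci"
        )
    qtl = np.sort(rng.choice(gmap.qtl_index, size=n_qtl, replace=False))
    return TraitArchitecture(qtl=qtl, effects=rng.standard_normal(n_qtl))


def tbv(individual: Individual, trait: TraitArchitecture) -> float:
    return float(individual.dosage(trait.qtl) @ trait.effects)


def tbv_many(individuals: Sequence[Individual], trait: TraitArchitecture) -> np.ndarray:
    if not individuals:
        return np.empty(0)
    dos = np.stack([ind.dosage(trait.qtl) for ind in individuals])
    return dos @ trait.effects


def calibrate_error_variance(training_tbvs: np.ndarray, h2: float) -> float:
    """sigma2_e such that h2 = Var(TBV)/(Var(TBV)+sigma2_e) in the training set."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]; h2 = 0 leaves no training signal")
    var_g = float(np.var(training_tbvs))
    return var_g * (1.0 - h2) / h2


def testcross_phenotypes(
    parents: Sequence[Individual],
    elite_hybrid: Individual,
    trait: TraitArchitecture,
    h2: float,
    gmap: GenomeMap,
    rng: np.random.Generator,
    sigma2_e: float | None = None,
    stage: str = "",
) -> tuple[list[Individual], list[PhenotypeRecord], float]:
    """Cross each parent to the elite hybrid and phenotype the testcross.

    With ``sigma2_e=None`` this is the *training* batch: the error variance is
    calibrated from the realized TBV variance of these very testcrosses and
    returned for reuse. Phenotype = TBV + N(0, sigma2_e).
    """
    testcrosses = [
        cross(p, elite_hybrid, gmap, rng, role="testcross") for p in parents
    ]
    tbvs = tbv_many(testcrosses, trait)
    if sigma2_e is None:
        sigma2_e = calibrate_error_variance(tbvs, h2)
    elif not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    noise = rng.normal(0.0, np.sqrt(sigma2_e), len(testcrosses)) if sigma2_e > 0 else 0.0
    values = tbvs + noise
    records = [
        PhenotypeRecord(
            testcross_id=tc.id, parent_id=p.id, value=float(v), stage=stage
        )
        for tc, p, v in zip(testcrosses, parents, values)
    ]
    return testcrosses, records, float(sigma2_e)


testcross_phenotypes.__test__ = False  # keep pytest from collecting the name
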