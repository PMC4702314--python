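"""RR-BLUP: ridge regression of testcross phenotypes on marker dosages.

The shrinkage parameter follows the standard RR-BLUP rule
lambda = m (1 - h2) / h2 with m the marker count and h2 the scenario's
heritability. The system is solved in the dual (n x n) whenever n < m, which
is the usual regime here (hundreds of phenotypes, thousands of markers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .gbs import GenotypeMatrix

__all__ = ["PredictionEquation", "train_ridge", "predict_ebv", "retrain_on_cycle"]


@dataclass
class PredictionEquation:
    intercept: float
    effects: np.ndarray  # trait units per dosage unit
    col_means: np.ndarray  # training-set centering means
    lam: float
    training_id: str = "discovery"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.effects.shape != self.col_means.shape:
            raise ValueError("effects and centering means must align")

    def to_json(self, path: str | Path, marker_index: np.ndarray | None = None) -> None:
        payload = {
            "intercept": self.intercept,
            "effects": self.effects.tolist(),
            "col_means": self.col_means.tolist(),
            "lambda": self.lam,
            "training_id": self.training_id,
        }
        if marker_index is not None:
            payload["marker_index"] = marker_index.tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionEquation":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=float(d["intercept"]),
            effects=np.asarray(d["effects"]),
            col_means=np.asarray(d["col_means"]),
            lam=float(d["lambda"]),
            training_id=d.get("training_id", "discovery"),
        )


def _as_matrix(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosages
    return np.asarray(genotypes, dtype=float)


def train_ridge(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotypes: np.ndarray,
    h2: float,
    lam: float | None = None,
    training_id: str = "discovery",
) -> PredictionEquation:
    """Fit effects = argmin ||y - mu - X beta||^2 + lambda ||beta||^2.

    ``lam=None`` applies the RR-BLUP rule m(1-h2)/h2; ``lam=0`` is an explicit
    ordinary-least-squares mode (only sensible on over-determined toys).
    """
    X = _as_matrix(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError(f"{n} genotype rows but {y.shape} phenotypes")
    if n < 2:
        raise ValueError("ridge training needs at least 2 observations")
    if lam is None:
        if not 0.0 < h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1] to set the shrinkage")
        lam = m * (1.0 - h2) / h2
    col_means = X.mean(axis=0)
    Xc = X - col_means
    yc = y - y.mean()
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    elif n < m:
        K = Xc @ Xc.T
        K[np.diag_indices_from(K)] += lam
        alpha = linalg.solve(K, yc, assume_a="pos")
        beta = Xc.T @ alpha
    else:
        A = Xc.T @ Xc
        A[np.diag_indices_from(A)] += lam
        beta = linalg.solve(A, Xc.T @ yc, assume_a="pos")
    return PredictionEquation(
        intercept=float(y.mean()),
        effects=beta,
        col_means=col_means,
        lam=float(lam),
        training_id=training_id,
    )


def predict_ebv(
    eq: PredictionEquation, genotypes: GenotypeMatrix | np.ndarray
) -> np.ndarray:
    """EBV = intercept + (genotype - training means) . effects."""
    X = _as_matrix(genotypes)
    return eq.intercept + (X - eq.col_means) @ eq.effects


def retrain_on_cycle(
    cycle_genotypes: GenotypeMatrix | np.ndarray,
    cycle_phenotypes: np.ndarray,
    h2: float,
    cycle: int,
) -> PredictionEquation | None:
    """Retrain on a cycle's synthetic-seed data only (discovery data excluded).

    Returns ``None`` when the cycle produced no phenotypes: the previous
    equation persists unchanged.
    """
    y = np.asarray(cycle_phenotypes, dtype=float)
    if y.size == 0:
        return None
    return train_ridge(cycle_genotypes, y, h2, training_id=f"cycle{cycle}")
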