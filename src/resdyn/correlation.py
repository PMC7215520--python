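"""Dynamic cross-correlation (DCC) of selected-atom motions.

For displacement vectors about the mean position,
``C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)`` averaged over frames:
+1 is fully correlated motion, −1 fully anti-correlated, 0 uncorrelated.
Frames are best-fit superposed onto the iterated mean structure first (by
default), since without fitting global rigid-body drift dominates the
internal motions the matrix is meant to resolve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import superpose_to_mean
from .trajectory import AtomSelection, ResidueLabel, Trajectory, TrajectoryError, coordinates_for

__all__ = ["CorrelationMatrix", "MotionClassification", "dcc_matrix", "classify_motion"]


@dataclass
class CorrelationMatrix:
    """Symmetric n×n residue correlation matrix with unit diagonal.

    Rows/columns of residues with zero fluctuation are NaN.
    """

    labels: list[ResidueLabel]
    values: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise TrajectoryError("correlation matrix must be n×n with n = len(labels)")
        self.values = v


def dcc_matrix(
    trajectory: Trajectory,
    selection: str | AtomSelection = "CA",
    superpose: bool = True,
    normalized: bool = True,
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of the selected atoms.

    With ``normalized=False`` the raw displacement covariances
    ``<Δr_i · Δr_j>`` (Å²) are returned instead of Pearson-form values.
    Residues with zero total fluctuation get NaN rows/columns and a warning.
    """
    if trajectory.n_frames < 2:
        raise TrajectoryError("DCC needs at least 2 frames")
    coords = coordinates_for(trajectory, selection)
    if superpose:
        fitted, mean = superpose_to_mean(coords)
    else:
        fitted = coords
        mean = coords.mean(axis=0)
    disp = fitted - mean[None, :, :]
    cov = np.einsum("tid,tjd->ij", disp, disp) / disp.shape[0]
    labels = trajectory.residue_labels
    if not normalized:
        return CorrelationMatrix(labels=labels, values=cov, normalized=False)

    diag = np.diag(cov).copy()
    zero = diag <= 0.0
    if np.any(zero):
        frozen = [str(labels[i]) for i in np.flatnonzero(zero)]
        warnings.warn(
            "residues with zero fluctuation excluded from DCC: " + ", ".join(frozen),
            RuntimeWarning,
            stacklevel=2,
        )
        diag[zero] = np.nan
    norm = np.sqrt(np.outer(diag, diag))
    with np.errstate(invalid="ignore"):
        values = cov / norm
    values = np.clip(values, -1.0, 1.0)
    values[~zero, ~zero] = 1.0  # exact unit diagonal for fluctuating residues
    return CorrelationMatrix(labels=labels, values=values, normalized=True)


@dataclass
class MotionClassification:
    """Off-diagonal pair categories and their fractions."""

    thresholds: tuple[float, float]
    counts: dict[str, int]
    fractions: dict[str, float]
    categories: np.ndarray  # n×n array of "anti" | "none" | "correlated" | "" (diag/NaN)


def classify_motion(
    matrix: CorrelationMatrix, thresholds: tuple[float, float] = (-0.25, 0.25)
) -> MotionClassification:
    """Bin off-diagonal residue pairs into anti / none / correlated motion.

    The "none" bin is the open interval between the thresholds: a pair is
    anti-correlated when ``C <= lower`` and correlated when ``C >= upper``.
    Fractions are over the unordered, non-NaN off-diagonal pairs and support
    statements like "predominately anti-correlated motion".
    """
    lo, hi = thresholds
    if not lo < hi:
        raise TrajectoryError("thresholds must be strictly increasing")
    v = matrix.values
    n = v.shape[0]
    categories = np.full((n, n), "", dtype=object)
    counts = {"anti": 0, "none": 0, "correlated": 0}
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        c = v[i, j]
        if np.isnan(c):
            continue
        if c <= lo:
            cat = "anti"
        elif c >= hi:
            cat = "correlated"
        else:
            cat = "none"
        categories[i, j] = categories[j, i] = cat
        counts[cat] += 1
    total = sum(counts.values())
    fractions = {k: (c / total if total else 0.0) for k, c in counts.items()}
    return MotionClassification(
        thresholds=(lo, hi), counts=counts, fractions=fractions, categories=categories
    )
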