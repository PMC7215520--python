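"""Superposition and global conformational metrics.

RMSD, radius of gyration and per-residue RMSF of the α-carbons, their
WT-minus-variant difference profiles, kernel-density estimates of metric
distributions over trajectory frames, and the summary table of per-protein
means with percent differences from the wild type.

Sign conventions for differences follow the comparative-variant usage:
profiles are subtracted WT − variant, so a *negative* ΔRMSF marks a residue
that is more flexible in the variant, and a positive one a residue that
rigidified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import gaussian_kde

from .trajectory import (
    AtomSelection,
    ResidueLabel,
    Trajectory,
    TrajectoryError,
    coordinates_for,
)

__all__ = [
    "MetricSeries",
    "ResidueProfile",
    "DensityEstimate",
    "SummaryRow",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rmsd_series",
    "rg_series",
    "rmsf_profile",
    "delta_profile",
    "kde_distribution",
    "summary_table",
    "summary_from_means",
    "percent_difference",
    "round_half_up",
    "superpose_to_mean",
]


class DegenerateGeometryError(TrajectoryError):
    """Point sets too degenerate for a unique superposition."""


@dataclass
class MetricSeries:
    """A per-frame scalar metric (Å) for one labelled protein."""

    label: str
    metric: str  # "RMSD" | "Rg"
    values: np.ndarray
    reference: str | None = None  # RMSD reference frame identifier
    times_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise TrajectoryError("metric values must be 1-D")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise TrajectoryError("metric values must be finite and >= 0")
        self.values = values

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ResidueProfile:
    """A per-residue scalar vector keyed by residue label."""

    labels: list[ResidueLabel]
    values: np.ndarray
    metric: str  # RMSF | avgL | avgBC | deltaRMSF | deltaL | deltaBC | ...
    label: str = ""  # protein or comparison label

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.labels),):
            raise TrajectoryError("one value per residue required")
        if not self.metric.startswith("delta") and np.any(values[np.isfinite(values)] < 0):
            raise TrajectoryError(f"{self.metric} values must be >= 0")
        self.values = values


@dataclass
class DensityEstimate:
    """A Gaussian-kernel density on a regular grid; integrates to 1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class SummaryRow:
    """Per-protein metric mean and its percent difference from the WT mean."""

    label: str
    metric: str
    mean: float
    percent_difference_from_wt: float

    def rounded(self) -> tuple[float, float]:
        return (
            round_half_up(self.mean, 3),
            round_half_up(self.percent_difference_from_wt, 2),
        )


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (2.675 -> 2.68 at 2 digits), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the minimum RMSD over
    all proper rotations and translations (reflections excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise TrajectoryError("point sets must share shape (n_points, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("all points (nearly) collinear")
    rot = _kabsch_rotation(mob_c, ref_c)
    aligned = mob_c @ rot.T + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd


def _kabsch_rotation(mob_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation for centred point sets (SVD with det fix)."""
    h = mob_c.T @ ref_c
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    fix = np.diag([1.0, 1.0, d])
    return vt.T @ fix @ u.T


def _fit_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, N, 3) onto ``reference``."""
    ref_c = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for t in range(coords.shape[0]):
        mob_c = coords[t] - coords[t].mean(axis=0)
        rot = _kabsch_rotation(mob_c, ref_c)
        out[t] = mob_c @ rot.T
    return out


def superpose_to_mean(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Fit all frames to an iteratively refined mean structure.

    Frames are superposed onto the running mean, the mean is recomputed,
    and the loop stops when the mean moves less than ``tol`` Å (max-norm)
    or after ``max_iter`` rounds. Returns (fitted frames, mean structure),
    both centred at the origin.
    """
    coords = np.asarray(coords, dtype=float)
    mean = coords[0] - coords[0].mean(axis=0)
    fitted = coords
    for _ in range(max_iter):
        fitted = _fit_frames(coords, mean)
        new_mean = fitted.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    return fitted, mean


# --------------------------------------------------------------------------
# Per-frame series
# --------------------------------------------------------------------------


def rmsd_series(
    trajectory: Trajectory,
    selection: str | AtomSelection = "CA",
    reference_frame: int = 0,
) -> MetricSeries:
    """Per-frame best-fit RMSD to the reference frame's selected atoms."""
    coords = coordinates_for(trajectory, selection)
    ref = coords[reference_frame]
    values = np.empty(coords.shape[0])
    for t in range(coords.shape[0]):
        _aligned, values[t] = kabsch_superpose(coords[t], ref)
    return MetricSeries(
        label=trajectory.label,
        metric="RMSD",
        values=values,
        reference=f"frame {reference_frame}",
        times_ps=trajectory.times_ps(),
    )


def rg_series(
    trajectory: Trajectory, selection: str | AtomSelection = "CA"
) -> MetricSeries:
    """Per-frame unweighted radius of gyration of the selected atoms."""
    coords = coordinates_for(trajectory, selection)
    centred = coords - coords.mean(axis=1, keepdims=True)
    values = np.sqrt(np.mean(np.sum(centred**2, axis=2), axis=1))
    return MetricSeries(
        label=trajectory.label, metric="Rg", values=values, times_ps=trajectory.times_ps()
    )


def rmsf_profile(
    trajectory: Trajectory, selection: str | AtomSelection = "CA"
) -> ResidueProfile:
    """Per-residue RMSF about the mean structure.

    Frames are first superposed onto the iterated mean structure, then
    ``RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2)``.
    """
    if trajectory.n_frames < 2:
        raise TrajectoryError("RMSF needs at least 2 frames")
    coords = coordinates_for(trajectory, selection)
    fitted, mean = superpose_to_mean(coords)
    disp = fitted - mean[None, :, :]
    rmsf = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    return ResidueProfile(
        labels=trajectory.residue_labels,
        values=rmsf,
        metric="RMSF",
        label=trajectory.label,
    )


def delta_profile(wt: ResidueProfile, variant: ResidueProfile) -> ResidueProfile:
    """Elementwise WT − variant difference of two residue profiles."""
    if len(wt.labels) != len(variant.labels):
        raise TrajectoryError(
            f"profiles differ in length ({len(wt.labels)} vs {len(variant.labels)})"
        )
    for a, b in zip(wt.labels, variant.labels):
        if a != b:
            raise TrajectoryError(f"residue label mismatch at {a} vs {b}")
    if wt.metric != variant.metric:
        raise TrajectoryError(f"metric mismatch: {wt.metric} vs {variant.metric}")
    base = wt.metric[3:] if wt.metric.startswith("avg") else wt.metric
    metric = base if base.startswith("delta") else "delta" + base
    return ResidueProfile(
        labels=list(wt.labels),
        values=wt.values - variant.values,
        metric=metric,
        label=f"{wt.label}-{variant.label}" if wt.label or variant.label else "",
    )


# --------------------------------------------------------------------------
# Distributions and summaries
# --------------------------------------------------------------------------


def kde_distribution(
    series: MetricSeries | np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> DensityEstimate:
    """Gaussian-kernel density of a metric's per-frame values.

    The bandwidth defaults to Scott's rule; the grid spans
    ``[min − 3h, max + 3h]`` with ``grid_size`` points.
    """
    values = series.values if isinstance(series, MetricSeries) else np.asarray(series, float)
    if values.size < 2 or np.ptp(values) == 0.0:
        raise TrajectoryError(
            "KDE needs >= 2 distinct values; a constant series usually means a "
            "static (degenerate) trajectory"
        )
    std = float(np.std(values, ddof=1))
    if bandwidth is None:
        kde = gaussian_kde(values)  # Scott's rule
        h = float(kde.factor) * std
    else:
        if bandwidth <= 0:
            raise TrajectoryError("bandwidth must be > 0")
        kde = gaussian_kde(values, bw_method=bandwidth / std)
        h = float(bandwidth)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    density = kde(grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=h)


def percent_difference(mean_wt: float, mean_variant: float) -> float:
    """100 × (mean_WT − mean_variant) / mean_WT."""
    return 100.0 * (mean_wt - mean_variant) / mean_wt


def summary_from_means(
    means: dict[str, float], wt_label: str, metric: str = ""
) -> list[SummaryRow]:
    """Summary rows from per-protein means; the WT row comes first at 0.00%."""
    if wt_label not in means:
        raise TrajectoryError(f"WT label {wt_label!r} missing from means")
    mean_wt = means[wt_label]
    rows = [SummaryRow(wt_label, metric, mean_wt, 0.0)]
    for label, m in means.items():
        if label == wt_label:
            continue
        rows.append(SummaryRow(label, metric, m, percent_difference(mean_wt, m)))
    return rows


def summary_table(
    series: list[MetricSeries],
    wt_label: str,
    frame_range: tuple[int, int] | None = None,
) -> list[SummaryRow]:
    """Per-protein means of one metric with percent differences from WT.

    ``frame_range`` restricts the mean to ``[start, stop)`` frames (e.g. an
    equilibrated tail).
    """
    metrics = {s.metric for s in series}
    if len(metrics) != 1:
        raise TrajectoryError(f"summary_table expects one metric, got {metrics}")
    metric = metrics.pop()

    def _mean(s: MetricSeries) -> float:
        vals = s.values if frame_range is None else s.values[frame_range[0] : frame_range[1]]
        if vals.size == 0:
            raise TrajectoryError(f"frame range {frame_range} empty for {s.label}")
        return float(np.mean(vals))

    means = {s.label: _mean(s) for s in series}
    return summary_from_means(means, wt_label, metric=metric)
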