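"""Dynamic residue networks (DRN) over trajectory frames.

Each sampled frame becomes an undirected, unweighted graph: one node per
residue, an edge wherever the Cβ–Cβ distance (Cα for glycine) is within a
cutoff (default 6.7 Å, every pair considered — no bonded exclusion). From
each frame graph two per-residue quantities are taken:

* ``L`` — the average shortest path from a residue's node to every other
  reachable node (BFS distance, nearest neighbour = 1). Lower ``L`` means a
  more accessible/central residue.
* ``BC`` — betweenness centrality, the fraction-weighted count of shortest
  paths passing through the node (endpoints excluded, unordered pairs).
  High ``BC`` marks residues important for intra-protein communication.

Per-frame profiles are min–max normalised across residues to [0, 1] and
averaged over frames; WT − variant Δ profiles are screened for residues
beyond ``k`` standard deviations of the Δ distribution (default k = 2),
the conventional selection for "residues with the most significant change".
Sign semantics of the report follow the comparative convention: positive
ΔL = variant residues more accessible, positive ΔBC = variant communication
reduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .metrics import ResidueProfile
from .trajectory import AtomSelection, ResidueLabel, Trajectory, TrajectoryError, coordinates_for

__all__ = [
    "ContactNetwork",
    "NetworkTimeSeries",
    "AveragedNetworkProfile",
    "OutlierReport",
    "contact_network",
    "shortest_path_profile",
    "betweenness_profile",
    "global_average_path_length",
    "network_timeseries",
    "average_profiles",
    "select_outliers",
    "stride_for_interval",
]

DEFAULT_CUTOFF = 6.7  # Å, Cβ contact distance


@dataclass
class ContactNetwork:
    """One frame's residue contact graph as a boolean adjacency matrix."""

    adjacency: np.ndarray
    frame_index: int = 0
    labels: list[ResidueLabel] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise TrajectoryError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise TrajectoryError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


def contact_network(
    coords: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    frame_index: int = 0,
    labels: list[ResidueLabel] | None = None,
    inclusive: bool = True,
) -> ContactNetwork:
    """Contact graph of one frame's residue coordinates.

    An edge joins residues whose Euclidean distance is ``<= cutoff``
    (``< cutoff`` with ``inclusive=False``). All residue pairs are
    considered, including sequence neighbours.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise TrajectoryError("coords must be (n_residues >= 2, 3)")
    if not np.all(np.isfinite(coords)):
        raise TrajectoryError("non-finite coordinates in contact network input")
    d = squareform(pdist(coords))
    adjacency = (d <= cutoff) if inclusive else (d < cutoff)
    np.fill_diagonal(adjacency, False)
    return ContactNetwork(adjacency=adjacency, frame_index=frame_index, labels=labels)


def shortest_path_profile(network: ContactNetwork) -> np.ndarray:
    """Per-residue average shortest path L (NaN for isolated residues).

    ``L(v) = sum of BFS distances to reachable partners / their count``.
    """
    g = network.graph()
    n = network.n
    out = np.full(n, np.nan)
    for v in range(n):
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(d for t, d in lengths.items() if t != v)
        count = len(lengths) - 1
        if count > 0:
            out[v] = total / count
    if np.any(np.isnan(out)):
        isolated = np.flatnonzero(np.isnan(out))
        warnings.warn(
            f"{isolated.size} residue(s) with no reachable partner; "
            "their L is reported as missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def global_average_path_length(network: ContactNetwork) -> float:
    """Graph-global mean shortest path: sum of d(s,t) over ordered reachable
    pairs divided by n(n−1). A convenience companion to the per-node L."""
    g = network.graph()
    n = network.n
    total = 0
    for v in range(n):
        lengths = nx.single_source_shortest_path_length(g, v)
        total += sum(d for t, d in lengths.items() if t != v)
    return total / (n * (n - 1))


def betweenness_profile(network: ContactNetwork) -> np.ndarray:
    """Per-residue raw betweenness centrality (Brandes accumulation).

    Sum over unordered pairs ``s != t != v`` of ``σ(s,t|v)/σ(s,t)``;
    disconnected pairs contribute 0. Bounded by ``(n−1)(n−2)/2``.
    """
    g = network.graph()
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[v] for v in range(network.n)], dtype=float)


def stride_for_interval(interval_ps: float, timestep_ps: float) -> int:
    """Frame stride realising a requested sampling interval."""
    if timestep_ps is None or timestep_ps <= 0:
        raise TrajectoryError("timestep_ps must be positive to derive a stride")
    return max(1, int(round(interval_ps / timestep_ps)))


@dataclass
class NetworkTimeSeries:
    """Per-sampled-frame per-residue L and raw BC."""

    labels: list[ResidueLabel]
    L: np.ndarray  # (n_sampled, n_residues), NaN = missing
    BC_raw: np.ndarray  # (n_sampled, n_residues)
    frames_used: np.ndarray  # original frame indices

    def __post_init__(self) -> None:
        if self.L.shape != self.BC_raw.shape or self.L.shape[1] != len(self.labels):
            raise TrajectoryError("inconsistent network time-series shapes")


def network_timeseries(
    trajectory: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    stride: int | None = None,
    interval_ps: float | None = None,
    selection: str | AtomSelection = "CB_GLY_CA",
) -> NetworkTimeSeries:
    """Contact graph + both per-residue profiles for every sampled frame.

    The stride is taken directly, or derived from ``interval_ps`` and the
    trajectory timestep (e.g. a 100 ps interval).
    """
    if stride is None:
        if interval_ps is not None:
            stride = stride_for_interval(interval_ps, trajectory.timestep_ps)
        else:
            stride = 1
    if stride < 1:
        raise TrajectoryError("stride must be >= 1")
    coords = coordinates_for(trajectory, selection)
    frames_used = np.arange(0, trajectory.n_frames, stride)
    labels = trajectory.residue_labels
    n = len(labels)
    L = np.empty((frames_used.size, n))
    BC = np.empty((frames_used.size, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # per-frame isolation noise
        for k, fi in enumerate(frames_used):
            net = contact_network(coords[fi], cutoff=cutoff, frame_index=int(fi), labels=labels)
            L[k] = shortest_path_profile(net)
            BC[k] = betweenness_profile(net)
    return NetworkTimeSeries(labels=labels, L=L, BC_raw=BC, frames_used=frames_used)


@dataclass
class AveragedNetworkProfile:
    """Frame-averaged, per-residue network metrics."""

    labels: list[ResidueLabel]
    avg_L_normalized: np.ndarray
    avg_BC_normalized: np.ndarray
    avg_BC_raw: np.ndarray
    avg_L_raw: np.ndarray
    missing_counts: np.ndarray  # frames in which a residue's L was undefined
    label: str = ""

    def profile(self, metric: str) -> ResidueProfile:
        values = {
            "avgL": self.avg_L_normalized,
            "avgBC": self.avg_BC_normalized,
            "avgBC_raw": self.avg_BC_raw,
            "avgL_raw": self.avg_L_raw,
        }[metric]
        return ResidueProfile(labels=self.labels, values=values, metric=metric, label=self.label)


def _minmax_rows(values: np.ndarray) -> np.ndarray:
    """Min–max normalise each row across residues, ignoring NaN.

    A row with max == min is defined as all zeros (with a warning).
    """
    out = np.full_like(values, np.nan, dtype=float)
    flat_rows = []
    for r in range(values.shape[0]):
        row = values[r]
        finite = np.isfinite(row)
        if not np.any(finite):
            continue
        lo, hi = np.min(row[finite]), np.max(row[finite])
        if hi == lo:
            out[r, finite] = 0.0
            flat_rows.append(r)
        else:
            out[r, finite] = (row[finite] - lo) / (hi - lo)
    if flat_rows:
        warnings.warn(
            f"constant profile in frame row(s) {flat_rows}; normalised values set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return out


def average_profiles(
    timeseries: NetworkTimeSeries,
    normalization: str = "minmax_per_frame",
    label: str = "",
) -> AveragedNetworkProfile:
    """Normalise per-frame profiles to [0, 1] and average over frames.

    ``minmax_per_frame`` rescales across residues within each frame before
    the arithmetic mean (missing values excluded); ``none`` averages the
    raw values. The raw BC average is always reported alongside.
    """
    if timeseries.L.shape[0] < 1:
        raise TrajectoryError("need at least one sampled frame")
    if normalization not in ("minmax_per_frame", "none"):
        raise TrajectoryError(f"unknown normalization {normalization!r}")
    L, BC = timeseries.L, timeseries.BC_raw
    if normalization == "minmax_per_frame":
        L_n, BC_n = _minmax_rows(L), _minmax_rows(BC)
    else:
        L_n, BC_n = L, BC
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        avg_L_norm = np.nanmean(L_n, axis=0)
        avg_L_raw = np.nanmean(L, axis=0)
    return AveragedNetworkProfile(
        labels=timeseries.labels,
        avg_L_normalized=avg_L_norm,
        avg_BC_normalized=BC_n.mean(axis=0),
        avg_BC_raw=BC.mean(axis=0),
        avg_L_raw=avg_L_raw,
        missing_counts=np.sum(~np.isfinite(L), axis=0),
        label=label,
    )


_SEMANTICS = {
    "deltaL": ("residue accessibility increase", "residue accessibility decrease"),
    "deltaBC": ("residue communication reduction", "residue communication increase"),
    "deltaRMSF": ("flexibility reduction", "flexibility increase"),
}


@dataclass
class OutlierReport:
    """Residues whose Δ value lies beyond mean ± k·SD of the Δ distribution."""

    metric: str
    increase_residues: list[ResidueLabel]
    decrease_residues: list[ResidueLabel]
    mean: float
    sd: float
    k: float
    note: str = ""

    @property
    def semantics(self) -> tuple[str, str]:
        """(meaning of positive outliers, meaning of negative outliers)."""
        return _SEMANTICS.get(self.metric, ("increase", "decrease"))


def select_outliers(delta: ResidueProfile, k: float = 2.0) -> OutlierReport:
    """Two-sided k-standard-deviation screen of a Δ profile.

    Uses the population SD of the finite Δ values; residues strictly above
    ``mean + k·SD`` are listed as increases and strictly below
    ``mean − k·SD`` as decreases. An SD of exactly 0 yields an empty report
    with an explanatory note.
    """
    values = delta.values
    finite = np.isfinite(values)
    if np.count_nonzero(finite) < 2:
        raise TrajectoryError("outlier screen needs at least 2 residues")
    vals = values[finite]
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population SD
    if sd <= 1e-12 * max(1.0, abs(mean)):  # identical up to float fuzz
        return OutlierReport(
            metric=delta.metric, increase_residues=[], decrease_residues=[],
            mean=mean, sd=sd, k=k,
            note="all delta values identical (SD = 0); no outliers defined",
        )
    hi, lo = mean + k * sd, mean - k * sd
    inc = [lab for lab, v, ok in zip(delta.labels, values, finite) if ok and v > hi]
    dec = [lab for lab, v, ok in zip(delta.labels, values, finite) if ok and v < lo]
    return OutlierReport(
        metric=delta.metric, increase_residues=inc, decrease_residues=dec,
        mean=mean, sd=sd, k=k,
    )
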