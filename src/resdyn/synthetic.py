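"""Seeded generator of protein-like Cα/Cβ trajectories with known statistics.

The generator emulates a solvated, already-stripped single-chain protein
trajectory (by default a ~268-residue chain numbered from 23, the size of
the carbonic-anhydrase fold it stands in for) with controllable
per-residue fluctuation amplitudes, correlated or anti-correlated group
motions driven by shared latent factors, optional global rigid-body motion
and optional two-state conformational switching. Because every statistical
ingredient is prescribed, downstream estimators (RMSF, DCC, residue
networks) can be tested against closed-form expectations.

Frame ``t`` is built as::

    R_t( base_{s(t)} + sum_k a_k z_k(t) + eps(t) ) + T_t

where ``base_{s(t)}`` is the reference geometry of the active conformational
state, ``a_k`` is factor ``k``'s signed per-residue loading (Å), ``z_k(t)``
an isotropic standard-normal 3-vector drawn i.i.d. per frame, ``eps_i(t)``
isotropic Gaussian jitter with per-residue standard deviation ``sigma_i``
per axis, and ``(R_t, T_t)`` an optional random rototranslation. With a
single factor of loading ``a`` on two residues and jitter ``sigma``, the
expected displacement correlation of the pair is ``a^2 / (a^2 + sigma^2)``
(negated for opposite-sign loadings), and the expected RMSF of a
factor-free residue is ``sqrt(3) * sigma_i``.

β-carbons are placed 1.53 Å from each α-carbon along a deterministic local
direction derived from the base geometry, and are omitted at glycine
positions; latent factors are i.i.d. across frames (all downstream
estimators are invariant to frame order, so temporal autocorrelation adds
nothing testable).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory, TrajectoryError

__all__ = [
    "GeneratorConfig",
    "Factor",
    "TwoStateConfig",
    "Perturbation",
    "generate",
    "make_variant_pair",
    "helix_backbone",
    "compact_walk_backbone",
]

CB_BOND_LENGTH = 1.53  # Å, Cα–Cβ
WALK_STEP = 3.8  # Å, consecutive-Cα distance
WALK_CLASH = 4.0  # Å, hard-sphere rejection radius between non-bonded beads


@dataclass(frozen=True)
class Factor:
    """A shared motion mode: signed per-residue loadings (Å) times an
    isotropic standard-normal 3-vector latent drawn independently per frame.

    Same-sign loadings move residues in unison (correlated motion);
    opposite signs move them in anti-phase (anti-correlated motion).
    """

    loading: np.ndarray

    def __post_init__(self) -> None:
        loading = np.asarray(self.loading, dtype=float)
        if loading.ndim != 1 or not np.all(np.isfinite(loading)):
            raise TrajectoryError("factor loading must be a finite 1-D array")
        object.__setattr__(self, "loading", loading)


@dataclass(frozen=True)
class TwoStateConfig:
    """Two-state conformational switching.

    The second state is the base geometry with a block of residues displaced
    by ``offset_angstrom`` along the deterministic local side-chain
    direction; the active state flips with probability
    ``switch_probability`` between successive frames.
    """

    offset_angstrom: float
    switch_probability: float
    displaced_fraction: float = 1.0 / 3.0  # trailing fraction of the chain

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_probability < 1.0):
            raise TrajectoryError("switch_probability must lie in (0, 1)")
        if self.offset_angstrom <= 0:
            raise TrajectoryError("offset_angstrom must be positive")
        if not (0.0 < self.displaced_fraction <= 1.0):
            raise TrajectoryError("displaced_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic trajectory.

    Defaults emulate the study conditions this generator stands in for: a
    268-residue single chain numbered from 23, 2000 saved frames 100 ps
    apart (200 ns of sampling) and ~0.5 Å per-axis thermal jitter.
    """

    n_residues: int = 268
    first_residue_number: int = 23
    n_frames: int = 2000
    timestep_ps: float = 100.0
    seed: int = 0
    base_geometry: str = "compact_walk"  # or "helix"
    fluctuation_sigma: float | Sequence[float] = 0.5
    motion_factors: tuple[Factor, ...] = ()
    rigid_body: str = "none"  # or "random"
    two_state: TwoStateConfig | None = None
    glycine_positions: frozenset[int] = frozenset()
    geometry_seed: int | None = None  # share a base geometry across variants
    base_offsets: np.ndarray | None = None  # (n_residues, 3) added to the base

    def sigma_array(self) -> np.ndarray:
        sigma = np.broadcast_to(
            np.asarray(self.fluctuation_sigma, dtype=float), (self.n_residues,)
        ).copy()
        if not np.all(np.isfinite(sigma)) or np.any(sigma < 0):
            raise TrajectoryError("fluctuation_sigma must be finite and >= 0")
        return sigma

    def validate(self) -> None:
        if self.n_residues < 2:
            raise TrajectoryError("need at least 2 residues")
        if self.n_frames < 1:
            raise TrajectoryError("need at least 1 frame")
        if self.base_geometry not in ("helix", "compact_walk"):
            raise TrajectoryError(f"unknown base_geometry {self.base_geometry!r}")
        if self.rigid_body not in ("none", "random"):
            raise TrajectoryError(f"unknown rigid_body mode {self.rigid_body!r}")
        self.sigma_array()
        for f in self.motion_factors:
            if f.loading.shape != (self.n_residues,):
                raise TrajectoryError(
                    f"factor loading length {f.loading.shape[0]} != n_residues"
                )
        if self.base_offsets is not None:
            offs = np.asarray(self.base_offsets, dtype=float)
            if offs.shape != (self.n_residues, 3):
                raise TrajectoryError("base_offsets must have shape (n_residues, 3)")

    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.n_residues) + self.first_residue_number


# --------------------------------------------------------------------------
# Base geometries
# --------------------------------------------------------------------------


def helix_backbone(n_residues: int) -> np.ndarray:
    """Ideal α-helix Cα trace: 1.5 Å rise, 100° turn, 2.3 Å radius."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def compact_walk_backbone(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Globular Cα trace: a 3.8 Å fixed-step walk confined to a sphere with
    hard-sphere rejection at 4.0 Å, backtracking when trapped."""
    radius = 4.2 * n_residues ** (1.0 / 3.0)
    for _restart in range(100):
        coords = np.zeros((n_residues, 3))
        i = 1
        backtracks = 0
        while i < n_residues:
            placed = False
            for _ in range(200):
                v = rng.normal(size=3)
                v *= WALK_STEP / np.linalg.norm(v)
                cand = coords[i - 1] + v
                if np.linalg.norm(cand) > radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if np.min(d) < WALK_CLASH:
                        continue
                coords[i] = cand
                placed = True
                break
            if placed:
                i += 1
                continue
            backtracks += 1
            if backtracks > 10 * n_residues:
                break  # deterministic restart with fresh randomness
            i = max(1, i - 5)  # deep backtrack to escape dead ends
        if i == n_residues:
            return coords - coords.mean(axis=0)
    raise TrajectoryError("compact walk failed to place all residues")


def _local_directions(base: np.ndarray) -> np.ndarray:
    """Deterministic unit side-chain direction per residue.

    Interior residues point along the bisector away from the midpoint of
    their sequence neighbours; termini copy their neighbour's direction.
    Degenerate (collinear) sites fall back to a fixed axis orthogonalised
    against the chain direction.
    """
    n = base.shape[0]
    dirs = np.zeros((n, 3))
    for i in range(1, n - 1):
        d = base[i] - 0.5 * (base[i - 1] + base[i + 1])
        norm = np.linalg.norm(d)
        if norm < 1e-8:
            chain = base[i + 1] - base[i - 1]
            d = np.cross(chain, [0.0, 0.0, 1.0])
            if np.linalg.norm(d) < 1e-8:
                d = np.cross(chain, [0.0, 1.0, 0.0])
            norm = np.linalg.norm(d)
        dirs[i] = d / norm
    if n >= 2:
        dirs[0] = dirs[1] if n > 2 else _fallback_dir(base[1] - base[0])
        dirs[-1] = dirs[-2] if n > 2 else dirs[0]
    return dirs


def _fallback_dir(chain: np.ndarray) -> np.ndarray:
    d = np.cross(chain, [0.0, 0.0, 1.0])
    if np.linalg.norm(d) < 1e-8:
        d = np.cross(chain, [0.0, 1.0, 0.0])
    return d / np.linalg.norm(d)


def _base_ca(config: GeneratorConfig) -> np.ndarray:
    geom_seed = config.geometry_seed if config.geometry_seed is not None else config.seed
    rng = np.random.default_rng(np.random.SeedSequence([geom_seed, 0xBA5E]))
    if config.base_geometry == "helix":
        base = helix_backbone(config.n_residues)
    else:
        base = compact_walk_backbone(config.n_residues, rng)
    if config.base_offsets is not None:
        base = base + np.asarray(config.base_offsets, dtype=float)
    return base


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def generate(config: GeneratorConfig) -> Trajectory:
    """Generate a trajectory. Identical config + seed gives identical output."""
    config.validate()
    n = config.n_residues
    sigma = config.sigma_array()
    base = _base_ca(config)
    cb_dirs = _local_directions(base)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5015E]))
    res_numbers = config.residue_numbers()
    is_gly = np.isin(res_numbers, sorted(config.glycine_positions))

    # state sequence for two-state switching
    states = np.zeros(config.n_frames, dtype=int)
    second_base = None
    if config.two_state is not None:
        ts = config.two_state
        flips = rng.random(config.n_frames) < ts.switch_probability
        flips[0] = False
        states = np.cumsum(flips) % 2
        n_disp = max(1, int(round(ts.displaced_fraction * n)))
        offsets = np.zeros((n, 3))
        offsets[n - n_disp :] = cb_dirs[n - n_disp :] * ts.offset_angstrom
        second_base = base + offsets

    ca = np.empty((config.n_frames, n, 3))
    for t in range(config.n_frames):
        frame = (base if states[t] == 0 else second_base).copy()
        for fac in config.motion_factors:
            z = rng.normal(size=3)
            frame += fac.loading[:, None] * z[None, :]
        frame += rng.normal(size=(n, 3)) * sigma[:, None]
        ca[t] = frame

    # assemble atom sites: CA for every residue, CB for non-glycine;
    # the Cβ rides rigidly on its Cα along the base-geometry direction.
    sites: list[tuple[str, str, int, str]] = []
    col_of: list[tuple[int, bool]] = []  # (residue index, is_cb)
    for i, num in enumerate(res_numbers):
        res_name = "GLY" if is_gly[i] else "ALA"
        sites.append(("CA", res_name, int(num), "A"))
        col_of.append((i, False))
        if not is_gly[i]:
            sites.append(("CB", res_name, int(num), "A"))
            col_of.append((i, True))

    coords = np.empty((config.n_frames, len(sites), 3))
    cb_off = cb_dirs * CB_BOND_LENGTH
    for j, (i, is_cb) in enumerate(col_of):
        coords[:, j, :] = ca[:, i, :] + (cb_off[i] if is_cb else 0.0)

    # rigid body applies to all atoms of a frame together, so internal
    # geometry (and hence best-fit RMSD) is untouched
    if config.rigid_body == "random":
        for t in range(config.n_frames):
            rot = Rotation.random(rng=rng).as_matrix()
            trans = rng.normal(scale=5.0, size=3)
            coords[t] = coords[t] @ rot.T + trans

    traj = Trajectory(sites, coords, label="synthetic", timestep_ps=config.timestep_ps)
    return traj


@dataclass(frozen=True)
class Perturbation:
    """A localized change applied to the variant of a trajectory pair.

    kind:
      ``sigma_scale``   multiply fluctuation sigma by ``amount`` on the residues;
      ``flip_factor``   negate factor ``factor_index`` loadings on the residues;
      ``displace``      shift the base geometry by ``amount`` Å along the local
                        side-chain direction on the residues.
    """

    kind: str
    residue_indices: tuple[int, ...]
    amount: float = 2.0
    factor_index: int = 0

    KINDS = ("sigma_scale", "flip_factor", "displace", "null")


def make_variant_pair(
    config: GeneratorConfig, perturbation: Perturbation | None
) -> tuple[Trajectory, Trajectory]:
    """Two independently seeded trajectories sharing one base geometry and
    topology, the second carrying the perturbation (or none for a null pair)."""
    config.validate()
    if perturbation is not None and perturbation.kind not in Perturbation.KINDS:
        raise TrajectoryError(f"unknown perturbation kind {perturbation.kind!r}")
    idx = np.asarray(perturbation.residue_indices, dtype=int) if perturbation else np.empty(0, int)
    if idx.size and (idx.min() < 0 or idx.max() >= config.n_residues):
        raise TrajectoryError("perturbation residue indices out of range")

    ss = np.random.SeedSequence([config.seed, 0x9A13])
    wt_seed, var_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    shared_geom = config.geometry_seed if config.geometry_seed is not None else config.seed

    wt_cfg = dataclasses.replace(config, seed=wt_seed, geometry_seed=shared_geom)
    var_cfg = dataclasses.replace(config, seed=var_seed, geometry_seed=shared_geom)

    if perturbation is not None and perturbation.kind != "null":
        if perturbation.kind == "sigma_scale":
            sigma = config.sigma_array()
            sigma[idx] *= perturbation.amount
            var_cfg = dataclasses.replace(var_cfg, fluctuation_sigma=tuple(sigma))
        elif perturbation.kind == "flip_factor":
            factors = list(config.motion_factors)
            if not factors:
                raise TrajectoryError("flip_factor perturbation needs motion_factors")
            loading = factors[perturbation.factor_index].loading.copy()
            loading[idx] *= -1.0
            factors[perturbation.factor_index] = Factor(loading)
            var_cfg = dataclasses.replace(var_cfg, motion_factors=tuple(factors))
        elif perturbation.kind == "displace":
            base = _base_ca(dataclasses.replace(config, base_offsets=None))
            dirs = _local_directions(base)
            offsets = np.zeros((config.n_residues, 3))
            offsets[idx] = dirs[idx] * perturbation.amount
            var_cfg = dataclasses.replace(var_cfg, base_offsets=offsets)

    wt = generate(wt_cfg)
    var = generate(var_cfg)
    wt.label, var.label = "WT", "variant"
    return wt, var
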