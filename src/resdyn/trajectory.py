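"""Domain types and file I/O for protein trajectories.

A trajectory is a fixed atom topology plus an ordered stack of per-frame
coordinates. The supported on-disk format is multi-model PDB (``MODEL`` /
``ENDMDL`` blocks sharing one topology); residue-set lists are plain text,
one ``Xxx###`` label per line.

Only ATOM/HETATM/MODEL/ENDMDL/TER records are interpreted. Alternate
locations other than blank/"A" are skipped, insertion codes are rejected,
and non-standard residues are rejected unless explicitly mapped to their
parent amino acid.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Trajectory",
    "AtomSelection",
    "ResidueLabel",
    "ResidueSet",
    "TrajectoryError",
    "PDBParseError",
    "TopologyMismatchError",
    "SelectionError",
    "ResidueSetParseError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "coordinates_for",
    "parse_residue_set",
    "read_residue_set",
    "STANDARD_RESIDUES",
    "NONSTANDARD_PARENT",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Common non-standard residues and the standard parent they are mapped to
#: when reading with ``map_nonstandard=True``.
NONSTANDARD_PARENT = {
    "MSE": "MET",
    "SEC": "CYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "MLY": "LYS",
}


class TrajectoryError(Exception):
    """Base class for trajectory-domain errors."""


class PDBParseError(TrajectoryError):
    """Malformed or unsupported PDB content."""


class TopologyMismatchError(TrajectoryError):
    """Frames of one trajectory do not share an identical atom topology."""


class SelectionError(TrajectoryError):
    """An atom selection cannot be resolved on a topology."""


class ResidueSetParseError(TrajectoryError):
    """A residue-set list contains an unparseable label."""


# --------------------------------------------------------------------------
# Residue labels
# --------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Za-z]{3})(\d+)$")

_THREE_TO_CANON = {code: code.capitalize() for code in STANDARD_RESIDUES}


@dataclass(frozen=True, order=True)
class ResidueLabel:
    """A residue identified by its 3-letter code and author residue number.

    The text form is ``Xxx###`` (e.g. ``Trp37``) and round-trips unchanged
    through :meth:`parse` / :meth:`__str__`.
    """

    residue_name: str  # canonical 3-letter code, upper case (e.g. "TRP")
    residue_number: int

    def __post_init__(self) -> None:
        if self.residue_name.upper() != self.residue_name:
            object.__setattr__(self, "residue_name", self.residue_name.upper())

    @classmethod
    def parse(cls, text: str) -> "ResidueLabel":
        m = _LABEL_RE.match(text.strip())
        if not m:
            raise ResidueSetParseError(f"unparseable residue label: {text!r}")
        name, num = m.group(1).upper(), int(m.group(2))
        if name not in STANDARD_RESIDUES:
            raise ResidueSetParseError(
                f"unknown residue code {m.group(1)!r} in label {text!r}"
            )
        return cls(name, num)

    def __str__(self) -> str:
        return f"{self.residue_name.capitalize()}{self.residue_number}"


# --------------------------------------------------------------------------
# Atoms, frames, trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: name, residue identity and Cartesian position (Å)."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,):
            raise TrajectoryError(f"coordinates must be a 3-vector, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.residue_name}{self.residue_number}"
            )
        object.__setattr__(self, "coordinates", coords)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class StructureFrame:
    """One conformation: an ordered atom list with a frame index and time."""

    atoms: list[AtomRecord]
    frame_index: int = 0
    time_ps: float | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise TrajectoryError("frame_index must be >= 0")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise TrajectoryError(
                        f"duplicate atom {k[2]} in residue {k[1]} chain {k[0]!r}"
                    )
                seen.add(k)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)


Residue = tuple[str, int, str]  # (chain_id, residue_number, residue_name)


class Trajectory:
    """Fixed atom topology plus an ordered stack of per-frame coordinates.

    Parameters
    ----------
    atom_sites
        Ordered ``(atom_name, residue_name, residue_number, chain_id)``
        tuples shared by every frame.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    label
        Protein label, e.g. ``"WT"`` or ``"S100P"``.
    timestep_ps
        Time between successive frames in picoseconds, if known.
    """

    def __init__(
        self,
        atom_sites: Sequence[tuple[str, str, int, str]],
        coords: np.ndarray,
        label: str = "",
        timestep_ps: float | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must have shape (n_frames, n_atoms, 3), got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        if coords.shape[1] != len(atom_sites):
            raise TrajectoryError("coords second axis must match the atom count")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("trajectory coordinates must be finite")
        self.atom_sites = [tuple(s) for s in atom_sites]
        self.coords = coords
        self.label = label
        self.timestep_ps = timestep_ps
        self._check_residue_consistency()

    def _check_residue_consistency(self) -> None:
        names: dict[tuple[str, int], str] = {}
        for atom_name, res_name, res_num, chain in self.atom_sites:
            key = (chain, res_num)
            if key in names and names[key] != res_name:
                raise TopologyMismatchError(
                    f"residue {res_num} chain {chain!r} has conflicting names "
                    f"{names[key]} / {res_name}"
                )
            names[key] = res_name

    # -- basic views -------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def topology(self) -> list[Residue]:
        """Ordered unique residues as ``(chain_id, residue_number, residue_name)``."""
        seen: set[tuple[str, int]] = set()
        out: list[Residue] = []
        for _atom, res_name, res_num, chain in self.atom_sites:
            if (chain, res_num) not in seen:
                seen.add((chain, res_num))
                out.append((chain, res_num, res_name))
        return out

    @property
    def residue_labels(self) -> list[ResidueLabel]:
        return [ResidueLabel(name, num) for _c, num, name in self.topology]

    def times_ps(self) -> np.ndarray | None:
        if self.timestep_ps is None:
            return None
        return np.arange(self.n_frames) * float(self.timestep_ps)

    def frame(self, index: int) -> StructureFrame:
        atoms = [
            AtomRecord(a, rn, num, ch, self.coords[index, i])
            for i, (a, rn, num, ch) in enumerate(self.atom_sites)
        ]
        t = None if self.timestep_ps is None else index * float(self.timestep_ps)
        return StructureFrame(atoms, frame_index=index, time_ps=t)

    def frames(self) -> Iterable[StructureFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def subsample(self, stride: int) -> "Trajectory":
        """Every ``stride``-th frame, starting at frame 0."""
        if stride < 1:
            raise TrajectoryError("stride must be >= 1")
        return Trajectory(
            self.atom_sites,
            self.coords[::stride],
            label=self.label,
            timestep_ps=None if self.timestep_ps is None else self.timestep_ps * stride,
        )

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[StructureFrame],
        label: str = "",
        timestep_ps: float | None = None,
    ) -> "Trajectory":
        if not frames:
            raise TrajectoryError("a trajectory needs at least one frame")
        ref_sites = [
            (a.atom_name, a.residue_name, a.residue_number, a.chain_id)
            for a in frames[0].atoms
        ]
        coords = np.empty((len(frames), len(ref_sites), 3), dtype=float)
        for fi, fr in enumerate(frames):
            sites = [
                (a.atom_name, a.residue_name, a.residue_number, a.chain_id)
                for a in fr.atoms
            ]
            if sites != ref_sites:
                raise TopologyMismatchError(
                    f"frame {fi} does not match the topology of frame 0"
                )
            coords[fi] = fr.coordinates()
        return cls(ref_sites, coords, label=label, timestep_ps=timestep_ps)


# --------------------------------------------------------------------------
# Atom selections
# --------------------------------------------------------------------------


@dataclass
class AtomSelection:
    """A resolved one-atom-per-residue selection.

    ``mode="CA"`` picks the α-carbon of every residue; ``mode="CB_GLY_CA"``
    picks the β-carbon except for glycine, which lacks one and contributes
    its α-carbon instead.
    """

    mode: str
    resolved_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    MODES = ("CA", "CB_GLY_CA")

    @classmethod
    def resolve(cls, trajectory: Trajectory, mode: str = "CA") -> "AtomSelection":
        if mode not in cls.MODES:
            raise SelectionError(f"unknown selection mode {mode!r}")
        index_of: dict[tuple[str, int, str], int] = {
            (ch, num, atom): i
            for i, (atom, _rn, num, ch) in enumerate(trajectory.atom_sites)
        }
        indices: list[int] = []
        missing: list[str] = []
        for chain, num, res_name in trajectory.topology:
            wanted = "CA"
            if mode == "CB_GLY_CA" and res_name != "GLY":
                wanted = "CB"
            idx = index_of.get((chain, num, wanted))
            if idx is None:
                missing.append(f"{res_name.capitalize()}{num} (needs {wanted})")
            else:
                indices.append(idx)
        if missing:
            raise SelectionError(
                f"selection {mode} unresolvable; missing atoms for: "
                + ", ".join(missing)
            )
        return cls(mode=mode, resolved_indices=np.asarray(indices, dtype=int))


def coordinates_for(trajectory: Trajectory, selection: AtomSelection | str) -> np.ndarray:
    """Dense ``(n_frames, n_residues, 3)`` coordinates for a selection.

    Residue order matches the trajectory topology order.
    """
    if isinstance(selection, str):
        selection = AtomSelection.resolve(trajectory, selection)
    return trajectory.coords[:, selection.resolved_indices, :]


# --------------------------------------------------------------------------
# PDB reading / writing
# --------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> tuple[tuple[str, str, int, str], np.ndarray, str, str]:
    """Parse one ATOM/HETATM line -> (site, xyz, altloc, icode)."""
    try:
        atom_name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip().upper()
        chain_id = line[21]
        res_seq = int(line[22:26])
        icode = line[26]
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    return (atom_name, res_name, res_seq, chain_id), xyz, altloc, icode


def read_multimodel_pdb(
    path: str | os.PathLike,
    selection_mode: str | None = None,
    label: str = "",
    timestep_ps: float | None = None,
    chain: str | None = None,
    map_nonstandard: bool = False,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Single-model files yield a one-frame trajectory. Every model must list
    the same atoms in the same order; the first offending frame is named in
    the :class:`TopologyMismatchError` otherwise.

    Parameters
    ----------
    selection_mode
        If given, the selection is resolved immediately so missing CA/CB
        atoms fail at read time rather than downstream.
    chain
        Required when the file contains more than one chain; only that
        chain is read.
    map_nonstandard
        Map known non-standard residues (e.g. MSE) to their standard parent
        instead of rejecting them.
    """
    path = Path(path)
    frames_sites: list[list[tuple[str, str, int, str]]] = []
    frames_xyz: list[list[np.ndarray]] = []
    cur_sites: list[tuple[str, str, int, str]] | None = None
    cur_xyz: list[np.ndarray] | None = None
    in_model = False
    chains_seen: set[str] = set()

    def _open_frame() -> None:
        nonlocal cur_sites, cur_xyz
        cur_sites, cur_xyz = [], []

    def _close_frame() -> None:
        nonlocal cur_sites, cur_xyz
        if cur_sites:
            frames_sites.append(cur_sites)
            frames_xyz.append(cur_xyz)  # type: ignore[arg-type]
        cur_sites, cur_xyz = None, None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if in_model:
                    raise PDBParseError(f"nested MODEL at line {lineno}")
                in_model = True
                _open_frame()
            elif record == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"ENDMDL without MODEL at line {lineno}")
                in_model = False
                _close_frame()
            elif record in ("ATOM", "HETATM"):
                if cur_sites is None:
                    _open_frame()  # single-model file without MODEL records
                site, xyz, altloc, icode = _parse_atom_line(line, lineno)
                if altloc not in (" ", "A"):
                    continue
                if icode != " ":
                    raise PDBParseError(
                        f"insertion code {icode!r} at line {lineno} is not supported"
                    )
                atom_name, res_name, res_seq, chain_id = site
                if res_name not in STANDARD_RESIDUES:
                    if map_nonstandard and res_name in NONSTANDARD_PARENT:
                        res_name = NONSTANDARD_PARENT[res_name]
                    else:
                        raise PDBParseError(
                            f"non-standard residue {res_name} at line {lineno} "
                            "(pass map_nonstandard=True to map known parents)"
                        )
                chains_seen.add(chain_id)
                if chain is not None and chain_id != chain:
                    continue
                cur_sites.append((atom_name, res_name, res_seq, chain_id))  # type: ignore[union-attr]
                cur_xyz.append(xyz)  # type: ignore[union-attr]
            # TER and every other record type are ignored

    if in_model:
        raise PDBParseError("file ends inside an open MODEL block")
    _close_frame()

    if chain is None and len(chains_seen) > 1:
        raise PDBParseError(
            f"multi-chain file (chains {sorted(chains_seen)}); pass an explicit chain"
        )
    if not frames_sites:
        raise PDBParseError(f"no atoms read from {path}")

    ref = frames_sites[0]
    for fi, sites in enumerate(frames_sites[1:], start=1):
        if sites != ref:
            raise TopologyMismatchError(
                f"model {fi + 1} of {path.name} does not match the topology of model 1"
            )

    coords = np.asarray(frames_xyz, dtype=float)
    traj = Trajectory(ref, coords, label=label or path.stem, timestep_ps=timestep_ps)
    if selection_mode is not None:
        AtomSelection.resolve(traj, selection_mode)
    return traj


_ELEMENT_GUESS = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H", "P": "P"}


def write_multimodel_pdb(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as standard MODEL/ENDMDL PDB blocks (3-decimal Å)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for fi in range(trajectory.n_frames):
            fh.write(f"MODEL     {fi + 1:4d}\n")
            serial = 1
            for ai, (atom_name, res_name, res_num, chain) in enumerate(
                trajectory.atom_sites
            ):
                x, y, z = trajectory.coords[fi, ai]
                # names < 4 chars start in column 14 per PDB convention
                name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
                element = _ELEMENT_GUESS.get(atom_name[0], atom_name[0])
                fh.write(
                    f"ATOM  {serial:5d} {name_field:<4s} {res_name:<3s} "
                    f"{chain:1s}{res_num:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}\n"
                )
                serial += 1
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Residue sets
# --------------------------------------------------------------------------


@dataclass
class ResidueSet:
    """A named set of residue labels (e.g. one predictor's binding-site list)."""

    name: str
    members: frozenset[ResidueLabel]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def numbers(self) -> frozenset[int]:
        return frozenset(m.residue_number for m in self.members)

    def __contains__(self, item: ResidueLabel | int) -> bool:
        if isinstance(item, int):
            return item in self.numbers()
        return item in self.members


def parse_residue_set(source: str | os.PathLike, name: str = "") -> ResidueSet:
    """Parse a residue-set list from text or from a file path.

    One ``Xxx###`` label per line; ``#`` starts a comment; blank lines and
    duplicates are ignored. A path-like argument, or a single-line string
    naming an existing file, is read from disk.
    """
    if isinstance(source, os.PathLike):
        return read_residue_set(source, name=name)
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        return read_residue_set(Path(source), name=name)
    members: set[ResidueLabel] = set()
    for lineno, raw in enumerate(str(source).splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for token in line.replace(",", " ").split():
            try:
                members.add(ResidueLabel.parse(token))
            except ResidueSetParseError as exc:
                raise ResidueSetParseError(f"line {lineno}: {exc}") from exc
    return ResidueSet(name=name, members=frozenset(members))


def read_residue_set(path: str | os.PathLike, name: str = "") -> ResidueSet:
    path = Path(path)
    parsed = parse_residue_set(path.read_text(encoding="utf-8"), name=name or path.stem)
    return parsed
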