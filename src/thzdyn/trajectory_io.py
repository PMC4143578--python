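"""Trajectory containers, readers/writers and atom selections.

All coordinates are stored in angstrom, all times in picoseconds,
regardless of the on-disk format (GRO files, which use nm, are converted
on ingestion).  Velocities, when present, are in angstrom/ps.

Multi-model PDB and frame-concatenated GRO files are parsed through
:mod:`mdtraj`; the resulting :class:`Trajectory` is a plain in-memory
container that every analysis module in this package consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Trajectory",
    "ShellSelection",
    "TrajectoryFormatError",
    "DEFAULT_WATER_RESNAMES",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "shell_waters",
    "finite_difference_velocities",
]

#: Residue names recognised as water molecules.
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})

_NM_TO_ANGSTROM = 10.0


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file is structurally inconsistent."""


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: name, element, residue and category.

    ``category`` is ``"water"`` iff the residue name belongs to the
    configured water set, ``"protein"`` for standard polymer residues,
    ``"other"`` otherwise (ions, ligands, ...).
    """

    index: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain: str = "A"
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.index} ({self.name}): empty element symbol")
        if self.category not in ("protein", "water", "other"):
            raise ValueError(f"unknown atom category {self.category!r}")


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinate series with optional velocities.

    Parameters
    ----------
    atoms:
        Ordered atom metadata; atom order is identical in every frame.
    coords:
        ``(n_frames, n_atoms, 3)`` array in angstrom.
    dt:
        Frame spacing in ps, strictly positive.
    velocities:
        Optional ``(n_frames, n_atoms, 3)`` array in angstrom/ps.
    box:
        Optional orthorhombic box lengths ``(3,)`` in angstrom; when set,
        distance computations use the minimum-image convention.
    velocities_derived:
        True when velocities were obtained by numerical differentiation
        rather than read from the source data.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    dt: float
    velocities: np.ndarray | None = None
    box: np.ndarray | None = None
    velocities_derived: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but {len(self.atoms)} records"
            )
        if not (self.dt > 0):
            raise ValueError(f"dt must be strictly positive, got {self.dt}")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError(
                    f"velocity shape {self.velocities.shape} != coords shape {self.coords.shape}"
                )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    def displacements_min_image(self, delta: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        if self.box is None:
            return delta
        return delta - self.box * np.round(delta / self.box)


@dataclass(frozen=True)
class ShellSelection:
    """Water molecules whose oxygen lies within ``cutoff`` of the protein."""

    cutoff: float
    frame: int
    water_oxygen_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.water_oxygen_indices)


# ---------------------------------------------------------------------------
# Reading / writing


def _category(resname: str, water_resnames: frozenset[str], is_protein: bool) -> str:
    if resname.upper() in water_resnames:
        return "water"
    if is_protein:
        return "protein"
    return "other"


_PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL HID HIE HIP CYX ACE NME""".split()
)


def _validate_pdb_models(path: Path) -> None:
    """Pre-scan a multi-model PDB so atom-count mismatches name the frame."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current:
        counts.append(current)
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"frame {bad} has {counts[bad]} atoms, expected {counts[0]} (from frame 0)"
        )


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    dt: float | None = None,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> Trajectory:
    """Read a multi-model PDB or frame-concatenated GRO file.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"pdb-multimodel"`` or ``"gro-series"``; inferred from the file
        suffix when omitted.
    dt:
        Frame spacing in ps.  Mandatory for formats that do not encode
        time (PDB always; GRO unless every frame carries a ``t=`` stamp).
        An explicit value always wins over file metadata.
    water_resnames:
        Residue names treated as water.

    Returns
    -------
    Trajectory
        Coordinates in angstrom (GRO input is converted from nm).
    """
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".pdb": "pdb-multimodel", ".gro": "gro-series"}.get(suffix)
        if format is None:
            raise TrajectoryFormatError(f"cannot infer format from suffix {suffix!r}")
    if format not in ("pdb-multimodel", "gro-series"):
        raise TrajectoryFormatError(f"unknown format {format!r}")

    if format == "pdb-multimodel":
        _validate_pdb_models(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = md.load_pdb(str(path), standard_names=False)
    else:
        traj = md.load(str(path))

    water_resnames = frozenset(r.upper() for r in water_resnames)
    atoms: list[AtomRecord] = []
    for a in traj.topology.atoms:
        res = a.residue
        element = a.element.symbol if a.element is not None else a.name[:1]
        atoms.append(
            AtomRecord(
                index=a.index,
                name=a.name,
                element=element,
                residue_seq=res.resSeq,
                residue_name=res.name,
                chain=str(res.chain.index),
                category=_category(
                    res.name,
                    water_resnames,
                    res.name.upper() in _PROTEIN_RESNAMES,
                ),
            )
        )

    if dt is None:
        # never trust fabricated frame indices as times: PDB has no time
        # record at all and GRO only carries one in 't=' header comments
        encodes_time = False
        if format == "gro-series":
            with open(path) as fh:
                encodes_time = "t=" in fh.readline()
        t = np.asarray(traj.time, dtype=float)
        steps = np.diff(t)
        if encodes_time and len(steps) and np.all(steps > 0) and np.allclose(steps, steps[0]):
            dt = float(steps[0])
        else:
            raise ValueError(
                f"{path.name}: frame spacing not encoded in file; pass dt explicitly"
            )

    box = None
    if traj.unitcell_lengths is not None:
        lengths = traj.unitcell_lengths[0] * _NM_TO_ANGSTROM
        if np.all(lengths > 0):
            box = lengths

    return Trajectory(
        atoms=atoms,
        coords=np.asarray(traj.xyz, dtype=float) * _NM_TO_ANGSTROM,
        dt=float(dt),
        box=box,
    )


def _mdtraj_topology(traj: Trajectory):
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[tuple[str, int, str], object] = {}
    for a in traj.atoms:
        if a.chain not in chains:
            chains[a.chain] = top.add_chain()
        key = (a.chain, a.residue_seq, a.residue_name)
        if key not in residues:
            residues[key] = top.add_residue(a.residue_name, chains[a.chain], resSeq=a.residue_seq)
        try:
            e = elem.get_by_symbol(a.element)
        except KeyError:
            e = elem.virtual
        top.add_atom(a.name, e, residues[key])
    return top


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> Path:
    """Write a trajectory as multi-model PDB or concatenated GRO frames.

    PDB stores coordinates at 3 decimals (round-trip error <= 5e-4 A);
    GRO at 3 decimals of nm (<= 5e-3 A).  Velocities are not written.
    """
    import mdtraj as md

    path = Path(path)
    if format is None:
        format = {".pdb": "pdb-multimodel", ".gro": "gro-series"}.get(path.suffix.lower())
        if format is None:
            raise TrajectoryFormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format not in ("pdb-multimodel", "gro-series"):
        raise TrajectoryFormatError(f"unknown format {format!r}")

    lengths = None
    angles = None
    if traj.box is not None:
        lengths = np.tile(traj.box / _NM_TO_ANGSTROM, (traj.n_frames, 1))
        angles = np.full((traj.n_frames, 3), 90.0)
    mtraj = md.Trajectory(
        xyz=traj.coords / _NM_TO_ANGSTROM,
        topology=_mdtraj_topology(traj),
        time=traj.times,
        unitcell_lengths=lengths,
        unitcell_angles=angles,
    )
    if format == "pdb-multimodel":
        mtraj.save_pdb(str(path))
    else:
        mtraj.save_gro(str(path))
    return path


# ---------------------------------------------------------------------------
# Selections

_BACKBONE_NAMES = ("N", "CA", "C", "O")


def select_atoms(
    traj: Trajectory,
    query: str,
    residue_range: tuple[int, int] | None = None,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Resolve a named selection to a sorted array of atom indices.

    ``query`` is one of ``all-protein``, ``backbone`` (N, CA, C, O),
    ``calpha``, ``water-oxygen``, ``residue-range`` (needs
    ``residue_range``, inclusive) and ``named-atoms`` (needs ``names``;
    may be combined with ``residue_range``).

    Raises
    ------
    ValueError
        If the query is unknown or the selection comes back empty.
    """
    out: list[int] = []
    names_up = {n.upper() for n in names} if names else None
    for a in traj.atoms:
        if query == "all-protein":
            ok = a.category == "protein"
        elif query == "backbone":
            ok = a.category == "protein" and a.name.upper() in _BACKBONE_NAMES
        elif query == "calpha":
            ok = a.category == "protein" and a.name.upper() == "CA"
        elif query == "water-oxygen":
            ok = a.category == "water" and a.element.upper() == "O"
        elif query == "residue-range":
            if residue_range is None:
                raise ValueError("residue-range query needs residue_range=(lo, hi)")
            ok = residue_range[0] <= a.residue_seq <= residue_range[1]
            if ok and names_up is not None:
                ok = a.name.upper() in names_up
        elif query == "named-atoms":
            if names_up is None:
                raise ValueError("named-atoms query needs names=[...]")
            ok = a.name.upper() in names_up
            if ok and residue_range is not None:
                ok = residue_range[0] <= a.residue_seq <= residue_range[1]
        else:
            raise ValueError(f"unknown selection query {query!r}")
        if ok:
            out.append(a.index)
    if not out:
        raise ValueError(f"selection {query!r} matched no atoms")
    return np.array(sorted(set(out)), dtype=int)


def water_molecules(traj: Trajectory) -> dict[tuple[str, int], list[int]]:
    """Group water atom indices by (chain, residue_seq) molecule key."""
    mols: dict[tuple[str, int], list[int]] = {}
    for a in traj.atoms:
        if a.category == "water":
            mols.setdefault((a.chain, a.residue_seq), []).append(a.index)
    return mols


def shell_waters(
    traj: Trajectory,
    frame: int,
    cutoff: float,
    any_atom: bool = False,
) -> ShellSelection:
    """Select hydration-shell waters around the protein at one frame.

    A water molecule belongs to the shell when its oxygen (default) or
    any of its atoms (``any_atom=True``) lies within ``cutoff`` angstrom
    of any protein atom.  Membership is decided per molecule; the
    molecule is reported through its oxygen index.  With a periodic box
    the minimum-image convention is used.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not (0 <= frame < traj.n_frames):
        raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
    protein_idx = [a.index for a in traj.atoms if a.category == "protein"]
    if not protein_idx:
        raise ValueError("trajectory contains no protein atoms")
    mols = water_molecules(traj)
    if not mols:
        raise ValueError("trajectory contains no water molecules")

    prot_xyz = traj.coords[frame, protein_idx]
    selected: list[int] = []
    for key, atom_ids in mols.items():
        oxy = [i for i in atom_ids if traj.atoms[i].element.upper() == "O"]
        if not oxy:
            warnings.warn(f"water molecule {key} has no oxygen; skipped")
            continue
        probe_ids = atom_ids if any_atom else oxy[:1]
        probe = traj.coords[frame, probe_ids]
        delta = probe[:, None, :] - prot_xyz[None, :, :]
        delta = traj.displacements_min_image(delta)
        dmin = np.sqrt((delta**2).sum(axis=2)).min()
        if dmin <= cutoff:
            selected.append(oxy[0])
    return ShellSelection(cutoff=cutoff, frame=frame, water_oxygen_indices=tuple(sorted(selected)))


def finite_difference_velocities(traj: Trajectory) -> Trajectory:
    """Derive velocities from positions by central differences.

    Interior frames use ``v(t) = (x(t+dt) - x(t-dt)) / (2 dt)`` (exact
    for quadratic motion, O(dt^2) otherwise); the first and last frames
    use one-sided differences.  The result is a copy flagged
    ``velocities_derived=True``.
    """
    if traj.n_frames < 3:
        raise ValueError(f"need >= 3 frames for finite differences, got {traj.n_frames}")
    if traj.velocities is not None:
        raise ValueError("trajectory already has velocities")
    x = traj.coords
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * traj.dt)
    v[0] = (x[1] - x[0]) / traj.dt
    v[-1] = (x[-1] - x[-2]) / traj.dt
    return replace(traj, velocities=v, velocities_derived=True)
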