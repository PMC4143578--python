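import numpy as np
import pytest

from thzdyn import (
    AtomRecord,
    HarmonicSpec,
    Trajectory,
    make_harmonic_trajectory,
)


def make_atoms(spec: list[tuple[str, str, int, str, str]]) -> list[AtomRecord]:
    """Build AtomRecords from (name, element, resseq, resname, category)."""
    return [
        AtomRecord(index=i, name=n, element=e, residue_seq=r,
                   residue_name=rn, chain="A", category=c)
        for i, (n, e, r, rn, c) in enumerate(spec)
    ]


def water(resseq: int) -> list[tuple[str, str, int, str, str]]:
    return [
        ("OW", "O", resseq, "HOH", "water"),
        ("HW1", "H", resseq, "HOH", "water"),
        ("HW2", "H", resseq, "HOH", "water"),
    ]


def place_water(origin: np.ndarray) -> np.ndarray:
    """Water geometry: O at origin, two H at 0.96 A, ~104.5 deg apart."""
    o = np.asarray(origin, dtype=float)
    h1 = o + 0.96 * np.array([1.0, 0.0, 0.0])
    h2 = o + 0.96 * np.array([np.cos(np.deg2rad(104.5)), np.sin(np.deg2rad(104.5)), 0.0])
    return np.stack([o, h1, h2])


@pytest.fixture
def two_mode_traj() -> Trajectory:
    """Harmonic trajectory with clean modes at 40 and 90 cm^-1."""
    return make_harmonic_trajectory(
        HarmonicSpec(
            modes=((40.0, 0.3, 0.0), (90.0, 0.2, 0.5)),
            dt=0.01, n_frames=4096, n_atoms=8, seed=11,
        )
    )


@pytest.fixture
def protein_water_traj() -> Trajectory:
    """Static 3-residue peptide-like chain plus 4 waters at set distances.

    Waters sit 2.5, 3.0, 4.0 and 6.0 A from the nearest protein atom, so
    shell membership at common cutoffs is known by construction.
    """
    atom_spec = []
    coords = []
    for r in range(3):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atom_spec.append((name, elem, r + 1, "ALA", "protein"))
            coords.append([3.8 * r + {"N": 0.0, "CA": 1.2, "C": 2.4, "O": 3.0}[name], 0.0, 0.0])
    for k, d in enumerate((2.5, 3.0, 4.0, 6.0)):
        atom_spec.extend(water(10 + k))
        coords.extend(place_water(np.array([3.0 * k, d, 0.0]) + np.array([0.0, 0.0, 0.0])))
    coords = np.asarray(coords)
    # distance from each water oxygen to the protein line y=0 is its y offset
    traj = Trajectory(
        atoms=make_atoms(atom_spec),
        coords=np.repeat(coords[None, :, :], 4, axis=0),
        dt=0.5,
    )
    return traj
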