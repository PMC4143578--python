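"""Synthetic trajectories, H-bond timelines and displacement fields with
known ground truth.

Every analysis stage in this package has a generator here whose output
is analytically predictable, so detectors, correlation functions and
spectra can be validated without running a molecular-dynamics engine:

* harmonic trajectories with prescribed vibrational wavenumbers (the
  clean-mode limit of protein collective motion),
* Ornstein-Uhlenbeck (Langevin) velocity baths with exponential VACF,
* two-state Markov hydrogen-bond occupancies with closed-form
  intermittent autocorrelation ``p + (1 - p) exp(-(k_on + k_off) tau)``,
* Gaussian residue displacement fields with a planted cross-correlation
  matrix,
* single-frame toy geometries with exactly placed hydrogen bonds.

All generators are bit-reproducible for a fixed (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .collective_motion import DisplacementField
from .hbond_dynamics import HBondCriteria, HBondTimeline, HBond
from .spectral_analysis import SPEED_OF_LIGHT_CM_PER_PS
from .trajectory_io import AtomRecord, Trajectory, write_trajectory

__all__ = [
    "HarmonicSpec",
    "MarkovHBondSpec",
    "CorrelatedFieldSpec",
    "HBondPlacement",
    "make_harmonic_trajectory",
    "make_langevin_trajectory",
    "make_markov_hbond_timeline",
    "make_correlated_displacements",
    "make_toy_hbond_frame",
    "write_fixture",
]


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class HarmonicSpec:
    """Sum-of-cosines atomic motion plus optional white positional noise.

    ``modes`` is a list of (wavenumber cm^-1, amplitude A, phase rad).
    Wavenumbers must sit below the Nyquist limit 1 / (2 dt c) cm^-1.
    """

    modes: tuple[tuple[float, float, float], ...]
    noise_sigma: float = 0.0
    dt: float = 0.01
    n_frames: int = 4096
    n_atoms: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        nyquist = 1.0 / (2.0 * self.dt) / SPEED_OF_LIGHT_CM_PER_PS
        for wn, amp, _ in self.modes:
            if not (0 < wn < nyquist):
                raise ValueError(
                    f"mode at {wn} cm^-1 violates Nyquist limit {nyquist:.1f} cm^-1 "
                    f"for dt={self.dt} ps"
                )
            if amp <= 0:
                raise ValueError("mode amplitudes must be positive")


@dataclass(frozen=True)
class MarkovHBondSpec:
    """Independent two-state (broken/formed) chains with rates in ps^-1.

    The stationary occupancy is ``p = k_on / (k_on + k_off)`` and the
    normalised intermittent ACF is ``p + (1 - p) exp(-(k_on+k_off) tau)``.
    """

    k_on: float
    k_off: float
    dt: float = 0.01
    n_frames: int = 100_000
    n_bonds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.dt * (self.k_on + self.k_off) >= 0.5:
            raise ValueError(
                "dt * (k_on + k_off) must be < 0.5 for a valid discretization"
            )

    @property
    def stationary_p(self) -> float:
        return self.k_on / (self.k_on + self.k_off)

    @property
    def relaxation_time(self) -> float:
        """1 / (k_on + k_off), the ACF decay time in ps."""
        return 1.0 / (self.k_on + self.k_off)


@dataclass(frozen=True)
class CorrelatedFieldSpec:
    """Gaussian displacement field with a planted correlation matrix."""

    target_C: tuple[tuple[float, ...], ...]
    n_frames: int = 10_000
    seed: int = 0

    def matrix(self) -> np.ndarray:
        C = np.asarray(self.target_C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("target_C must be square")
        if np.abs(C - C.T).max() > 1e-10:
            raise ValueError("target_C must be symmetric")
        if np.abs(np.diag(C) - 1.0).max() > 1e-10:
            raise ValueError("target_C must have unit diagonal")
        if C.min() < -1 - 1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("target_C entries must lie in [-1, 1]")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8:
            raise ValueError(
                f"target_C is not positive semidefinite (eigenvalue {w.min():.3g})"
            )
        return C


# ---------------------------------------------------------------------------
# Trajectory generators


def _grid_atoms(n_atoms: int, spacing: float = 5.0) -> tuple[list[AtomRecord], np.ndarray]:
    """One C-alpha pseudo-atom per residue, laid out on a cubic grid."""
    atoms: list[AtomRecord] = []
    base = np.empty((n_atoms, 3))
    side = int(np.ceil(n_atoms ** (1 / 3)))
    for i in range(n_atoms):
        atoms.append(
            AtomRecord(index=i, name="CA", element="C", residue_seq=i + 1,
                       residue_name="ALA", chain="A", category="protein")
        )
        base[i] = spacing * np.array([i % side, (i // side) % side, i // side**2])
    return atoms, base


def make_harmonic_trajectory(spec: HarmonicSpec) -> Trajectory:
    """Cosine-mode displacements with exact analytic velocities.

    Each atom oscillates along its own random unit direction with a
    random phase offset per mode, so atoms are decorrelated while every
    atom carries all modes.  White positional noise of ``noise_sigma``
    (A per coordinate) emulates a thermal bath; the stored velocities
    remain the analytic derivative of the noise-free motion.
    """
    rng = np.random.default_rng(spec.seed)
    atoms, base = _grid_atoms(spec.n_atoms)
    t = np.arange(spec.n_frames) * spec.dt  # (F,)

    dirs = rng.normal(size=(spec.n_atoms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    disp = np.zeros((spec.n_frames, spec.n_atoms))
    vel = np.zeros((spec.n_frames, spec.n_atoms))
    for wn, amp, phase in spec.modes:
        omega = 2.0 * np.pi * wn * SPEED_OF_LIGHT_CM_PER_PS  # rad/ps
        atom_phase = phase + rng.uniform(0, 2 * np.pi, size=spec.n_atoms)
        arg = omega * t[:, None] + atom_phase[None, :]
        disp += amp * np.cos(arg)
        vel += -amp * omega * np.sin(arg)

    coords = base[None, :, :] + disp[:, :, None] * dirs[None, :, :]
    velocities = vel[:, :, None] * dirs[None, :, :]
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0, spec.noise_sigma, size=coords.shape)
    return Trajectory(atoms=atoms, coords=coords, dt=spec.dt, velocities=velocities)


def make_langevin_trajectory(
    theta: float,
    sigma: float,
    dt: float = 0.01,
    n_frames: int = 10_000,
    n_atoms: int = 4,
    seed: int = 0,
) -> Trajectory:
    """Ornstein-Uhlenbeck velocity bath: broadband relaxational motion.

    Each velocity coordinate follows ``dv = -theta v dt + sigma dW``
    (exact discretization), started from the stationary distribution
    N(0, sigma^2 / (2 theta)), so the ensemble VACF is exp(-theta tau)
    from frame 0.  Positions are the Euler integral of the velocities.

    Parameters: ``theta`` ps^-1 (inverse correlation time), ``sigma``
    A ps^-3/2 (noise strength).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    atoms, base = _grid_atoms(n_atoms)
    stat_std = sigma / np.sqrt(2.0 * theta)
    decay = np.exp(-theta * dt)
    kick = stat_std * np.sqrt(1.0 - decay**2)
    v = np.empty((n_frames, n_atoms, 3))
    v[0] = rng.normal(0, stat_std, size=(n_atoms, 3))
    noise = rng.normal(size=(n_frames - 1, n_atoms, 3))
    for f in range(1, n_frames):
        v[f] = v[f - 1] * decay + kick * noise[f - 1]
    coords = base[None, :, :] + np.concatenate(
        [np.zeros((1, n_atoms, 3)), np.cumsum(v[:-1], axis=0) * dt]
    )
    return Trajectory(atoms=atoms, coords=coords, dt=dt, velocities=v)


# ---------------------------------------------------------------------------
# Markov H-bond timelines


def make_markov_hbond_timeline(spec: MarkovHBondSpec) -> HBondTimeline:
    """Independent two-state chains with exact per-step switch probabilities.

    Per step: broken -> formed with probability ``1 - exp(-k_on dt)``,
    formed -> broken with ``1 - exp(-k_off dt)``; initial states drawn
    from the stationary distribution.  Chains that never form a bond
    (possible at tiny k_on) are dropped so the timeline invariant
    (every bond present at least once) holds.
    """
    rng = np.random.default_rng(spec.seed)
    p_on = 1.0 - np.exp(-spec.k_on * spec.dt)
    p_off = 1.0 - np.exp(-spec.k_off * spec.dt)
    init = rng.random(spec.n_bonds) < spec.stationary_p
    occ = np.empty((spec.n_bonds, spec.n_frames), dtype=np.uint8)
    # sojourn times in each state are geometric (memoryless discrete
    # chain), so each bond is built from alternating geometric runs --
    # distributionally identical to stepping frame by frame
    for b in range(spec.n_bonds):
        state = bool(init[b])
        runs: list[np.ndarray] = []
        states: list[np.ndarray] = []
        total = 0
        while total < spec.n_frames:
            batch = 64
            r1 = rng.geometric(p_off if state else p_on, size=batch)
            r2 = rng.geometric(p_on if state else p_off, size=batch)
            lengths = np.empty(2 * batch, dtype=np.int64)
            lengths[0::2], lengths[1::2] = r1, r2
            svals = np.empty(2 * batch, dtype=np.uint8)
            svals[0::2], svals[1::2] = int(state), int(not state)
            runs.append(lengths)
            states.append(svals)
            total += int(lengths.sum())
        occ[b] = np.repeat(np.concatenate(states), np.concatenate(runs))[: spec.n_frames]
    alive = occ.any(axis=1)
    occ = occ[alive]
    bonds = [
        HBond(donor_heavy=3 * i, hydrogen=3 * i + 1, acceptor_heavy=3 * i + 2,
              bond_class="water-water")
        for i in range(occ.shape[0])
    ]
    return HBondTimeline(bonds=bonds, occupancy=occ, dt=spec.dt)


# ---------------------------------------------------------------------------
# Correlated displacement fields


def make_correlated_displacements(spec: CorrelatedFieldSpec) -> DisplacementField:
    """Gaussian field whose sample cross-correlation converges to target_C.

    White noise (residues x frames x 3) is coloured by the symmetric
    matrix square root of target_C, the same factor for the x, y and z
    components, which makes both the numerator and denominator of the
    cross-correlation coefficient analytically predictable.  The sample
    time mean is removed so the field satisfies the displacement-field
    contract exactly.
    """
    C = spec.matrix()
    rng = np.random.default_rng(spec.seed)
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    z = rng.normal(size=(C.shape[0], spec.n_frames, 3))
    x = np.einsum("ij,jfc->ifc", L, z)
    x -= x.mean(axis=1, keepdims=True)
    return DisplacementField(
        residue_ids=list(range(1, C.shape[0] + 1)),
        displacements=x,
        superposed=True,
    )


# ---------------------------------------------------------------------------
# Toy hydrogen-bond geometries


@dataclass(frozen=True)
class HBondPlacement:
    """One donor-H / acceptor pair placed at exact geometry.

    ``d_da`` is the donor-acceptor heavy distance (A), ``angle_deg`` the
    angle at the donor between D->H and D->A, ``r_covalent`` the
    covalent D-H length.  When ``d_ha`` (H...A distance) is given the
    covalent length is solved from the triangle instead; an infeasible
    combination raises.  ``donor_protein``/``acceptor_protein`` switch
    the molecule from water to a serine-like hydroxyl group.
    """

    d_da: float
    angle_deg: float
    r_covalent: float = 1.0
    d_ha: float | None = None
    donor_protein: bool = False
    acceptor_protein: bool = False

    def resolve(self) -> tuple[float, float]:
        """Return (covalent OH length, H...A distance)."""
        if self.d_da <= 0 or not (0 <= self.angle_deg < 90):
            raise ValueError(f"impossible geometry: d_da={self.d_da}, angle={self.angle_deg}")
        cos_t = np.cos(np.deg2rad(self.angle_deg))
        if self.d_ha is None:
            r = self.r_covalent
            d_ha = np.sqrt(r**2 + self.d_da**2 - 2 * r * self.d_da * cos_t)
        else:
            # law of cosines: d_ha^2 = r^2 + d_da^2 - 2 r d_da cos(theta)
            disc = self.d_da**2 * cos_t**2 - (self.d_da**2 - self.d_ha**2)
            if disc < 0:
                raise ValueError(
                    f"impossible geometry: no covalent length gives d_ha={self.d_ha}"
                )
            r = self.d_da * cos_t - np.sqrt(disc)
            if r <= 0:
                r = self.d_da * cos_t + np.sqrt(disc)
            d_ha = self.d_ha
        if not (0 < r <= 1.2):
            raise ValueError(
                f"impossible geometry: covalent OH length {r:.3f} A outside (0, 1.2]"
            )
        return float(r), float(d_ha)


def make_toy_hbond_frame(
    layout: Sequence[HBondPlacement],
    criteria: HBondCriteria | None = None,
    dt: float = 1.0,
) -> tuple[Trajectory, set[tuple[int, int, int]]]:
    """Single-frame geometry with an exactly known hydrogen-bond truth set.

    Each placement occupies its own cluster 30 A from the others, so no
    cross-cluster bonds arise.  The truth set of (donor, hydrogen,
    acceptor) index triples is computed from the placement numbers
    against ``criteria`` (default thresholds 3.5 A / 2.6 A / 30 deg,
    strict), never from the detector under test.
    """
    if criteria is None:
        criteria = HBondCriteria()
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    truth: set[tuple[int, int, int]] = set()

    def add_atom(name, element, resseq, resname, category, xyz) -> int:
        idx = len(atoms)
        atoms.append(AtomRecord(index=idx, name=name, element=element,
                                residue_seq=resseq, residue_name=resname,
                                chain="A", category=category))
        coords.append(np.asarray(xyz, dtype=float))
        return idx

    resseq = 0
    for k, plc in enumerate(layout):
        r_cov, d_ha = plc.resolve()
        origin = np.array([30.0 * k, 0.0, 0.0])
        theta = np.deg2rad(plc.angle_deg)

        resseq += 1
        if plc.donor_protein:
            d_idx = add_atom("OG", "O", resseq, "SER", "protein", origin)
            h_idx = add_atom(
                "HG", "H", resseq, "SER", "protein",
                origin + r_cov * np.array([np.cos(theta), np.sin(theta), 0.0]),
            )
        else:
            d_idx = add_atom("OW", "O", resseq, "HOH", "water", origin)
            h_idx = add_atom(
                "HW1", "H", resseq, "HOH", "water",
                origin + r_cov * np.array([np.cos(theta), np.sin(theta), 0.0]),
            )
            # second water hydrogen, pointing away from the acceptor
            add_atom("HW2", "H", resseq, "HOH", "water",
                     origin + 0.96 * np.array([-0.80, -0.60, 0.0]))

        resseq += 1
        acc_origin = origin + np.array([plc.d_da, 0.0, 0.0])
        resname, cat = ("SER", "protein") if plc.acceptor_protein else ("HOH", "water")
        a_idx = add_atom("OG" if plc.acceptor_protein else "OW", "O",
                         resseq, resname, cat, acc_origin)
        if not plc.acceptor_protein:
            # acceptor water hydrogens on the far side of the donor
            add_atom("HW1", "H", resseq, "HOH", "water",
                     acc_origin + 0.96 * np.array([0.94, 0.34, 0.0]))
            add_atom("HW2", "H", resseq, "HOH", "water",
                     acc_origin + 0.96 * np.array([0.94, -0.34, 0.0]))

        if (
            plc.d_da < criteria.max_heavy_distance
            and d_ha < criteria.max_OH_distance
            and plc.angle_deg < criteria.max_angle
        ):
            truth.add((d_idx, h_idx, a_idx))

    traj = Trajectory(atoms=atoms, coords=np.array(coords)[None, :, :], dt=dt)
    return traj, truth


def write_fixture(traj: Trajectory, path: str | Path, format: str | None = None) -> Path:
    """Write a synthetic trajectory as a PDB or GRO fixture file.

    Round-trip precision: PDB coordinates are stored at 3 decimals of A
    (error <= 5e-4 A); GRO at 3 decimals of nm (<= 5e-3 A).
    """
    return write_trajectory(traj, path, format)
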