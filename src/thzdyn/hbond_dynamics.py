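"""Geometric hydrogen-bond detection, occupancy timelines, the H-bond
autocorrelation function and exponential lifetime fits.

A hydrogen bond D-H...A is accepted when all three geometric conditions
hold simultaneously (strict inequalities):

* heavy-atom distance  d(D, A)   < 3.5 A,
* hydrogen-acceptor    d(H, A)   < 2.6 A,
* the angle at the donor between D->H and D->A  < 30 deg.

The intermittent H-bond autocorrelation function

    C_hb(tau) = < hb_i(t + tau) hb_i(t) > / < hb_i(t)^2 >

(with hb_i(t) in {0, 1}) is averaged over time origins and over bonds;
a bond broken and later re-formed keeps contributing, which makes the
long-lag decay sensitive to the re-formation kinetics.  Lifetimes come
from a least-squares fit of ``plateau + (1 - plateau) exp(-tau/tau0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spectral_analysis import CorrelationSeries, _acf_1d_fft
from .trajectory_io import Trajectory, shell_waters

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondTimeline",
    "LifetimeFit",
    "DonorAcceptorAssignment",
    "assign_donors_acceptors",
    "detect_hbonds_frame",
    "hbond_timeline",
    "hbacf",
    "fit_hbond_lifetime",
]

#: Maximum covalent H-heavy atom distance (A) used for donor assignment.
COVALENT_H_CUTOFF = 1.2

SCOPES = ("protein-protein", "protein-water", "water-water")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds; all comparisons are strict.

    ``angle_at`` selects the convention for the angular test: the
    default ``"donor"`` measures the angle between the D->H and D->A
    vectors (acceptance-cone convention matching the 30 deg magnitude);
    ``"hydrogen"`` measures the D-H...A angle deviation from linearity
    at the hydrogen instead.  ``heavy_distance_mode`` may be switched
    from heavy-atom pair distance to water molecular centre-of-mass
    distance (meaningful for water-water pairs only).
    """

    max_heavy_distance: float = 3.5
    max_OH_distance: float = 2.6
    max_angle: float = 30.0
    angle_at: str = "donor"
    heavy_distance_mode: str = "heavy-atom"

    def __post_init__(self) -> None:
        if min(self.max_heavy_distance, self.max_OH_distance, self.max_angle) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.max_angle >= 90:
            raise ValueError("max_angle must be < 90 degrees")
        if self.angle_at not in ("donor", "hydrogen"):
            raise ValueError("angle_at must be 'donor' or 'hydrogen'")
        if self.heavy_distance_mode not in ("heavy-atom", "water-com"):
            raise ValueError("heavy_distance_mode must be 'heavy-atom' or 'water-com'")


@dataclass(frozen=True)
class HBond:
    """One hydrogen bond identified by its (donor, hydrogen, acceptor)
    atom indices; hashable so it can key an occupancy timeline."""

    donor_heavy: int
    hydrogen: int
    acceptor_heavy: int
    bond_class: str = "water-water"

    def __post_init__(self) -> None:
        if self.donor_heavy == self.acceptor_heavy:
            raise ValueError("donor and acceptor heavy atoms must differ")
        if self.bond_class not in SCOPES:
            raise ValueError(f"unknown bond class {self.bond_class!r}")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.donor_heavy, self.hydrogen, self.acceptor_heavy)


@dataclass
class HBondTimeline:
    """Binary occupancy of every bond ever observed, bonds x frames."""

    bonds: list[HBond]
    occupancy: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy)
        if self.occupancy.ndim != 2 or self.occupancy.shape[0] != len(self.bonds):
            raise ValueError(
                f"occupancy must be (n_bonds, n_frames), got {self.occupancy.shape}"
            )
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_bonds(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[1]

    def mean_occupancy(self) -> float:
        return float(self.occupancy.mean())


@dataclass
class LifetimeFit:
    """Result of an exponential fit to a (normalised) H-bond ACF."""

    tau: float
    plateau: float
    fit_window: tuple[float, float]
    residual_rms: float


@dataclass
class DonorAcceptorAssignment:
    donors: np.ndarray          # heavy atoms with >= 1 bound hydrogen
    acceptors: np.ndarray       # all N/O heavy atoms
    hydrogen_to_donor: dict[int, int]

    @property
    def donor_hydrogen_pairs(self) -> list[tuple[int, int]]:
        return [(d, h) for h, d in sorted(self.hydrogen_to_donor.items())]


# ---------------------------------------------------------------------------
# Chemistry: who can donate / accept


def assign_donors_acceptors(traj: Trajectory, frame: int = 0) -> DonorAcceptorAssignment:
    """Map hydrogens to their donor heavy atom; list donors and acceptors.

    Donors are N/O heavy atoms with at least one hydrogen within 1.2 A
    in the given frame (covalent attachment is assumed static over the
    trajectory); acceptors are all N/O atoms.  A hydrogen with no heavy
    atom nearby is excluded with a warning.
    """
    heavy = np.array(
        [a.index for a in traj.atoms if a.element.upper() in ("N", "O")], dtype=int
    )
    hydrogens = np.array(
        [a.index for a in traj.atoms if a.element.upper() == "H"], dtype=int
    )
    h2d: dict[int, int] = {}
    if heavy.size and hydrogens.size:
        hx = traj.coords[frame, hydrogens]
        dx = traj.coords[frame, heavy]
        delta = hx[:, None, :] - dx[None, :, :]
        delta = traj.displacements_min_image(delta)
        dist = np.sqrt((delta**2).sum(axis=2))
        nearest = dist.argmin(axis=1)
        for i, h in enumerate(hydrogens):
            if dist[i, nearest[i]] <= COVALENT_H_CUTOFF:
                h2d[int(h)] = int(heavy[nearest[i]])
            else:
                warnings.warn(
                    f"hydrogen {h} has no N/O heavy atom within "
                    f"{COVALENT_H_CUTOFF} A; excluded from donor assignment"
                )
    donors = np.array(sorted(set(h2d.values())), dtype=int)
    return DonorAcceptorAssignment(donors=donors, acceptors=heavy, hydrogen_to_donor=h2d)


def _bond_class(traj: Trajectory, donor: int, acceptor: int) -> str:
    cats = {traj.atoms[donor].category, traj.atoms[acceptor].category}
    if cats == {"protein"}:
        return "protein-protein"
    if cats == {"water"}:
        return "water-water"
    return "protein-water"


def _water_com(traj: Trajectory, frame: int, oxygen: int) -> np.ndarray:
    """Approximate molecular centre of a water through its residue atoms."""
    a = traj.atoms[oxygen]
    members = [
        b.index
        for b in traj.atoms
        if b.category == "water" and b.residue_seq == a.residue_seq and b.chain == a.chain
    ]
    masses = np.array(
        [15.999 if traj.atoms[i].element.upper() == "O" else 1.008 for i in members]
    )
    xyz = traj.coords[frame, members]
    return (xyz * masses[:, None]).sum(axis=0) / masses.sum()


def detect_hbonds_frame(
    traj: Trajectory,
    frame: int,
    criteria: HBondCriteria | None = None,
    scope: str | None = None,
    assignment: DonorAcceptorAssignment | None = None,
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame by the geometric criterion.

    ``scope`` restricts results to one interaction class
    (``protein-protein``, ``protein-water`` or ``water-water``); the
    three classes partition the unfiltered detections.
    """
    if criteria is None:
        criteria = HBondCriteria()
    if scope is not None and scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    if assignment is None:
        assignment = assign_donors_acceptors(traj)
    pairs = assignment.donor_hydrogen_pairs
    acceptors = assignment.acceptors
    if not pairs or acceptors.size == 0:
        warnings.warn("no donors or acceptors in the system")
        return []

    xyz = traj.coords[frame]
    cos_max = np.cos(np.deg2rad(criteria.max_angle))
    out: list[HBond] = []
    for donor, hydrogen in pairs:
        da = traj.displacements_min_image(xyz[acceptors] - xyz[donor])
        d_da = np.linalg.norm(da, axis=1)
        ha = traj.displacements_min_image(xyz[acceptors] - xyz[hydrogen])
        d_ha = np.linalg.norm(ha, axis=1)
        dh = traj.displacements_min_image(xyz[hydrogen] - xyz[donor])

        if criteria.heavy_distance_mode == "water-com":
            for k, acc in enumerate(acceptors):
                if (
                    traj.atoms[donor].category == "water"
                    and traj.atoms[acc].category == "water"
                ):
                    d_da[k] = np.linalg.norm(
                        traj.displacements_min_image(
                            _water_com(traj, frame, int(acc))
                            - _water_com(traj, frame, donor)
                        )
                    )

        if criteria.angle_at == "donor":
            # angle at D between D->H and D->A
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (da @ dh) / (d_da * np.linalg.norm(dh))
        else:
            # deviation from linearity of D-H...A measured at H
            hd = -dh
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = -(ha @ hd) / (d_ha * np.linalg.norm(hd))
        ok = (
            (d_da < criteria.max_heavy_distance)
            & (d_ha < criteria.max_OH_distance)
            & (cosang > cos_max)
            & (acceptors != donor)
        )
        for k in np.nonzero(ok)[0]:
            acc = int(acceptors[k])
            cls = _bond_class(traj, donor, acc)
            if scope is None or cls == scope:
                out.append(
                    HBond(donor_heavy=donor, hydrogen=hydrogen,
                          acceptor_heavy=acc, bond_class=cls)
                )
    out.sort(key=lambda b: b.key)
    return out


def hbond_timeline(
    traj: Trajectory,
    criteria: HBondCriteria | None = None,
    scope: str | None = None,
    shell_cutoff: float | None = None,
) -> HBondTimeline:
    """Per-frame H-bond detection collected into a binary occupancy matrix.

    Bond identity is the (donor, hydrogen, acceptor) index triple; the
    bond list is the union over frames.  With ``scope="water-water"``
    and a ``shell_cutoff``, both partner oxygens must belong to the
    hydration shell of that frame (shell membership is re-evaluated per
    frame), which is how the interfacial water-water timeline of a
    protein hydration layer is built.
    """
    if criteria is None:
        criteria = HBondCriteria()
    assignment = assign_donors_acceptors(traj)
    seen: dict[tuple[int, int, int], HBond] = {}
    per_frame: list[set[tuple[int, int, int]]] = []
    for f in range(traj.n_frames):
        bonds = detect_hbonds_frame(traj, f, criteria, scope=scope, assignment=assignment)
        if shell_cutoff is not None and scope == "water-water":
            shell = set(shell_waters(traj, f, shell_cutoff).water_oxygen_indices)
            if not shell:
                warnings.warn(f"hydration shell empty at frame {f}")
            bonds = [
                b for b in bonds
                if b.donor_heavy in shell and b.acceptor_heavy in shell
            ]
        keys = set()
        for b in bonds:
            seen.setdefault(b.key, b)
            keys.add(b.key)
        per_frame.append(keys)
    bond_list = [seen[k] for k in sorted(seen)]
    occupancy = np.zeros((len(bond_list), traj.n_frames), dtype=np.uint8)
    index = {b.key: i for i, b in enumerate(bond_list)}
    for f, keys in enumerate(per_frame):
        for k in keys:
            occupancy[index[k], f] = 1
    return HBondTimeline(bonds=bond_list, occupancy=occupancy, dt=traj.dt)


# ---------------------------------------------------------------------------
# Kinetics


def hbacf(
    timeline: HBondTimeline,
    max_lag: float,
    averaging: str = "per-bond",
) -> CorrelationSeries:
    """Intermittent H-bond autocorrelation function of a timeline.

    For each bond the raw correlation ``<hb(t+tau) hb(t)>`` is averaged
    over all valid time origins (division by n - tau).  With
    ``averaging="per-bond"`` (default) each bond's curve is normalised
    by its own occupancy before averaging over bonds; ``"pooled"`` sums
    numerators and denominators across bonds first.  Either way
    C(0) = 1.
    """
    if averaging not in ("per-bond", "pooled"):
        raise ValueError("averaging must be 'per-bond' or 'pooled'")
    occ = timeline.occupancy.astype(float)
    n = timeline.n_frames
    n_lags = int(round(max_lag / timeline.dt)) + 1
    if n_lags >= n:
        raise ValueError(f"max_lag {max_lag} ps >= timeline duration")
    corr = _acf_1d_fft(occ, n_lags, "unbiased")
    # FFT correlation of 0/1 data: clean up negative rounding noise
    corr = np.clip(corr, 0.0, None)
    c0 = corr[:, 0]
    live = c0 > 0
    if not np.any(live):
        raise ValueError("timeline has no occupied frames")
    if averaging == "per-bond":
        values = (corr[live] / c0[live, None]).mean(axis=0)
    else:
        values = corr[live].sum(axis=0) / c0[live].sum()
    values[0] = 1.0
    return CorrelationSeries(
        lags=np.arange(n_lags) * timeline.dt,
        values=values,
        normalized=True,
        n_samples_per_lag=n - np.arange(n_lags),
        meta={"averaging": averaging, "n_bonds": int(live.sum()),
              "definition": "intermittent"},
    )


def fit_hbond_lifetime(
    acf: CorrelationSeries,
    fit_window: tuple[float, float] = (0.5, 8.0),
    free_plateau: bool = True,
) -> LifetimeFit:
    """Fit ``C(tau) = plateau + (1 - plateau) exp(-tau / tau0)``.

    The fit runs over lags inside ``fit_window`` (ps).  The plateau term
    absorbs the long-lag asymptote of intermittent kinetics (a bond in
    equilibrium re-forms, so C(inf) > 0); ``free_plateau=False`` forces
    a pure exponential through zero.

    Returns the fitted lifetime tau (ps), the plateau and the RMS
    residual over the window.
    """
    if not acf.normalized:
        raise ValueError("lifetime fit needs a normalized ACF")
    lo, hi = fit_window
    if lo < 0 or hi <= lo:
        raise ValueError(f"bad fit window {fit_window}")
    if hi > acf.lags[-1] + 1e-12:
        raise ValueError(
            f"fit window upper edge {hi} ps exceeds lag support {acf.lags[-1]} ps"
        )
    mask = (acf.lags >= lo) & (acf.lags <= hi)
    t, y = acf.lags[mask], acf.values[mask]
    if t.size < 3:
        raise ValueError("fewer than 3 points inside the fit window")
    if np.ptp(y) < 1e-10:
        raise ValueError("ACF shows no decay inside the fit window; nothing to fit")

    if free_plateau:
        def model(tau, tau0, p):
            return p + (1.0 - p) * np.exp(-tau / tau0)
        p0 = [max(0.5 * (lo + hi), 1e-3), max(float(y.min()), 0.0)]
        bounds = ([1e-6, 0.0], [np.inf, 1.0 - 1e-9])
    else:
        def model(tau, tau0):
            return np.exp(-tau / tau0)
        p0 = [max(0.5 * (lo + hi), 1e-3)]
        bounds = ([1e-6], [np.inf])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RuntimeError(
            f"lifetime fit failed to converge over {fit_window}: {exc}"
        ) from exc
    resid = y - model(t, *popt)
    return LifetimeFit(
        tau=float(popt[0]),
        plateau=float(popt[1]) if free_plateau else 0.0,
        fit_window=(float(lo), float(hi)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
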