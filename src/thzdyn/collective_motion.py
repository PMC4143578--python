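"""Correlated residue fluctuations: superposition, displacement fields,
cross-correlation matrices and networks, and essential-dynamics PCA.

The residue cross-correlation coefficient

    C_ij = < dr_i . dr_j > / ( <|dr_i|^2> <|dr_j|^2> )^(1/2)

is computed from Cartesian displacement vectors ``dr_i(t) = r_i(t) -
<r_i>`` of (by default) the C-alpha atoms, after a rigid-body
least-squares fit of every frame onto the mean structure removed global
rotation and translation.  C_ij = 1 means fully correlated motion,
-1 fully anti-correlated, 0 uncorrelated.  Thresholding |C_ij| yields a
residue network whose nodes carry the mean-square fluctuation amplitude.

PCA diagonalises the 3N x 3N covariance of the superposed C-alpha
coordinates; per-residue square fluctuations of a mode are the squared
mode components summed per residue and scaled by the eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory_io import Trajectory, select_atoms

__all__ = [
    "DisplacementField",
    "CrossCorrMatrix",
    "CorrelationNetwork",
    "PCAResult",
    "superpose",
    "displacement_field",
    "cross_correlation_matrix",
    "build_network",
    "pca_modes",
    "project_trajectory",
]


@dataclass
class DisplacementField:
    """Mean-free residue displacement vectors, residues x frames x 3 (A)."""

    residue_ids: list[int]
    displacements: np.ndarray
    superposed: bool = True

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if (
            self.displacements.ndim != 3
            or self.displacements.shape[0] != len(self.residue_ids)
            or self.displacements.shape[2] != 3
        ):
            raise ValueError(
                f"displacements must be (residues, frames, 3), got {self.displacements.shape}"
            )
        mean = self.displacements.mean(axis=1)
        if np.abs(mean).max() > 1e-10:
            raise ValueError("per-residue time mean of displacements must be 0")

    @property
    def n_frames(self) -> int:
        return self.displacements.shape[1]

    def amplitudes(self) -> np.ndarray:
        """Mean-square fluctuation <|dr_i|^2> per residue (A^2)."""
        return (self.displacements**2).sum(axis=2).mean(axis=1)


@dataclass
class CrossCorrMatrix:
    residue_ids: list[int]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.residue_ids)
        if self.C.shape != (n, n):
            raise ValueError(f"C must be {n}x{n}, got {self.C.shape}")
        if np.abs(self.C - self.C.T).max() > 1e-12:
            raise ValueError("C must be symmetric")
        if np.abs(np.diag(self.C) - 1.0).max() > 1e-10:
            raise ValueError("diagonal of C must be 1")
        if self.C.min() < -1 - 1e-10 or self.C.max() > 1 + 1e-10:
            raise ValueError("entries of C must lie in [-1, 1]")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(str(r) for r in self.residue_ids) + "\n")
            for rid, row in zip(self.residue_ids, self.C):
                fh.write(str(rid) + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
        return path


@dataclass
class CorrelationNetwork:
    """Thresholded correlation graph; a thin wrapper over networkx."""

    graph: nx.Graph
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def to_edge_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# residue_i\tresidue_j\tweight\tsign\n")
            for i, j, data in sorted(self.graph.edges(data=True)):
                fh.write(f"{i}\t{j}\t{data['weight']:.8g}\t{data['sign']:+d}\n")
        return path

    def to_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        nx.write_graphml(self.graph, path)
        return path


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of C-alpha motion.

    ``modes`` columns are orthonormal vectors over the 3N coordinates;
    ``eigenvalues`` (A^2, descending) are the variances along them.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray  # (3N, n_modes), columns orthonormal
    mean_structure: np.ndarray  # (N, 3)
    residue_ids: list[int]
    projections: np.ndarray  # (frames, n_modes)
    selection: np.ndarray

    def square_fluctuations(self, mode_index: int = 0) -> np.ndarray:
        """Per-residue contribution (A^2) of one mode: eigenvalue times
        the squared mode components summed over x, y, z."""
        v = self.modes[:, mode_index].reshape(-1, 3)
        return self.eigenvalues[mode_index] * (v**2).sum(axis=1)


# ---------------------------------------------------------------------------
# Superposition


def _kabsch_fit(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning ``mobile`` onto ``ref``."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def superpose(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    reference: str = "mean",
) -> Trajectory:
    """Rigid-body least-squares fit of every frame onto a reference.

    The optimal rotation/translation is computed over ``selection``
    (default: C-alpha atoms) and applied to all atoms.  With
    ``reference="mean"`` frames are first fitted to frame 0, the mean of
    the fitted selection is taken as the reference, and the original
    frames are fitted once more onto that mean.  ``"frame0"`` fits
    directly onto the first frame.
    """
    if reference not in ("mean", "frame0"):
        raise ValueError("reference must be 'mean' or 'frame0'")
    sel = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else select_atoms(traj, "calpha")
    )
    if sel.size < 3:
        raise ValueError("superposition needs >= 3 atoms")
    probe = traj.coords[0, sel] - traj.coords[0, sel].mean(axis=0)
    if np.linalg.matrix_rank(probe, tol=1e-8) < 2:
        raise ValueError("selection is degenerate (collinear or coincident atoms)")

    def fit_all(ref_sel: np.ndarray) -> np.ndarray:
        out = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            R, mc, rc = _kabsch_fit(traj.coords[f, sel], ref_sel)
            out[f] = (traj.coords[f] - mc) @ R.T + rc
        return out

    if reference == "frame0":
        fitted = fit_all(traj.coords[0, sel])
    else:
        first_pass = fit_all(traj.coords[0, sel])
        fitted = fit_all(first_pass[:, sel].mean(axis=0))
    return replace(traj, coords=fitted, velocities=None, velocities_derived=False)


def displacement_field(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose_first: bool = True,
) -> DisplacementField:
    """Residue displacement vectors dr_i(t) = r_i(t) - <r_i> (A).

    ``selection`` defaults to the C-alpha atoms, one per residue.
    """
    if traj.n_frames < 2:
        raise ValueError("displacement field needs >= 2 frames")
    sel = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else select_atoms(traj, "calpha")
    )
    if sel.size == 0:
        raise ValueError("empty selection")
    if superpose_first:
        traj = superpose(traj, sel, reference="mean")
    coords = traj.coords[:, sel, :]  # (F, R, 3)
    disp = coords - coords.mean(axis=0, keepdims=True)
    return DisplacementField(
        residue_ids=[traj.atoms[i].residue_seq for i in sel],
        displacements=disp.transpose(1, 0, 2),
        superposed=superpose_first,
    )


# ---------------------------------------------------------------------------
# Cross-correlation and networks


def cross_correlation_matrix(field: DisplacementField) -> CrossCorrMatrix:
    """Normalised covariance of residue displacement vectors.

    The numerator is the time-averaged full 3-vector dot product
    ``<dr_i . dr_j>``.  Residues with zero variance get a zeroed
    row/column (diagonal kept at 1) with a warning, so the matrix stays
    usable for network construction.
    """
    if field.n_frames < 2:
        raise ValueError("need >= 2 frames")
    d = field.displacements  # (R, F, 3)
    flat = d.reshape(d.shape[0], -1)
    cov = flat @ flat.T / field.n_frames
    var = np.diag(cov).copy()
    dead = var <= 1e-14
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} zero-variance residue(s); correlations zeroed")
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    return CrossCorrMatrix(residue_ids=list(field.residue_ids), C=C)


def build_network(
    C: CrossCorrMatrix,
    field: DisplacementField | None = None,
    threshold: float = 0.35,
    keep_isolated: bool = False,
) -> CorrelationNetwork:
    """Threshold |C_ij| into a residue graph.

    Edges connect residue pairs with ``|C_ij| >= threshold``; the edge
    weight is |C_ij| with the sign of C_ij kept as an attribute.  Node
    amplitudes are the mean-square fluctuations from ``field`` when
    given.  Isolated nodes are dropped unless ``keep_isolated``.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    amps = field.amplitudes() if field is not None else None
    g = nx.Graph()
    ids = C.residue_ids
    if keep_isolated:
        for k, rid in enumerate(ids):
            g.add_node(rid, amplitude=float(amps[k]) if amps is not None else 1.0)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(C.C[i, j])
            if w >= threshold:
                for k in (i, j):
                    if ids[k] not in g:
                        g.add_node(
                            ids[k], amplitude=float(amps[k]) if amps is not None else 1.0
                        )
                g.add_edge(
                    ids[i], ids[j], weight=float(w),
                    sign=int(np.sign(C.C[i, j])) or 1,
                )
    return CorrelationNetwork(graph=g, threshold=threshold)


# ---------------------------------------------------------------------------
# PCA


def pca_modes(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose_first: bool = True,
    n_modes: int | None = None,
) -> PCAResult:
    """Eigendecomposition of the 3N x 3N C-alpha covariance matrix.

    Unweighted (no masses).  Eigenvalues are in A^2, descending; mode
    projections of the input trajectory are returned alongside, and the
    variance of projection k equals eigenvalue k by construction.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs >= 2 frames")
    sel = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else select_atoms(traj, "calpha")
    )
    if superpose_first:
        traj = superpose(traj, sel, reference="mean")
    coords = traj.coords[:, sel, :]
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    if n_frames <= 3 * n_atoms:
        warnings.warn(
            f"{n_frames} frames for {3 * n_atoms} coordinates: covariance is rank-deficient"
        )
    mean = coords.mean(axis=0)
    X = (coords - mean).reshape(n_frames, -1)  # (F, 3N)
    cov = X.T @ X / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_modes is not None:
        evals, evecs = evals[:n_modes], evecs[:, :n_modes]
    return PCAResult(
        eigenvalues=evals,
        modes=evecs,
        mean_structure=mean,
        residue_ids=[traj.atoms[i].residue_seq for i in sel],
        projections=X @ evecs,
        selection=sel,
    )


def project_trajectory(
    traj: Trajectory,
    pca: PCAResult,
    mode_index: int,
    superpose_first: bool = True,
) -> np.ndarray:
    """Project a trajectory onto one PCA mode (time series, A).

    The trajectory is fitted frame-by-frame onto the PCA mean structure
    over the same selection, centred on that mean and projected.  For
    the trajectory the PCA was built from this reproduces the stored
    projections; the variance of the series equals the eigenvalue.
    """
    if not (0 <= mode_index < pca.modes.shape[1]):
        raise ValueError(f"mode_index {mode_index} out of range")
    sel = pca.selection
    if sel.max() >= traj.n_atoms:
        raise ValueError("trajectory does not cover the PCA selection")
    coords = traj.coords[:, sel, :]
    if superpose_first:
        fitted = np.empty_like(coords)
        for f in range(coords.shape[0]):
            R, mc, rc = _kabsch_fit(coords[f], pca.mean_structure)
            fitted[f] = (coords[f] - mc) @ R.T + rc
        coords = fitted
    X = (coords - pca.mean_structure).reshape(coords.shape[0], -1)
    return X @ pca.modes[:, mode_index]
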