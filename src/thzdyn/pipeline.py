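"""Stage orchestration: the two study workflows plus collective motion.

Three runners compose the analysis modules into reproducible pipelines:

* :func:`run_protein_modes` — VACF of a protein selection, its
  wavenumber spectrum and a peak table (optionally a per-temperature
  trend classification).
* :func:`run_hydration_kinetics` — interfacial water-water H-bond
  timeline inside a hydration shell, the intermittent HBACF, an
  exponential lifetime fit and the HBACF spectrum in a band.
* :func:`run_collective` — residue cross-correlation matrix, the
  thresholded correlation network and PCA square fluctuations.

Configs are plain dictionaries (or YAML files) with units spelled out
in the key names (``shell_cutoff_angstrom``, ``dt_ps``, ...).  Every
runner writes TSV/GraphML stage outputs plus a single JSON report that
echoes the full config and the seed, so a report is exactly
reproducible from its own metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .collective_motion import (
    build_network,
    cross_correlation_matrix,
    displacement_field,
    pca_modes,
)
from .hbond_dynamics import (
    HBondCriteria,
    fit_hbond_lifetime,
    hbacf,
    hbond_timeline,
)
from .spectral_analysis import (
    classify_peak_trend,
    find_peaks,
    spectrum_from_acf,
    vacf,
)
from .synthetic_data import (
    CorrelatedFieldSpec,
    HarmonicSpec,
    MarkovHBondSpec,
    make_correlated_displacements,
    make_harmonic_trajectory,
    make_markov_hbond_timeline,
)
from .trajectory_io import Trajectory, read_trajectory, select_atoms

__all__ = [
    "PipelineError",
    "RunReport",
    "load_config",
    "run_protein_modes",
    "run_hydration_kinetics",
    "run_collective",
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Parameter echo, stage outputs and summary tables of one run."""

    workflow: str
    config: dict
    seed: int | None
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    tables: dict[str, Any] = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dictionary."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} does not contain a mapping")
    return cfg


def _resolve_trajectory(cfg: dict, stage: str) -> Trajectory:
    """Load a trajectory from ``input`` or build one from ``synthetic``."""
    if "input" in cfg:
        inp = cfg["input"]
        if "path" not in inp:
            raise PipelineError(stage, "input config needs a 'path'")
        return read_trajectory(
            inp["path"], format=inp.get("format"), dt=inp.get("dt_ps")
        )
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        kind = syn.pop("kind", "harmonic")
        if kind != "harmonic":
            raise PipelineError(stage, f"unknown synthetic trajectory kind {kind!r}")
        if "dt_ps" not in syn:
            raise PipelineError(stage, "synthetic trajectory config needs dt_ps")
        spec = HarmonicSpec(
            modes=tuple(tuple(m) for m in syn["modes_cm1_amp_phase"]),
            noise_sigma=syn.get("noise_sigma_angstrom", 0.0),
            dt=syn["dt_ps"],
            n_frames=syn.get("n_frames", 4096),
            n_atoms=syn.get("n_atoms", 8),
            seed=syn.get("seed", cfg.get("seed", 0)),
        )
        return make_harmonic_trajectory(spec)
    raise PipelineError(stage, "config needs an 'input' or 'synthetic' section")


def _outdir(cfg: dict, stage: str) -> Path:
    if "outdir" not in cfg:
        raise PipelineError(stage, "config needs an 'outdir'")
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# Workflows


def run_protein_modes(cfg: dict) -> RunReport:
    """VACF -> spectrum -> peak table for a protein atom selection."""
    stage = "protein-modes"
    out = _outdir(cfg, stage)
    traj = _resolve_trajectory(cfg, stage)
    selection_query = cfg.get("selection", "backbone")
    try:
        sel = select_atoms(traj, selection_query)
    except ValueError:
        if selection_query != "backbone":
            raise
        # synthetic C-alpha-only systems have no full backbone
        sel = select_atoms(traj, "calpha")
    max_lag = cfg.get("max_lag_ps", min(20.0, 0.25 * (traj.n_frames - 1) * traj.dt))
    window = cfg.get("window", "hann")
    zero_pad = cfg.get("zero_pad_factor", 4)
    band = tuple(cfg.get("band_cm1", (5.0, 250.0)))
    min_prom = cfg.get("min_prominence", 0.05)

    acf = vacf(traj, sel, max_lag=max_lag)
    spec = spectrum_from_acf(acf, window=window, zero_pad_factor=zero_pad)
    peaks = find_peaks(spec, min_prominence=min_prom, band=band)

    report = RunReport(
        workflow=stage,
        config=cfg,
        seed=cfg.get("seed"),
        version=__version__,
        tables={
            "peaks_cm1": [
                {"position_cm1": p.position, "height": p.height, "prominence": p.prominence}
                for p in peaks.peaks
            ],
            "n_atoms_averaged": acf.meta.get("n_atoms"),
            "spectrum_bin_width_cm1": spec.bin_width,
        },
    )
    report.outputs["vacf_tsv"] = str(acf.to_tsv(out / "vacf.tsv"))
    report.outputs["spectrum_tsv"] = str(spec.to_tsv(out / "vacf_spectrum.tsv"))
    if "peak_positions_by_temperature" in cfg:
        report.tables["peak_trend"] = classify_peak_trend(
            [tuple(x) for x in cfg["peak_positions_by_temperature"]],
            shift_tolerance=cfg.get("shift_tolerance_cm1", 2.0),
        )
    report.save(out / "report.json")
    report.outputs["report_json"] = str(out / "report.json")
    return report


def run_hydration_kinetics(cfg: dict) -> RunReport:
    """Shell H-bond timeline -> HBACF -> lifetime fit -> HBACF spectrum.

    A ``synthetic`` section with ``kind: markov`` bypasses geometric
    detection and feeds a two-state timeline with known rates straight
    into the kinetics stages (the ground-truth route).
    """
    stage = "hydration-kinetics"
    out = _outdir(cfg, stage)

    syn = cfg.get("synthetic", {})
    if syn.get("kind") == "markov":
        spec = MarkovHBondSpec(
            k_on=syn["k_on_per_ps"],
            k_off=syn["k_off_per_ps"],
            dt=syn.get("dt_ps", 0.01),
            n_frames=syn.get("n_frames", 100_000),
            n_bonds=syn.get("n_bonds", 100),
            seed=syn.get("seed", cfg.get("seed", 0)),
        )
        timeline = make_markov_hbond_timeline(spec)
        scope_counts: dict[str, int] = {}
    else:
        traj = _resolve_trajectory(cfg, stage)
        criteria = HBondCriteria(
            max_heavy_distance=cfg.get("max_heavy_distance_angstrom", 3.5),
            max_OH_distance=cfg.get("max_oh_distance_angstrom", 2.6),
            max_angle=cfg.get("max_angle_deg", 30.0),
        )
        shell = cfg.get("shell_cutoff_angstrom", 3.8)
        timeline = hbond_timeline(
            traj, criteria, scope="water-water", shell_cutoff=shell
        )
        if timeline.n_bonds == 0:
            raise PipelineError(
                stage,
                f"no interfacial water-water H-bonds inside the {shell} A shell; "
                "check the shell cutoff and water residue names",
            )
        scope_counts = {
            s: len(hbond_timeline(traj, criteria, scope=s).bonds)
            for s in ("protein-protein", "protein-water", "water-water")
        }

    max_lag = cfg.get("max_lag_ps", min(20.0, 0.25 * (timeline.n_frames - 1) * timeline.dt))
    acf = hbacf(timeline, max_lag=max_lag)
    band = tuple(cfg.get("band_cm1", (10.0, 160.0)))
    spec_out = spectrum_from_acf(acf)
    fit_window = tuple(cfg.get("fit_window_ps", (0.5, min(8.0, max_lag))))

    if np.ptp(acf.values) < 1e-10:
        raise PipelineError(
            stage, "HBACF is constant (static bonds); no kinetics to fit"
        )
    fit = fit_hbond_lifetime(acf, fit_window=fit_window)

    report = RunReport(
        workflow=stage,
        config=cfg,
        seed=cfg.get("seed"),
        version=__version__,
        tables={
            "lifetime_ps": fit.tau,
            "plateau": fit.plateau,
            "fit_residual_rms": fit.residual_rms,
            "n_bonds": timeline.n_bonds,
            "mean_occupancy": timeline.mean_occupancy(),
            "scope_bond_counts": scope_counts,
            "spectrum_band_cm1": list(band),
        },
    )
    report.outputs["hbacf_tsv"] = str(acf.to_tsv(out / "hbacf.tsv"))
    report.outputs["hbacf_spectrum_tsv"] = str(spec_out.to_tsv(out / "hbacf_spectrum.tsv"))
    report.save(out / "report.json")
    report.outputs["report_json"] = str(out / "report.json")
    return report


def run_collective(cfg: dict) -> RunReport:
    """Cross-correlation matrix -> network; PCA square fluctuations."""
    stage = "collective"
    out = _outdir(cfg, stage)
    threshold = cfg.get("network_threshold", 0.35)
    if not (0 < threshold <= 1):
        raise PipelineError(stage, f"network threshold {threshold} outside (0, 1]")

    syn = cfg.get("synthetic", {})
    pca = None
    if syn.get("kind") == "correlated-field":
        spec = CorrelatedFieldSpec(
            target_C=tuple(tuple(row) for row in syn["target_C"]),
            n_frames=syn.get("n_frames", 10_000),
            seed=syn.get("seed", cfg.get("seed", 0)),
        )
        fld = make_correlated_displacements(spec)
    else:
        traj = _resolve_trajectory(cfg, stage)
        if traj.n_frames < 100:
            warnings.warn(f"only {traj.n_frames} frames; correlations will be noisy")
        sel = select_atoms(traj, cfg.get("selection", "calpha"))
        fld = displacement_field(traj, sel, superpose_first=cfg.get("superpose", True))
        pca = pca_modes(traj, sel, superpose_first=cfg.get("superpose", True))

    C = cross_correlation_matrix(fld)
    net = build_network(C, fld, threshold=threshold)

    report = RunReport(
        workflow=stage,
        config=cfg,
        seed=cfg.get("seed"),
        version=__version__,
        tables={
            "n_residues": len(C.residue_ids),
            "network_threshold": threshold,
            "network_edges": net.n_edges,
            "network_nodes": net.graph.number_of_nodes(),
        },
    )
    report.outputs["dccm_tsv"] = str(C.to_tsv(out / "dccm.tsv"))
    report.outputs["network_edges_tsv"] = str(net.to_edge_tsv(out / "network_edges.tsv"))
    report.outputs["network_graphml"] = str(net.to_graphml(out / "network.graphml"))
    if pca is not None:
        sq = pca.square_fluctuations(0)
        with open(out / "pc1_square_fluctuations.tsv", "w") as fh:
            fh.write("# residue\tsquare_fluctuation_A2\n")
            for rid, v in zip(pca.residue_ids, sq):
                fh.write(f"{rid}\t{v:.8g}\n")
        report.outputs["pc1_square_fluctuations_tsv"] = str(
            out / "pc1_square_fluctuations.tsv"
        )
        report.tables["pca_eigenvalues_A2"] = pca.eigenvalues[:10].tolist()
        report.tables["pc1_top_residue"] = int(pca.residue_ids[int(np.argmax(sq))])
    report.save(out / "report.json")
    report.outputs["report_json"] = str(out / "report.json")
    return report
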