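"""End-to-end workflow: features → tICA → microstates → MSM → macrostates →
transition-path kinetics → reports.

A single :class:`PipelineConfig` drives the whole analysis.  Three input
modalities are supported: structural (PDB topology + DCD/XTC frames),
feature CSV (skip featurization), and pure discrete trajectories (skip
everything up to counting, so the kinetics half runs without structural
files).  The estimation lag (transition-matrix fit) and the analysis lag
(fluxes, barriers, MFPTs) are independent settings.

Every stage persists its artifact; rerunning with the same config and
inputs reproduces identical outputs except for the report timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import features as feat
from . import kinetics as kin
from . import msm as msmlib
from .trajectory import read_trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineStageError",
           "run_pipeline", "write_reports"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the workflow; defaults follow common MSM practice
    (4 tICA dimensions, 500 microstates) scaled by the user to the data."""

    # inputs (exactly one modality)
    topology: str | None = None
    trajectories: list[str] = field(default_factory=list)
    feature_csv: str | None = None
    dtraj_files: list[str] = field(default_factory=list)
    frame_interval_ns: float = 1.0
    # embedding / clustering
    tica_lag_frames: int = 10
    tica_dim: int = 4
    k_microstates: int = 500
    # estimation / analysis
    estimation_lag_ns: float = 1.0
    analysis_lag_ns: float | None = None
    n_macrostates: int = 2
    reversible: bool = True
    temperature_K: float = 300.0
    n_total: int | None = None
    its_lags_frames: list[int] = field(default_factory=list)
    # bookkeeping
    seed: int = 0
    out_dir: str = "kinemsm_output"

    def __post_init__(self):
        if self.analysis_lag_ns is None:
            self.analysis_lag_ns = self.estimation_lag_ns
        modes = [bool(self.topology), bool(self.feature_csv), bool(self.dtraj_files)]
        if sum(modes) != 1:
            raise ValueError(
                "exactly one input modality required: topology+trajectories, "
                "feature_csv, or dtraj_files")
        if self.tica_lag_frames < 1:
            raise ValueError("tica_lag_frames must be >= 1")
        if self.estimation_lag_ns < self.frame_interval_ns:
            raise ValueError("estimation lag must be >= one frame interval")
        if self.analysis_lag_ns < self.frame_interval_ns:
            raise ValueError("analysis lag must be >= one frame interval")
        if self.n_macrostates < 2:
            raise ValueError("n_macrostates must be >= 2")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def lag_frames(self, lag_ns: float) -> int:
        lag = int(round(lag_ns / self.frame_interval_ns))
        return max(lag, 1)


@dataclass
class RunReport:
    config: PipelineConfig
    stages: dict
    populations: np.ndarray
    mfpt: "object"            # pandas DataFrame (µs)
    barriers: "object"        # pandas DataFrame
    basins: tuple
    network: kin.KineticNetwork
    profiles: dict
    warnings: list
    provenance: dict


def _matrix_json(M: np.ndarray) -> dict:
    M = np.asarray(M)
    return {"shape": list(M.shape), "data": M.ravel().tolist()}


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig, warnings_list: list):
    """Returns (features | None, dtraj | None, trajectory | None)."""
    if config.dtraj_files:
        segs = [np.loadtxt(p, dtype=np.int64).reshape(-1) for p in config.dtraj_files]
        dtraj = msmlib.DiscreteTrajectory(segs, config.frame_interval_ns)
        return None, dtraj, None
    if config.feature_csv:
        fm = feat.read_feature_csv(config.feature_csv, config.frame_interval_ns)
        return fm, None, None
    traj = read_trajectory(config.topology, config.trajectories or None,
                           config.frame_interval_ns)
    return feat.compute_backbone_dihedrals(traj, encoding="sincos"), None, traj


def _remap_assignment(est_model, ana_model, assignment, warnings_list):
    """Carry the macrostate definition onto a model estimated at another lag."""
    if np.array_equal(est_model.active_set, ana_model.active_set):
        pops = np.array([ana_model.pi[assignment.crisp == j].sum()
                         for j in range(assignment.n_macrostates)])
        return msmlib.MacroAssignment(chi=assignment.chi, crisp=assignment.crisp,
                                      populations=pops / pops.sum())
    pos = {int(o): i for i, o in enumerate(est_model.active_set)}
    crisp = np.empty(ana_model.n_states, dtype=int)
    for i, orig in enumerate(ana_model.active_set):
        if int(orig) not in pos:
            raise ValueError(
                f"microstate {int(orig)} in the analysis model is absent from "
                "the estimation model's active set")
        crisp[i] = assignment.crisp[pos[int(orig)]]
    present = np.unique(crisp)
    if present.size < assignment.n_macrostates:
        warnings_list.append(
            "analysis-lag model lost microstates of some macrostate(s); "
            f"macrostates present: {present.tolist()}")
    chi = np.eye(assignment.n_macrostates)[crisp]
    pops = np.array([ana_model.pi[crisp == j].sum()
                     for j in range(assignment.n_macrostates)])
    return msmlib.MacroAssignment(chi=chi, crisp=crisp, populations=pops / pops.sum())


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and write all artifacts under ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    if not os.access(config.out_dir, os.W_OK):
        raise PipelineStageError("setup", PermissionError(config.out_dir))
    stages: dict = {}
    warns: list[str] = []
    out = config.out_dir
    t_start = time.time()

    def _stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # abort with stage name, keep partial outputs
            with open(os.path.join(out, f"FAILED_{name}.txt"), "w") as fh:
                fh.write(f"{type(exc).__name__}: {exc}\n")
            raise PipelineStageError(name, exc) from exc
        stages.setdefault(name, {})["elapsed_s"] = round(time.time() - t0, 3)
        logger.info("stage %-12s done in %.2fs", name, time.time() - t0)
        return result

    features_fm, dtraj, traj = _stage("load", lambda: _load_inputs(config, warns))

    profiles: dict = {}
    if traj is not None:
        def _profiles():
            from .synthetic import generate_native_reference

            ref = generate_native_reference(traj, frame=0)
            q_series, qi = feat.compute_native_contact_fraction(traj, ref)
            return {
                "helicity": feat.compute_helicity(traj),
                "entropy": feat.compute_dihedral_entropy(traj),
                "qi": qi,
                "q_series": q_series,
                "rmsd_series": feat.compute_rmsd(traj, ref_frame=0),
            }
        profiles = _stage("profiles", _profiles)

    if dtraj is None:
        def _tica():
            model = msmlib.fit_tica(features_fm, config.tica_lag_frames,
                                    min(config.tica_dim, features_fm.values.shape[1]))
            proj = model.transform(features_fm.values)
            with open(os.path.join(out, "tica.json"), "w") as fh:
                json.dump({"eigenvalues": model.eigenvalues.tolist(),
                           "mean": model.mean.tolist(),
                           "components": _matrix_json(model.components),
                           "lag_frames": model.lag_frames, "dim": model.dim,
                           "config_hash": config.config_hash()}, fh)
            stages["tica"] = {"eigenvalues": model.eigenvalues[:8].tolist()}
            return model, proj
        tica_model, proj = _stage("tica", _tica)

        def _cluster():
            micro, dt = msmlib.cluster_kmeans(
                proj, min(config.k_microstates, proj.shape[0]), seed=config.seed,
                frame_interval_ns=config.frame_interval_ns,
                boundaries=features_fm.boundaries)
            np.savetxt(os.path.join(out, "dtraj.txt"), dt.concatenated(), fmt="%d")
            stages["cluster"] = {"k": micro.centers.shape[0],
                                 "inertia": micro.inertia}
            return dt
        dtraj = _stage("cluster", _cluster)

    if config.its_lags_frames:
        def _its():
            table = msmlib.implied_timescales(dtraj, config.its_lags_frames)
            table.to_csv(os.path.join(out, "implied_timescales.csv"))
            return table
        stages["its_table"] = _stage("implied_timescales", _its).to_dict()

    def _estimate():
        lag = config.lag_frames(config.estimation_lag_ns)
        counts = msmlib.count_transitions(dtraj, lag)
        model = msmlib.estimate_markov_model(counts, reversible=config.reversible)
        stages["estimate"] = {
            "lag_frames": lag, "lag_ns": counts.lag_ns,
            "active_set_size": model.n_states,
            "n_microstates_total": counts.counts.shape[0],
            "top_eigenvalues": np.real(model.eigenvalues(5)).tolist(),
        }
        with open(os.path.join(out, "markov_model.json"), "w") as fh:
            json.dump({"T": _matrix_json(model.T), "pi": model.pi.tolist(),
                       "lag_ns": model.lag_ns,
                       "active_set": model.active_set.tolist(),
                       "config_hash": config.config_hash()}, fh)
        return model
    est_model = _stage("estimate", _estimate)

    def _pcca():
        assignment = msmlib.pcca_plus(est_model, config.n_macrostates)
        with open(os.path.join(out, "macrostates.json"), "w") as fh:
            json.dump({"chi": _matrix_json(assignment.chi),
                       "crisp": assignment.crisp.tolist(),
                       "populations": assignment.populations.tolist(),
                       "config_hash": config.config_hash()}, fh)
        stages["pcca"] = {"populations": assignment.populations.tolist()}
        return assignment
    assignment = _stage("pcca", _pcca)

    def _kinetics():
        lag = config.lag_frames(config.analysis_lag_ns)
        if lag == est_model.lag_frames:
            ana_model, ana_assign = est_model, assignment
        else:
            counts = msmlib.count_transitions(dtraj, lag)
            ana_model = msmlib.estimate_markov_model(counts,
                                                     reversible=config.reversible)
            ana_assign = _remap_assignment(est_model, ana_model, assignment, warns)
        n_total = config.n_total or dtraj.n_frames
        warns.append(
            "barrier formula uses the dimensionally consistent reading "
            "rate = F_ST/(tau*N_total), F* = -kBT ln(rate*h/kBT)")
        n = ana_assign.n_macrostates
        barriers = {}
        for s in range(n):
            for t in range(n):
                if s == t:
                    continue
                cp = kin.compute_committors(ana_model, ana_assign.members(s),
                                            ana_assign.members(t))
                flux = kin.compute_flux(ana_model, cp)
                barriers[(s, t)] = kin.apparent_free_energy_barrier(
                    flux.total, ana_model.lag_ns, n_total, config.temperature_K)
        mfpts = kin.mfpt_matrix(ana_model, ana_assign)
        network = kin.build_kinetic_network(ana_assign, barriers, mfpts)
        stages["kinetics"] = {"analysis_lag_ns": ana_model.lag_ns,
                              "n_total": int(n_total)}
        return barriers, mfpts, network, ana_assign
    barriers, mfpts, network, ana_assign = _stage("kinetics", _kinetics)

    import pandas as pd

    labels = [f"S{i+1}" for i in range(ana_assign.n_macrostates)]
    barrier_rows = [
        {"source": labels[s], "sink": labels[t],
         "total_flux": res.total_flux,
         "barrier_kcal_mol": res.barrier_kcal_mol,
         "tau_ns": res.lag_ns, "n_total": res.n_total}
        for (s, t), res in sorted(barriers.items())]
    report = RunReport(
        config=config,
        stages=stages,
        populations=ana_assign.populations,
        mfpt=mfpts.to_frame(labels),
        barriers=pd.DataFrame(barrier_rows),
        basins=network.basins,
        network=network,
        profiles=profiles,
        warnings=warns,
        provenance={
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": _versions(),
            "elapsed_s": round(time.time() - t_start, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    write_reports(report)
    return report


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("kinemsm", "numpy", "scipy", "scikit-learn", "mdtraj"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            pass
    return out


def write_reports(report: RunReport, out_dir: str | None = None) -> list[str]:
    """Persist MFPT/barrier tables, the network, profiles and a summary."""
    out = out_dir or report.config.out_dir
    os.makedirs(out, exist_ok=True)
    written = []

    path = os.path.join(out, "mfpt_matrix.csv")
    report.mfpt.to_csv(path)
    written.append(path)

    path = os.path.join(out, "barriers.csv")
    report.barriers.to_csv(path, index=False)
    written.append(path)

    path = os.path.join(out, "network.json")
    with open(path, "w") as fh:
        json.dump(report.network.to_json_dict(), fh, indent=1, default=float)
    written.append(path)
    path = os.path.join(out, "network.graphml")
    report.network.write_graphml(path)
    written.append(path)

    for name, prof in report.profiles.items():
        if isinstance(prof, feat.ResidueProfile):
            path = os.path.join(out, f"profile_{name}.csv")
            prof.to_frame().to_csv(path, index=False)
            written.append(path)
        elif isinstance(prof, np.ndarray):
            path = os.path.join(out, f"series_{name}.csv")
            np.savetxt(path, prof, header=name, comments="")
            written.append(path)

    lines = ["kinemsm run summary", "===================", ""]
    lines.append(f"config hash: {report.provenance['config_hash']}")
    lines.append(f"seed: {report.provenance['seed']}")
    lines.append("macrostate populations: "
                 + ", ".join(f"{p:.4f}" for p in report.populations))
    lines.append(f"basins: {[sorted(b) for b in report.basins]}")
    lines.append("")
    lines.append("MFPT matrix (µs, row=source):")
    lines.append(report.mfpt.to_string(float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    lines.append("warnings:")
    lines.extend(f"  - {w}" for w in report.warnings or ["(none)"])
    path = os.path.join(out, "summary.txt")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written.append(path)

    prov = dict(report.provenance)
    prov["stages"] = {k: v for k, v in report.stages.items() if k != "its_table"}
    prov["artifact_hashes"] = {os.path.basename(p): _hash_file(p) for p in written}
    prov["warnings"] = report.warnings
    path = os.path.join(out, "report.json")
    with open(path, "w") as fh:
        json.dump(prov, fh, indent=1, default=str)
    written.append(path)
    return written
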