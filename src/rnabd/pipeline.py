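"""End-to-end orchestration: build -> equilibrate -> sample -> analyse.

The default workflow mirrors the intended use of the model: a free-draining
("smart Monte Carlo") production run generates the equilibrium ensemble,
the rigid-body treatment averaged over snapshots yields D_t, tau_h and R_g
with five-block uncertainties, and — when an arm definition is available —
the inter-arm angle trace and histogram.  An optional short HI run provides
the Einstein-relation (MSD) route to D_t.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import (ArmDefinition, angle_histogram, angle_trace,
                       block_stats, msd_diffusion, rg_trace)
from .bd import BDConfig, Trajectory, run
from .forcefield import ForceField
from .geometry import assemble_initial_conformation
from .hydro import ensemble_properties
from .params import ModelParameters, DEFAULT_PARAMS
from .topology import (SecondaryStructure, assign_equilibrium_lengths,
                       build_spring_network)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, partial: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.partial = partial or {}


@dataclass
class PipelineConfig:
    """Schedule for one production run (times in ps)."""

    dt: float = 0.1
    equilibration_ps: float = 100_000.0     # 100 ns
    production_ps: float = 480_000.0        # 480 ns, ~20 tRNA relaxation times
    snapshot_every_ps: float = 50.0
    hydro_snapshots: int = 600              # rigid-body treatment sample size
    seed: int = 1
    hi_production: bool = False             # append an HI run + MSD D_t
    hi_production_ps: float = 50_000.0
    hi_snapshot_every_ps: float = 10.0
    cholesky_every: int = 10
    dry_run: bool = False


def _topology_hash(ss: SecondaryStructure) -> str:
    return hashlib.sha256(ss.to_dot_bracket().encode()).hexdigest()[:16]


def run_pipeline(
    ss: SecondaryStructure,
    arms: ArmDefinition | None = None,
    params: ModelParameters = DEFAULT_PARAMS,
    config: PipelineConfig | None = None,
    trajectory: Trajectory | None = None,
    out_dir: str | Path | None = None,
    log=print,
) -> dict:
    """Run the full workflow and return the report dictionary.

    Passing a saved ``trajectory`` skips simulation and re-runs the
    analysis stages on it (idempotent re-analysis).
    """
    cfg = config or PipelineConfig()
    report: dict = {
        "topology_hash": _topology_hash(ss),
        "n_residues": ss.n_residues,
        "n_helices": ss.n_helices,
        "seed": cfg.seed,
        "dt_ps": cfg.dt,
    }
    t0 = time.time()

    def stage(name: str):
        log(f"[rnabd] {name} (t+{time.time() - t0:.1f}s)")

    try:
        stage("build topology")
        net = build_spring_network(ss, params)
        report["n_springs"] = len(net.springs)
        stage("build initial conformation")
        conf = assemble_initial_conformation(ss, params, seed=cfg.seed)
        net = assign_equilibrium_lengths(net, conf.coords, params)
        ff = ForceField(net, params)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("build", str(exc), report) from exc

    if cfg.dry_run:
        report["dry_run"] = True
        return report

    try:
        if trajectory is None:
            stage("BD-noHI production")
            every = max(1, round(cfg.snapshot_every_ps / cfg.dt))
            bdc = BDConfig(
                dt=cfg.dt,
                n_steps=round(cfg.production_ps / cfg.dt),
                equilibration_steps=round(cfg.equilibration_ps / cfg.dt),
                snapshot_every=every,
                seed=cfg.seed,
                hi=False,
            )
            trajectory = run(ff, conf, bdc)
        report["n_snapshots"] = trajectory.n_snapshots
        report["production_ns"] = float(trajectory.times[-1]) / 1000.0
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulation", str(exc), report) from exc

    try:
        stage("rigid-body ensemble treatment")
        stride = max(1, trajectory.n_snapshots // cfg.hydro_snapshots)
        props, per_snap = ensemble_properties(trajectory, params=params,
                                              stride=stride)
        report["solution_properties"] = props.to_dict()
        rgs = rg_trace(trajectory)
        report["R_g_trace_mean_A"] = float(np.sqrt((rgs ** 2).mean()))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("hydro", str(exc), report) from exc

    angles = None
    if arms is not None:
        try:
            stage("inter-arm angle analysis")
            angles = angle_trace(trajectory, arms)
            mean_theta, sd_theta = block_stats(angles)
            hist = angle_histogram(trajectory, arms)
            modal = hist.loc[hist["frequency"].idxmax()]
            report["inter_arm_angle"] = {
                "mean_deg": mean_theta,
                "block_sd_deg": sd_theta,
                "modal_bin_deg": [float(modal.theta_lo), float(modal.theta_hi)],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("angles", str(exc), report) from exc

    if cfg.hi_production:
        try:
            stage("BD-HI production + MSD")
            every = max(1, round(cfg.hi_snapshot_every_ps / cfg.dt))
            bdc = BDConfig(
                dt=cfg.dt,
                n_steps=round(cfg.hi_production_ps / cfg.dt),
                equilibration_steps=0,
                snapshot_every=every,
                seed=cfg.seed + 1,
                hi=True,
                cholesky_every=cfg.cholesky_every,
            )
            hi_traj = run(ff, trajectory.snapshots[-1], bdc)
            msd = msd_diffusion(hi_traj)
            report["msd_D_t_cm2_s"] = msd.D_t
            report["msd_r_squared"] = msd.r_squared
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("hi", str(exc), report) from exc

    report["wall_time_s"] = time.time() - t0
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        per_snap.to_csv(out / "hydro_per_snapshot.tsv", sep="\t", index=False)
        np.savetxt(out / "rg_trace.tsv",
                   np.column_stack([trajectory.times, rgs]),
                   header="time_ps\tR_g_A", delimiter="\t", comments="")
        if angles is not None:
            np.savetxt(out / "theta_trace.tsv",
                       np.column_stack([trajectory.times, angles]),
                       header="time_ps\ttheta_deg", delimiter="\t", comments="")
            hist.to_csv(out / "theta_histogram.tsv", sep="\t", index=False)
        trajectory.save_npz(out / "trajectory.npz")
    return report
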