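"""Rigid-body bead-model hydrodynamics of single conformations.

Each snapshot is treated as instantaneously rigid: the 3N x 3N RPY mobility
supermatrix is inverted to the friction supermatrix, contracted to a 6x6
resistance matrix at an origin (each bead also contributes its own Stokes
rotational friction ``8 pi eta sigma^3`` to the rotational block), and
inverted to the 6x6 rigid-body diffusion matrix.  The translational block
is reported at the centre of diffusion, where its trace is minimal; the
rotational block is origin-independent.

Ensemble averaging over an equilibrium (free-draining) trajectory gives the
"smart Monte Carlo" estimates of D_t, tau_h = 1/(6 <D_r>) and R_g, with
uncertainties from five contiguous trajectory blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bd import Trajectory, rpy_mobility
from .geometry import Conformation
from .params import (ModelParameters, DEFAULT_PARAMS,
                     A2_PER_PS_TO_CM2_PER_S, PER_PS_TO_PER_S)

__all__ = ["HydroResult", "SolutionProperties", "rigid_body_hydro",
           "kirkwood_dt", "ensemble_properties"]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


@dataclass
class HydroResult:
    """Rigid-body hydrodynamic output for one conformation (CGS units)."""

    D_t: float                 # cm^2/s, at the centre of diffusion
    D_rr: np.ndarray           # 3x3 rotational diffusion tensor, s^-1
    D_r: float                 # mean of the D_rr eigenvalues, s^-1
    tau_h: float               # ns, 1/(6 D_r)
    R_g: float                 # A
    origin: np.ndarray         # centre of diffusion, A

    @property
    def D_r_eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.D_rr)


@dataclass
class SolutionProperties:
    """Block-averaged ensemble estimates (mean, SD over blocks)."""

    D_t: float
    D_t_sd: float
    tau_h: float
    tau_h_sd: float
    R_g: float
    R_g_sd: float
    n_blocks: int
    block_D_t: np.ndarray
    block_tau_h: np.ndarray
    block_R_g: np.ndarray
    n_snapshots: int

    def to_dict(self) -> dict:
        return {
            "D_t_cm2_s": self.D_t, "D_t_sd": self.D_t_sd,
            "tau_h_ns": self.tau_h, "tau_h_sd": self.tau_h_sd,
            "R_g_A": self.R_g, "R_g_sd": self.R_g_sd,
            "n_blocks": self.n_blocks, "n_snapshots": self.n_snapshots,
            "block_D_t": list(self.block_D_t),
            "block_tau_h": list(self.block_tau_h),
            "block_R_g": list(self.block_R_g),
        }


def _rigid_body_internal(
    coords: np.ndarray, sigma: float, params: ModelParameters
) -> tuple[float, np.ndarray, np.ndarray]:
    """(D_t, D_rr, centre of diffusion) in internal units (A^2/ps, 1/ps)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    mob = rpy_mobility(coords, sigma, params)
    xi = np.linalg.inv(mob)  # friction supermatrix, kBT ps / A^2

    origin = coords.mean(axis=0)
    r = coords - origin
    # contract bead-pair friction blocks to the 6x6 resistance at the origin
    xi_tt = np.zeros((3, 3))
    xi_rt = np.zeros((3, 3))
    xi_rr = np.zeros((3, 3))
    U = [_skew(r[i]) for i in range(n)]
    blocks = xi.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)  # [i, j, 3, 3]
    row_sums = blocks.sum(axis=1)                          # sum_j xi_ij
    xi_tt = blocks.sum(axis=(0, 1))
    for i in range(n):
        xi_rt += U[i] @ row_sums[i]
        for j in range(n):
            xi_rr -= U[i] @ blocks[i, j] @ U[j]
    # each sphere's own rotational friction (Stokes, 8 pi eta sigma^3)
    zeta_rot = 1.0 / (params.bead_Dr0 * (params.sigma / sigma) ** 3)
    xi_rr += n * zeta_rot * np.eye(3)

    res = np.empty((6, 6))
    res[:3, :3] = xi_tt
    res[:3, 3:] = xi_rt.T
    res[3:, :3] = xi_rt
    res[3:, 3:] = xi_rr
    diff = np.linalg.inv(res)  # kBT = 1
    d_tt, d_tr, d_rr = diff[:3, :3], diff[:3, 3:], diff[3:, 3:]

    # centre of diffusion: minimise trace of the translational block.
    # trace(D_tt(P)) is quadratic in the shift d; build it on basis vectors.
    A = (d_tr - d_tr.T)
    lin = np.array([np.trace(A @ _skew(e)) for e in np.eye(3)])
    Q = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            Ua, Ub = _skew(np.eye(3)[a]), _skew(np.eye(3)[b])
            Q[a, b] = -0.5 * (np.trace(Ua @ d_rr @ Ub) + np.trace(Ub @ d_rr @ Ua))
    shift = np.linalg.solve(2.0 * Q, -lin)
    Us = _skew(shift)
    d_tt_cd = d_tt + d_tr @ Us - Us @ d_tr.T - Us @ d_rr @ Us
    dt_int = float(np.trace(d_tt_cd)) / 3.0
    return dt_int, d_rr, origin + shift


def rigid_body_hydro(
    conf: Conformation | np.ndarray,
    sigma: float | None = None,
    params: ModelParameters = DEFAULT_PARAMS,
) -> HydroResult:
    """Full rigid-body treatment of one conformation (CGS output)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("need an (N, 3) array with N >= 1")
    if sigma is None:
        sigma = params.sigma
    dt_int, d_rr_int, origin = _rigid_body_internal(coords, sigma, params)
    d_t = dt_int * A2_PER_PS_TO_CM2_PER_S
    d_rr = d_rr_int * PER_PS_TO_PER_S
    d_r = float(np.trace(d_rr)) / 3.0
    tau_h = 1.0 / (6.0 * d_r) * 1e9  # s -> ns
    cm = coords.mean(axis=0)
    rg = float(np.sqrt(((coords - cm) ** 2).sum(axis=1).mean()))
    return HydroResult(D_t=d_t, D_rr=d_rr, D_r=d_r, tau_h=tau_h, R_g=rg,
                       origin=origin)


def kirkwood_dt(
    conf: Conformation | np.ndarray,
    sigma: float | None = None,
    params: ModelParameters = DEFAULT_PARAMS,
) -> float:
    """Kirkwood double-sum approximation to D_t (cm^2/s)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    from scipy.spatial.distance import pdist

    if sigma is None:
        sigma = params.sigma
    n = coords.shape[0]
    d0 = params.bead_D0 * (params.sigma / sigma)
    inv_sum = float((1.0 / pdist(coords)).sum()) * 2.0 if n > 1 else 0.0
    # D_t = [kBT/(6 pi eta sigma N)] * [1 + (sigma/N) sum_{i!=j} 1/r_ij]
    dt_int = (d0 / n) * (1.0 + (sigma / n) * inv_sum)
    return dt_int * A2_PER_PS_TO_CM2_PER_S


def ensemble_properties(
    traj: Trajectory,
    sigma: float | None = None,
    params: ModelParameters = DEFAULT_PARAMS,
    n_blocks: int = 5,
    stride: int = 1,
    min_per_block: int = 5,
) -> tuple[SolutionProperties, pd.DataFrame]:
    """Rigid-body ensemble averages over a trajectory.

    Returns the block-averaged :class:`SolutionProperties` (with
    ``tau_h = 1/(6 <D_r>)`` and ``R_g = sqrt(<R_g^2>)``) and the
    per-snapshot results as a DataFrame.
    """
    snaps = traj.snapshots[::stride]
    m = snaps.shape[0]
    if m < n_blocks * min_per_block:
        raise ValueError(
            f"insufficient sampling: {m} snapshots for {n_blocks} blocks "
            f"(need >= {min_per_block} per block)")
    dts = np.empty(m)
    drs = np.empty(m)
    rg2 = np.empty(m)
    for k in range(m):
        res = rigid_body_hydro(snaps[k], sigma, params)
        dts[k] = res.D_t
        drs[k] = res.D_r
        rg2[k] = res.R_g ** 2

    def block_means(x: np.ndarray) -> np.ndarray:
        edges = np.linspace(0, m, n_blocks + 1).astype(int)
        return np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])

    b_dt = block_means(dts)
    b_tau = 1.0 / (6.0 * block_means(drs)) * 1e9
    b_rg = np.sqrt(block_means(rg2))
    props = SolutionProperties(
        D_t=float(dts.mean()), D_t_sd=float(b_dt.std(ddof=1)),
        tau_h=float(1.0 / (6.0 * drs.mean()) * 1e9), tau_h_sd=float(b_tau.std(ddof=1)),
        R_g=float(np.sqrt(rg2.mean())), R_g_sd=float(b_rg.std(ddof=1)),
        n_blocks=n_blocks, block_D_t=b_dt, block_tau_h=b_tau, block_R_g=b_rg,
        n_snapshots=m)
    per_snap = pd.DataFrame({
        "time_ps": traj.times[::stride][:m],
        "D_t_cm2_s": dts, "D_r_s": drs, "R_g_A": np.sqrt(rg2)})
    return props, per_snap
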