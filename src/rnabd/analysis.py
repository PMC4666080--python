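"""Trajectory observables.

Radius of gyration, centre-of-mass mean-squared displacement and the
Einstein-relation diffusion coefficient, the inter-arm angle between two
stem axis vectors, its histogram, five-block statistics, and the Svedberg
sedimentation estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bd import Trajectory
from .geometry import Conformation
from .params import R_GAS_CGS, A2_PER_PS_TO_CM2_PER_S

__all__ = ["ArmDefinition", "MSDResult", "radius_of_gyration", "msd_diffusion",
           "inter_arm_angle", "angle_histogram", "svedberg", "block_stats"]


def _coords(conf) -> np.ndarray:
    c = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("need an (N, 3) coordinate array")
    return c


@dataclass(frozen=True)
class ArmDefinition:
    """Two disjoint stems, each an ordered bead-index tuple with the
    hinge-proximal end first, so each arm vector points hinge -> tip."""

    stem_a: tuple[int, ...]
    stem_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stem_a) < 3 or len(self.stem_b) < 3:
            raise ValueError("each stem needs at least three beads")
        if set(self.stem_a) & set(self.stem_b):
            raise ValueError("stems must be disjoint")


def radius_of_gyration(conf) -> float:
    """Equal-mass root-mean-square distance from the centre of mass (A)."""
    c = _coords(conf)
    cm = c.mean(axis=0)
    return float(np.sqrt(((c - cm) ** 2).sum(axis=1).mean()))


def rg_trace(traj: Trajectory) -> np.ndarray:
    cm = traj.snapshots.mean(axis=1, keepdims=True)
    return np.sqrt(((traj.snapshots - cm) ** 2).sum(axis=2).mean(axis=1))


@dataclass
class MSDResult:
    D_t: float                 # cm^2/s
    lags_ps: np.ndarray
    msd_A2: np.ndarray
    r_squared: float
    sublinear_warning: bool


def msd_diffusion(
    traj: Trajectory,
    fit_min_ps: float = 1000.0,
    fit_max_fraction: float = 0.1,
) -> MSDResult:
    """Translational diffusion from the Einstein relation <d^2> = 6 D_t dt.

    The centre-of-mass MSD is averaged over all time origins and fitted
    linearly (through the origin's slope via least squares with intercept)
    over lag times from ``fit_min_ps`` to ``fit_max_fraction`` of the
    trajectory length; the short-lag bound skips intramolecular transients,
    the long-lag bound avoids poorly averaged points.  A fit with
    R^2 < 0.9 sets ``sublinear_warning``.
    """
    if traj.n_snapshots < 100:
        raise ValueError("need >= 100 snapshots for an MSD estimate")
    com = traj.snapshots.mean(axis=1)  # (M, 3)
    m = com.shape[0]
    dt_snap = traj.times[1] - traj.times[0]
    max_lag = max(2, int(m * fit_max_fraction))
    min_lag = max(1, int(math.ceil(fit_min_ps / dt_snap)))
    if min_lag >= max_lag:  # short trajectory: use whatever window exists
        min_lag, max_lag = 1, max(2, max_lag)
    lags = np.arange(min_lag, max_lag + 1)
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = com[lag:] - com[:-lag]
        msd[k] = (d * d).sum(axis=1).mean()
    t = lags * dt_snap
    # weighted linear fit of <d^2> = 6 D t (+ intercept); weights favour
    # short lags, which average over more independent origins
    wts = 1.0 / lags
    A = np.column_stack([t, np.ones_like(t)])
    W = np.diag(wts)
    beta, *_ = np.linalg.lstsq(W @ A, W @ msd, rcond=None)
    slope = beta[0]
    pred = A @ beta
    ss_res = float(((msd - pred) ** 2).sum())
    ss_tot = float(((msd - msd.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_int = max(slope, 0.0) / 6.0  # A^2/ps
    return MSDResult(D_t=d_int * A2_PER_PS_TO_CM2_PER_S,
                     lags_ps=t, msd_A2=msd, r_squared=r2,
                     sublinear_warning=bool(r2 < 0.9))


def _arm_vector(coords: np.ndarray, stem: tuple[int, ...]) -> np.ndarray:
    pts = coords[list(stem)]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise ValueError("degenerate stem: zero-variance bead coordinates")
    axis = v[:, -1]
    # orient hinge -> tip: first half of the (ordered) stem is hinge-proximal
    half = len(stem) // 2
    direction = pts[half:].mean(axis=0) - pts[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis


def inter_arm_angle(conf, arms: ArmDefinition) -> float:
    """Angle (degrees, in [0, 180]) between the principal axes of the two
    stems, each oriented from its hinge-proximal end to its tip."""
    c = _coords(conf)
    va = _arm_vector(c, arms.stem_a)
    vb = _arm_vector(c, arms.stem_b)
    cosang = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angle_trace(traj: Trajectory, arms: ArmDefinition) -> np.ndarray:
    return np.array([inter_arm_angle(s, arms) for s in traj.snapshots])


def angle_histogram(
    traj: Trajectory, arms: ArmDefinition, bin_width: float = 10.0
) -> pd.DataFrame:
    """Normalised frequency of inter-arm angles in ``bin_width``-degree bins."""
    if traj.n_snapshots < 100:
        raise ValueError("need >= 100 snapshots for a histogram")
    angles = angle_trace(traj, arms)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    freq = counts / counts.sum()
    return pd.DataFrame({"theta_lo": edges[:-1], "theta_hi": edges[1:],
                         "count": counts, "frequency": freq})


def svedberg(D_t: float, M: float, v_bar: float, rho: float, T: float) -> float:
    """Sedimentation coefficient from the Svedberg relation, in S (1e-13 s).

    ``s = D_t M (1 - v_bar rho) / (R T)`` with D_t in cm^2/s, M in Da,
    v_bar in cm^3/g, rho in g/cm^3.  A buoyancy factor <= 0 (flotation)
    yields a non-positive result.
    """
    if D_t <= 0 or M <= 0 or v_bar <= 0 or rho <= 0 or T <= 0:
        raise ValueError("all Svedberg inputs must be positive")
    buoyancy = 1.0 - v_bar * rho
    if buoyancy <= 0:
        import warnings

        warnings.warn("v_bar * rho >= 1: particle floats, s <= 0")
    s_seconds = D_t * M * buoyancy / (R_GAS_CGS * T)
    return s_seconds / 1e-13


def block_stats(values, n_blocks: int = 5) -> tuple[float, float]:
    """Mean of block means and SD of block means over contiguous blocks."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("need a 1-D series")
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} cannot fill {n_blocks} blocks")
    edges = np.linspace(0, len(x), n_blocks + 1).astype(int)
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return float(means.mean()), float(means.std(ddof=1))
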