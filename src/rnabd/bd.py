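"""Brownian dynamics propagation (Ermak-McCammon).

Two regimes:

* free-draining (``hi=False``): diagonal mobility, independent Gaussian
  displacements — cheap, samples the correct equilibrium ensemble, used as
  a "smart Monte Carlo" generator of conformations;
* with hydrodynamic interaction (``hi=True``): the configuration-dependent
  Rotne-Prager-Yamakawa mobility supermatrix couples the beads and the
  random displacements are correlated through its Cholesky factor — needed
  for faithful *dynamics* (e.g. centre-of-mass diffusion).

The RPY tensor is divergence-free, so the Ermak-McCammon drift correction
term vanishes and no drift correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg

from . import _kernels
from .forcefield import ForceField
from .geometry import Conformation
from .params import ModelParameters, DEFAULT_PARAMS

__all__ = ["BDConfig", "Trajectory", "PropagationError", "rpy_mobility",
           "bd_step", "run"]

#: hard stability bound on H dt / zeta (fraction of the stiffest spring's
#: relaxation time covered by one step)
STABILITY_LIMIT = 0.05


class PropagationError(RuntimeError):
    """Numerical failure (instability or non-finite forces) during BD."""


@dataclass(frozen=True)
class BDConfig:
    """Integration schedule.  ``dt`` in ps; defaults give
    ``H dt / zeta ~= 0.035`` for the standard parameter set."""

    dt: float = 0.1
    n_steps: int = 100_000
    hi: bool = False
    seed: int = 0
    snapshot_every: int = 1000
    equilibration_steps: int = 0
    cholesky_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0 or self.equilibration_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.cholesky_every < 1:
            raise ValueError("cholesky_every must be >= 1")


@dataclass
class Trajectory:
    """Uniformly spaced snapshots of a BD run (coordinates in A, times ps)."""

    snapshots: np.ndarray          # (M, N, 3)
    times: np.ndarray              # (M,)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.snapshots.ndim != 3 or self.snapshots.shape[2] != 3:
            raise ValueError("snapshots must have shape (M, N, 3)")
        if self.times.shape != (self.snapshots.shape[0],):
            raise ValueError("times length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]

    @property
    def n_beads(self) -> int:
        return self.snapshots.shape[1]

    def save_npz(self, path) -> None:
        np.savez_compressed(path, snapshots=self.snapshots, times=self.times,
                            config=np.array([repr(self.config)], dtype=object))

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        import ast

        data = np.load(path, allow_pickle=True)
        cfg = ast.literal_eval(str(data["config"][0])) if "config" in data else {}
        return cls(data["snapshots"], data["times"], cfg)


def check_stability(ff: ForceField, dt: float) -> float:
    """Return H dt / zeta for the stiffest spring; raise above the limit."""
    p = ff.params
    zeta_inv = p.bead_D0  # 1/zeta in kBT units
    if ff._H.size == 0:
        return 0.0
    ratio = float(np.max(ff._H)) * dt * zeta_inv
    if ratio > STABILITY_LIMIT:
        raise ValueError(
            f"time step too large: H dt/zeta = {ratio:.3f} > {STABILITY_LIMIT}")
    return ratio


def rpy_mobility(
    coords: np.ndarray,
    sigma: float | None = None,
    params: ModelParameters = DEFAULT_PARAMS,
) -> np.ndarray:
    """RPY diffusion supermatrix in internal units (A^2/ps), kBT-scaled.

    Symmetric positive definite for any configuration of equal, non-
    coincident beads; diagonal blocks are the Stokes-Einstein ``D0 I``.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    if sigma is None:
        sigma = params.sigma
    n = coords.shape[0]
    if n > 1:
        from scipy.spatial.distance import pdist

        if pdist(coords).min() == 0.0:
            raise FloatingPointError("coincident beads in RPY mobility")
    d0 = params.bead_D0 * (params.sigma / sigma)
    out = np.empty((3 * n, 3 * n))
    _kernels.rpy_fill(coords, float(sigma), d0, out)
    return out


def bd_step(
    coords: np.ndarray,
    ff: ForceField,
    dt: float,
    rng: np.random.Generator,
    mobility: np.ndarray | None = None,
    cholesky: np.ndarray | None = None,
    noise: bool = True,
) -> np.ndarray:
    """One Ermak-McCammon step; returns new coordinates.

    ``mobility=None`` means free draining.  For the HI case pass the 3N x 3N
    supermatrix (and optionally its precomputed lower Cholesky factor).
    """
    coords = np.asarray(coords, dtype=float)
    f = ff.total_forces(coords)
    if not np.all(np.isfinite(f)):
        raise PropagationError("non-finite force")
    n = coords.shape[0]
    if mobility is None:
        d0 = ff.params.bead_D0
        disp = d0 * dt * f
        if noise:
            disp = disp + math.sqrt(2.0 * d0 * dt) * rng.standard_normal((n, 3))
    else:
        drift = (mobility @ f.ravel()) * dt
        disp = drift.reshape(n, 3)
        if noise:
            if cholesky is None:
                cholesky = scipy.linalg.cholesky(mobility, lower=True)
            disp = disp + math.sqrt(2.0 * dt) * (
                cholesky @ rng.standard_normal(3 * n)).reshape(n, 3)
    return coords + disp


def run(
    ff: ForceField,
    initial: Conformation | np.ndarray,
    config: BDConfig,
) -> Trajectory:
    """Propagate and collect snapshots after the equilibration period.

    Snapshots are taken every ``snapshot_every`` steps of the production
    phase.  A spring stretched beyond three times its equilibrium length
    aborts the run with a diagnostic.
    """
    coords = (initial.coords if isinstance(initial, Conformation) else
              np.asarray(initial, dtype=float)).copy()
    if coords.shape != (ff.n_beads, 3):
        raise ValueError("initial conformation does not match force field")
    check_stability(ff, config.dt)

    if config.hi:
        return _run_hi(ff, coords, config)

    rng = np.random.default_rng(config.seed)
    args = ff.kernel_args()
    d0 = ff.params.bead_D0
    drift = d0 * config.dt  # kBT = 1
    amp = math.sqrt(2.0 * d0 * config.dt)
    n = ff.n_beads
    chunk = 5000  # noise pre-generation block; fixed for reproducibility

    def propagate(n_steps: int, snaps: np.ndarray, every: int, phase: str) -> None:
        isnap = 0
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            noise = amp * rng.standard_normal((m, n, 3))
            bad, isnap = _kernels.bd_nohi_chunk(
                coords, *args, drift, noise, done, every, snaps, isnap)
            _raise_if_bad(bad, phase)
            done += m

    if config.equilibration_steps:
        propagate(config.equilibration_steps, np.empty((0, n, 3)), 0,
                  "equilibration")
    n_snap = config.n_steps // config.snapshot_every
    snaps = np.empty((n_snap, n, 3))
    propagate(config.n_steps, snaps, config.snapshot_every, "production")
    if n_snap == 0:
        snaps = coords[None, :, :].copy()
        times = np.array([0.0])
    else:
        times = config.dt * config.snapshot_every * np.arange(1, n_snap + 1)
    return Trajectory(snaps, times, config=asdict(config))


def _raise_if_bad(step: int, phase: str) -> None:
    if step >= 0:
        raise PropagationError(
            f"instability during {phase}: a spring exceeded 3 l_e near step {step}")


def _run_hi(ff: ForceField, coords: np.ndarray, config: BDConfig) -> Trajectory:
    rng = np.random.default_rng(config.seed)
    d0 = ff.params.bead_D0
    dt = config.dt
    n = ff.n_beads
    si, sj, s_le = ff._si, ff._sj, ff._le

    def propagate(n_steps: int, snaps: np.ndarray | None, every: int) -> None:
        chol = None
        isnap = 0
        for step in range(n_steps):
            if step % config.cholesky_every == 0:
                mob = rpy_mobility(coords, ff.params.sigma, ff.params)
                chol = scipy.linalg.cholesky(mob, lower=True)
            f = ff.total_forces(coords)
            if not np.all(np.isfinite(f)):
                raise PropagationError(f"non-finite force at step {step}")
            disp = (mob @ f.ravel()) * dt + math.sqrt(2.0 * dt) * (
                chol @ rng.standard_normal(3 * n))
            coords[:, :] += disp.reshape(n, 3)
            if snaps is not None and (step + 1) % every == 0:
                d = coords[sj] - coords[si]
                if np.any((d * d).sum(axis=1) > 9.0 * s_le**2):
                    raise PropagationError(
                        f"instability: a spring exceeded 3 l_e near step {step}")
                if isnap < snaps.shape[0]:
                    snaps[isnap] = coords
                    isnap += 1

    if config.equilibration_steps:
        propagate(config.equilibration_steps, None, config.snapshot_every)
    n_snap = config.n_steps // config.snapshot_every
    if n_snap == 0:
        propagate(config.n_steps, None, config.snapshot_every)
        snaps = coords[None, :, :].copy()
        times = np.array([0.0])
    else:
        snaps = np.empty((n_snap, n, 3))
        propagate(config.n_steps, snaps, config.snapshot_every)
        times = dt * config.snapshot_every * np.arange(1, n_snap + 1)
    return Trajectory(snaps, times, config=asdict(config))
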