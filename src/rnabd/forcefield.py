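"""Elastic and excluded-volume potentials and their forces.

Springs are harmonic, ``V = 1/2 H (l - l_e)^2``, with one force constant
for every connector.  All bead pairs that do not share a spring of any kind
interact through the full 12-6 Lennard-Jones potential
``V = 4 eps [(sigma_LJ/r)^12 - (sigma_LJ/r)^6]`` (the attractive tail is
kept: it mimics good-solvent conditions).  Energies are in kBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .params import ModelParameters, DEFAULT_PARAMS
from .topology import SpringNetwork

__all__ = ["ForceField", "spring_energy", "lj_energy"]


def spring_energy(l: float, l_e: float, H: float) -> float:
    """Hooke energy (kBT) of a spring stretched to length ``l``."""
    if l <= 0:
        raise ValueError("spring length must be positive")
    return 0.5 * H * (l - l_e) ** 2


def lj_energy(r_ij, eps_lj: float, sigma_lj: float):
    """12-6 Lennard-Jones energy (kBT); zero crossing at sigma_LJ,
    minimum -eps_lj at 2^(1/6) sigma_LJ."""
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ distance must be positive (singularity at r=0)")
    s6 = (sigma_lj / r) ** 6
    out = 4.0 * eps_lj * (s6 * s6 - s6)
    return float(out) if out.ndim == 0 else out


@dataclass
class ForceField:
    """Spring network plus the complementary non-bonded pair list."""

    network: SpringNetwork
    params: ModelParameters = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        si, sj, le, hh = self.network.as_arrays()
        if np.any(~np.isfinite(le)):
            raise ValueError("spring equilibrium lengths are unset; "
                             "call assign_equilibrium_lengths first")
        self._si, self._sj = si.astype(np.int64), sj.astype(np.int64)
        self._le, self._H = le, hh
        n = self.network.n_beads
        sprung = self.network.pair_set()
        nb = [(i, j) for i in range(n) for j in range(i + 1, n)
              if (i, j) not in sprung]
        self._nbi = np.array([p[0] for p in nb], dtype=np.int64)
        self._nbj = np.array([p[1] for p in nb], dtype=np.int64)
        rc = self.params.lj_cutoff
        if rc is None:
            self._rc2, self._eshift = -1.0, 0.0
        else:
            self._rc2 = rc * rc
            self._eshift = lj_energy(rc, self.params.eps_lj, self.params.sigma_lj)

    @property
    def n_beads(self) -> int:
        return self.network.n_beads

    @property
    def nonbonded_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self._nbi.tolist(), self._nbj.tolist()))

    def kernel_args(self) -> tuple:
        p = self.params
        return (self._si, self._sj, self._le, self._H,
                self._nbi, self._nbj, p.eps_lj, p.sigma_lj,
                self._rc2, self._eshift)

    def _distances(self, coords, i, j):
        d = coords[j] - coords[i]
        return np.sqrt((d * d).sum(axis=1))

    def total_forces(self, coords: np.ndarray) -> np.ndarray:
        """Forces F = -grad V (kBT/A), summing to the zero vector."""
        coords = np.ascontiguousarray(coords, dtype=float)
        self._check(coords)
        forces = np.empty_like(coords)
        _kernels.accumulate_forces(coords, *self.kernel_args(), forces)
        return forces

    def total_energy(self, coords: np.ndarray) -> float:
        coords = np.ascontiguousarray(coords, dtype=float)
        self._check(coords)
        forces = np.empty_like(coords)
        return float(_kernels.accumulate_forces(coords, *self.kernel_args(), forces))

    def energy_decomposition(self, coords: np.ndarray) -> pd.DataFrame:
        """Per-interaction-kind energy report (kBT), for inspection."""
        coords = np.asarray(coords, dtype=float)
        self._check(coords)
        rows = []
        kinds: dict[str, float] = {}
        order = sorted(self.network.springs, key=lambda s: (s.i, s.j))
        ls = self._distances(coords, self._si, self._sj)
        for s, l in zip(order, ls):
            kinds[s.kind] = kinds.get(s.kind, 0.0) + spring_energy(l, s.l_e, s.H)
        for kind, e in sorted(kinds.items()):
            rows.append({"kind": kind, "energy_kBT": e})
        if len(self._nbi):
            r = self._distances(coords, self._nbi, self._nbj)
            ev = lj_energy(r, self.params.eps_lj, self.params.sigma_lj)
            if self._rc2 > 0:
                mask = r * r <= self._rc2
                ev = np.where(mask, ev - self._eshift, 0.0)
            rows.append({"kind": "excluded_volume", "energy_kBT": float(np.sum(ev))})
        return pd.DataFrame(rows, columns=["kind", "energy_kBT"])

    def _check(self, coords: np.ndarray) -> None:
        if coords.shape != (self.n_beads, 3):
            raise ValueError(f"coords shape {coords.shape} != ({self.n_beads}, 3)")
        if len(self._nbi):
            r = self._distances(coords, self._nbi, self._nbj)
            if np.any(r == 0.0):
                k = int(np.argmin(r))
                raise FloatingPointError(
                    f"coincident beads {self._nbi[k]}, {self._nbj[k]} "
                    "(LJ singularity)")
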