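"""Model parameters and unit system.

Internal units are Angstrom (length), picosecond (time) and kBT (energy).
All physical constants are converted from CGS at construction time, so the
rest of the package never sees ergs or poise; conversions back to CGS
(cm^2/s, s^-1, Svedberg) happen only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Boltzmann constant, erg/K
KB_CGS = 1.380649e-16
#: Gas constant, erg/(mol K)
R_GAS_CGS = 8.31446261815324e7

#: 1 A^2/ps expressed in cm^2/s
A2_PER_PS_TO_CM2_PER_S = 1.0e-4
#: 1 ps^-1 expressed in s^-1
PER_PS_TO_PER_S = 1.0e12


@dataclass(frozen=True)
class ModelParameters:
    """Physical parameters of the one-bead-per-nucleotide RNA model.

    The defaults encode an A-form duplex geometry (right-handed, 11 bp per
    turn, 2.8 A rise, 10 A helix radius) with touching beads of hydrodynamic
    radius ``sigma`` = 3.15 A, a uniform Hooke constant
    ``H = H_factor * kBT / l_e1**2`` for every connector, and a full 12-6
    Lennard-Jones excluded-volume potential between non-connected beads.

    ``inclination`` and the groove widths are descriptive metadata of the
    A form: with a single bead per nucleotide the placement is fully
    determined by radius, rise, twist and the inter-strand phase angle.
    """

    sigma: float = 3.15            # bead hydrodynamic radius, A
    helix_radius: float = 10.0     # A-form cylinder radius, A
    rise: float = 2.8              # axial rise per base pair, A
    bp_per_turn: float = 11.0
    inclination: float = 16.1      # deg, metadata only
    phase_angle: float = 200.0     # deg, azimuthal offset between strands
    major_groove: float = 3.8      # A, metadata only
    minor_groove: float = 10.9     # A, metadata only
    H_factor: float = 200.0        # H = H_factor * kBT / l_e1^2
    eps_lj: float = 0.1            # kBT
    sigma_lj_factor: float = 0.8   # sigma_LJ = factor * l_e1
    eta_s: float = 0.01            # solvent viscosity, poise
    temperature: float = 293.0     # K
    lj_cutoff_factor: float | None = None  # optional cutoff at factor*sigma_LJ

    def __post_init__(self) -> None:
        for name in ("sigma", "helix_radius", "rise", "eta_s", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bp_per_turn <= 1:
            raise ValueError("bp_per_turn must exceed 1")
        if not 0.0 <= self.phase_angle < 360.0:
            raise ValueError("phase_angle must lie in [0, 360)")

    # ---- derived quantities (internal units) ----

    @property
    def l_e1(self) -> float:
        """Equilibrium first-neighbour length 2*sigma (touching beads), A."""
        return 2.0 * self.sigma

    @property
    def sigma_lj(self) -> float:
        """Lennard-Jones length parameter, A."""
        return self.sigma_lj_factor * self.l_e1

    @property
    def lj_cutoff(self) -> float | None:
        """Cutoff radius (A) of the shifted-truncated LJ, or None (full)."""
        if self.lj_cutoff_factor is None:
            return None
        return self.lj_cutoff_factor * self.sigma_lj

    @property
    def spring_H(self) -> float:
        """Uniform spring constant in kBT/A^2."""
        return self.H_factor / self.l_e1**2

    @property
    def kBT_cgs(self) -> float:
        """Thermal energy in erg."""
        return KB_CGS * self.temperature

    @property
    def bead_D0(self) -> float:
        """Stokes-Einstein diffusion coefficient of one bead, A^2/ps."""
        d_cgs = self.kBT_cgs / (6.0 * math.pi * self.eta_s * self.sigma * 1e-8)
        return d_cgs / A2_PER_PS_TO_CM2_PER_S  # cm^2/s -> A^2/ps

    @property
    def bead_Dr0(self) -> float:
        """Stokes rotational diffusion coefficient of one bead, ps^-1."""
        d_cgs = self.kBT_cgs / (8.0 * math.pi * self.eta_s * (self.sigma * 1e-8) ** 3)
        return d_cgs / PER_PS_TO_PER_S

    @property
    def twist_per_bp(self) -> float:
        """Helical twist per base pair, radians."""
        return 2.0 * math.pi / self.bp_per_turn

    @property
    def backbone_chord(self) -> float:
        """Distance between consecutive beads of one helix strand, A."""
        c = 2.0 * self.helix_radius * math.sin(math.pi / self.bp_per_turn)
        return math.sqrt(self.rise**2 + c**2)

    @property
    def duplex_width(self) -> float:
        """Distance between the two beads of a base pair, A."""
        phi = math.radians(self.phase_angle)
        return 2.0 * self.helix_radius * abs(math.sin(phi / 2.0))


DEFAULT_PARAMS = ModelParameters()
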