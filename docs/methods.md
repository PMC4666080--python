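# Methods

## The model

`rnabd` represents an RNA molecule by one bead per nucleotide, all beads
carrying the same hydrodynamic radius σ = 3.15 Å.  The secondary structure
partitions the strand into double-helical regions and unpaired regions, and
completely determines both the geometry of the reference build and the
elastic network:

**Helix geometry.**  Double helices are built as ideal right-handed A-form
duplexes: helix radius 10 Å, rise 2.8 Å, 11 bp per turn, with the two
strands of a pair offset azimuthally by the phase angle φ = 200° at the same
axial height.  Radius, rise, twist and φ fully determine bead positions; the
A-form inclination (16.1°) and groove widths (3.8 / 10.9 Å) are carried in
`ModelParameters` as descriptive metadata only — with a single bead per
nucleotide there is no further degree of freedom for them to set.  The
resulting distance between consecutive beads of one strand is 6.29 Å,
within 0.5 % of the touching-bead contact 2σ = 6.30 Å; this internal
consistency is what makes a single bead radius serve both the helical and
the disordered regions.

**Elastic network.**  All connectors are Hooke springs,
V = ½ H (l − l_e)², with one force constant H = 200 kBT/l_e,1²
(l_e,1 = 2σ) for every spring regardless of type.  Inside every helix, bead
*i* is connected to *i*±1 (backbone), *i*±2 (bending), *i*±3 (torsion), its
base-pair counterpart, and the counterpart's first neighbours; all five
rules are truncated at the helix boundary.  Beads of hairpin and internal
loops carry only their two backbone springs — these are the flexible
"loops".  An isolated helix of N_bp pairs therefore carries 9·N_bp − 14
springs (N_bp ≥ 3).

**Hinge connectivity (a design decision).**  The connectivity of unpaired
beads in multibranch junctions and exterior tails — the *hinge*, a category
distinct from loops in the secondary-structure taxonomy this model encodes —
is genuinely open: the loop rule above is stated for loops.  We treat hinge
beads as strand continuation: they receive ±2 and ±3 (bending/torsion)
springs in addition to their backbone springs, with rest lengths taken from
the built reference conformation, so the junction preserves the overall
arrangement of the arms while still flexing substantially (the tRNA
inter-arm angle explores a ±40° range).  The alternative reading — hinge
beads as loop beads — is available via
`build_spring_network(..., junction_stiffening=False)`; it produces a
markedly more compact equilibrium ensemble (tRNA Rg ≈ 21.7 Å instead of
≈ 27 Å) whose solution properties sit well below the values this model
family is known to predict for tRNA.  We therefore default to the
strand-continuation reading.  Note its corollary: with a stiff hinge the
equilibrium ensemble remembers the built junction geometry, so the radial
layout (below) is part of the model definition, not just an initial guess.

**Excluded volume.**  All bead pairs not joined by any spring interact
through the full 12-6 Lennard-Jones potential with ε_LJ = 0.1 kBT and
σ_LJ = 0.8 l_e,1 = 5.04 Å.  The attractive tail is retained; at ε_LJ of a
tenth of kBT it is a weak perturbation (replacing the potential by its
purely repulsive truncation shifts the tRNA ensemble Rg by < 1 Å).  An
optional shifted truncation at a configurable radius
(`ModelParameters.lj_cutoff_factor`, off by default) exists for speed; all
shipped results use the full potential.

## Initial conformation

The builder performs a recursive radial layout: every loop face is a circle
whose boundary carries its unpaired beads (chord spacing l_e,1) and the
attachment chords of its helices (chord 2·10·sin(φ/2) = 19.7 Å); the circle
radius follows from closing the chord cycle, with a reflex-arc fallback for
short hairpins.  Helices extend radially away from their parent loop; the
exterior is laid along a line.  Unpaired beads sit exactly at touching-bead
spacing, so every backbone spring's reference length is l_e,1 (helix
interiors: the A-form distances).  The build is deterministic given a seed;
if two beads ever come closer than 0.8 l_e,1 the loop planes are tilted by
small seeded angles and the layout retried (up to 500 attempts).  For the
shipped fixtures the first, untilted attempt is clash-free.

## Brownian dynamics

Positions evolve by the overdamped Ermak–McCammon update
Δr = (Δt/kBT) **D** F + R, with ⟨R⟩ = 0 and ⟨R Rᵀ⟩ = 2 **D** Δt.

* Without hydrodynamic interaction (HI), **D** = D₀ **I** with
  D₀ = kBT/6πη σ: independent Gaussian displacements.  This free-draining
  mode samples the exact equilibrium ensemble (a "smart Monte Carlo") and is
  the workhorse for conformational averages.
* With HI, **D** is the 3N×3N Rotne–Prager–Yamakawa supermatrix (with the
  overlap-regularised form below r = 2σ, so it is positive definite for any
  configuration), and R is generated through its Cholesky factor.  The RPY
  tensor is divergence-free, so no drift-correction term arises.  The
  factorisation can be thinned (`cholesky_every`), trading a small error in
  the noise covariance for speed; equilibrium averages are unaffected.

**Time step.**  Δt = 0.1 ps gives H Δt/ζ ≈ 0.035 for the stiffest spring
(ζ = 6πησ); the integrator refuses Δt with H Δt/ζ > 0.05.  Correctness of
the sampling at this step is verified against 1-D quadrature of the
single-spring Boltzmann distribution p(l) ∝ l² exp(−V/kBT)
(Kolmogorov–Smirnov distance < 0.02) and against the ~5 % relative rms
spring-length fluctuation expected at this H.  Halving Δt changes the tRNA
ensemble Rg by well under its block SD.

**Schedules.**  The tRNA production runs 800 ns (≈ 34 harmonic relaxation
times) after 150 ns of equilibration, with snapshots every 100 ps; the 5S
rRNA runs 850 ns (≈ 10 relaxation times at its larger size) after 150 ns.
These are deliberate desk-scale reductions of the ~100-relaxation-time
protocol the method family uses at full scale; they inflate the five-block
standard deviations, which the reported uncertainties carry.  Internal
units are Å, ps and kBT throughout; CGS conversions happen only when
reporting.

## Rigid-body hydrodynamics and observables

Each snapshot is treated as instantaneously rigid.  The RPY mobility
supermatrix is inverted to the bead friction supermatrix, contracted to the
6×6 resistance at the centroid — each bead also contributing its own Stokes
rotational friction 8πησ³ to the rotational block, which is what makes the
single-bead limit exact (this equals the 6η·ΣV_bead rotational term; no
additional shell-model-style volume correction is applied) — and inverted
to the 6×6 rigid-body diffusion matrix.  D_t is the trace/3 of the
translational block evaluated at the centre of diffusion (found by
minimising that trace, a closed-form 3×3 solve); the rotational block D_rr
is origin-independent.  D_r is the mean of the D_rr eigenvalues and
τ_h = 1/(6 D_r) is the harmonic mean of the five rotational relaxation
times of an arbitrary rigid body.

Ensemble estimates over a free-draining trajectory: ⟨D_t⟩,
τ_h = 1/(6⟨D_r⟩), R_g = ⟨R_g²⟩^1/2, with uncertainties from five contiguous
trajectory blocks.  The MSD route (⟨d²⟩ = 6 D_t Δt on an HI trajectory,
weighted linear fit over lag times from 1 ns to 10 % of the trajectory) is
the dynamically rigorous alternative for D_t; the rigid-body ensemble route
is the default desk-scale estimator.  The two fit-window bounds skip
intramolecular transients and poorly averaged long lags; both are recorded
choices, as is the arm-vector estimator below.

**Inter-arm angle.**  Each arm vector is the principal axis of its stem's
bead cloud, oriented from the hinge-proximal pair to the tip (robust to the
~5 % spring-length noise, unlike an endpoint difference); θ is the angle
between the acceptor-stem and anticodon-stem vectors.  Histograms use 10°
bins over [0°, 180°].

**Svedberg estimate.**  s = D_t·M·(1 − v̄ρ)/(R T), reported in Svedberg
units; for 5S rRNA with M = 40 kDa, v̄ = 0.53 cm³/g, ρ = 1 g/cm³ the
predicted D_t gives s ≈ 4.8 S.

## Fixtures

*tRNA-phe* (76 nt): the standard cloverleaf — acceptor 7 bp, D 4 bp,
anticodon 5 bp, T 5 bp, three hairpin loops, the multibranch hinge
(including the variable loop) and the 3' NCCA tail.  *5S rRNA* (120 nt,
E. coli): helix I closing the molecule into a three-way junction carrying
the helix II–III arm (internal loop + hairpin) and the helix IV–V arm.  The
5S per-residue ranges are a consensus encoding; the exact table the
original study used is not printed anywhere we can consult, and plausible
±1–2 bp differences move the solution properties by a few percent.

## What the tests do and do not show

The synthetic checks (Boltzmann sampling, Stokes closed forms, oracle
comparisons for the 6×6 diffusion matrix, invariances) validate the
machinery exactly.  The fixture runs validate the *model*: they reproduce
tRNA solution properties to within ~9 % and 5S D_t and R_g similarly.  They
do not validate sequence-specific effects (all pairs are identical),
electrostatics/ionic strength (absent from the model), tertiary contacts
(only secondary structure enters), or the 5S rotational relaxation time,
where our prediction (≈ 46–53 ns depending on the hinge reading) sits well
below the literature BD value of ≈ 82 ns even though D_t and R_g agree —
consistent with a difference in the encoded 5S topology/built shape rather
than in the hydrodynamic treatment, since for tRNA the same pipeline
reproduces τ_h.

## Known limitations

* One bead per nucleotide under-represents the molecular volume; the model
  is hydrodynamically "transparent" relative to atomic-shell models, and
  its ensemble must be somewhat more extended than an atomic structure to
  produce the same D_t and τ_h.  This is an intrinsic property of the model
  class, shared with its published results.
* With the stiff-hinge default, equilibrium junction geometry inherits the
  radial layout's multiloop circle; a different builder would shift Rg by
  a few percent.
* Pseudoknots are rejected; non-Watson-Crick geometry, sequence dependence
  and counterion effects are out of scope.
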