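# rnabd

Solution properties and internal dynamics of RNA from Brownian dynamics of
a coarse-grained, one-bead-per-nucleotide elastic-network model.

Small structured RNAs — tRNAs, the ribosomal 5S RNA — are segmentally
flexible: rigid double-helical stems joined by disordered loops and hinges.
Their dilute-solution observables (translational diffusion coefficient
D_t, rotational relaxation time, radius of gyration R_g, sedimentation
coefficient) probe exactly that flexibility, but connecting them to
structure requires a model that is flexible too.  `rnabd` is for
structural/biophysical modellers who want those predictions from nothing
but a secondary structure and a handful of physical constants.

## The model and the method

* One bead per nucleotide, hydrodynamic radius σ = 3.15 Å.  Helices are
  ideal A-form duplexes (radius 10 Å, rise 2.8 Å, 11 bp/turn, inter-strand
  phase angle φ = 200°).
* A minimalist elastic network of Hooke springs, V = ½H(l − l_e)² with
  H = 200 kBT/l_e,1² (l_e,1 = 2σ) for every connector: inside helices each
  bead binds its ±1, ±2, ±3 strand neighbours, its base-pair partner and
  the partner's ±1 neighbours; loop beads bind only their ±1 neighbours;
  hinge/junction beads are treated as strand continuation (±1, ±2, ±3).
* Excluded volume between non-connected beads:
  V = 4ε_LJ[(σ_LJ/r)¹² − (σ_LJ/r)⁶], ε_LJ = 0.1 kBT, σ_LJ = 0.8 l_e,1.
* Ermak–McCammon Brownian dynamics at T = 293 K, η = 0.01 P: free-draining
  for equilibrium sampling ("smart Monte Carlo"), or with full
  hydrodynamic interaction through the Rotne–Prager–Yamakawa supermatrix
  and Cholesky-correlated noise for real-time dynamics.
* Per-snapshot rigid-body bead-model hydrodynamics: invert the RPY
  supermatrix, contract to the 6×6 resistance, diffusion at the centre of
  diffusion; D_t = tr(D_tt)/3, D_r = tr(D_rr)/3, τ_h = 1/(6⟨D_r⟩);
  Einstein-relation MSD fits as the alternative D_t route; the Svedberg
  relation s = D_t·M(1 − v̄ρ)/RT for sedimentation.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and limitations.

## Worked example

```sh
python examples/04_trna_solution_properties.py
```

builds the 76-nt yeast tRNA-phe cloverleaf fixture, samples its equilibrium
ensemble for 300 ns of free-draining BD and applies the rigid-body
treatment to 500 snapshots:

```
production: 300 ns, 500 snapshots for the rigid-body treatment
R_g   = 27.0 +- 1.4 A
tau_h = 23.1 +- 1.9 ns
D_t   = 8.44 +- 0.23 x 1e-7 cm^2/s
theta = 95 +- 4 deg (modal bin [100.0, 110.0])
```

R_g is the rms radius of gyration of the flexible ensemble; τ_h the
harmonic mean of the five rigid-body rotational relaxation times,
ensemble-averaged — the number to compare with rotational relaxation
experiments (≈ 23 ns for tRNA); D_t the translational diffusion
coefficient (experimental range 7.3–7.9 ×10⁻⁷ cm²/s); θ the angle between
the acceptor and anticodon stems, fluctuating broadly around the ~90° of
the crystal's L-shape.  Uncertainties are five-block standard deviations;
the longer acceptance-grade schedule (below) tightens them.

Other example scripts: `01` topology and spring census, `02` a short BD
run with energy/R_g traces, `03` rigid-body hydrodynamics of single
conformations (Stokes closed forms, Kirkwood comparison), `05` the
Svedberg estimate for 5S rRNA (`s = 4.78 S`, i.e. the "5S" of its name).

A thin CLI mirrors the library: `rnabd fixtures`, `rnabd build`,
`rnabd run`, `rnabd analyze`, `rnabd hydro`.

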