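# Methods

This note documents the models, conventions and numerical choices behind
`kinemsm`, in the order data flows through the package.

## Synthetic dynamics and what they stand in for

The generators in `kinemsm.synthetic` emulate the statistical structure of
long all-atom MD ensembles of a small ligand-binding protein — several
independent multi-microsecond runs exhibiting 3–6 metastable conformations
whose exchange times span roughly 10–100 lag times — without simulating any
force field.  Three levels of realism are provided, each with exact ground
truth:

* **Explicit Markov chains** (`generate_markov_chain`): the generating
  matrix *is* the truth; used to validate counting, estimation, committors,
  fluxes and MFPTs.  Sampling uses per-state inverse-CDF tables; all
  generators are pure functions of their arguments including the seed.
* **Brownian dynamics** (`simulate_brownian_dynamics`): overdamped
  Euler–Maruyama with unit friction, x ← x − ∇U·dt + √(2·kT·dt)·ξ.  The
  stationary law is exp(−U/kT), so macrostate populations can be checked
  against numerical quadrature (`boltzmann_populations`).  Stability
  requires dt·k_max < 0.1, where k_max is the largest curvature within
  20 kT of the global minimum (curvature outside the thermally accessible
  region is irrelevant and would otherwise forbid reasonable time steps for
  quartic walls).  Potentials: harmonic; a quartic double well with the
  barrier height in kT (optional linear tilt for asymmetric wells, which
  shifts the well positions slightly — the quadrature truth accounts for
  it); and a triple well of Gaussian basins on a weak harmonic confinement
  (5 % of the well stiffness by default).  The Gaussian widths are set so
  each well's bottom curvature equals the requested stiffness, and the
  confinement keeps the density normalizable — it also slightly favours the
  central well, which the quadrature truth again reflects.
* **Helix–coil toy backbones** (`generate_toy_protein_trajectory`): an
  N–Cα–C backbone with ideal geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
  1.329 Å; angles 121.7°, 111.2°, 116.2°; ω = 180°) built by natural
  extension of reference frames from per-frame φ/ψ angles.  A hidden Markov
  chain switches all residues between emission states (wrapped-normal in
  φ/ψ, spread ≥ 0 with 0 meaning deterministic), emulating a short portal
  helix folding and unfolding as a unit.  The hidden path is returned, so
  downstream models can be checked against the closed-form exchange
  timescale −τ/ln(1 − a − b) of a two-state switcher.

What the toys do **not** emulate: side chains, tertiary packing beyond what
the backbone produces, solvent, anisotropic friction, and state-dependent
emission correlations between residues.  Passing tests therefore certify
the *estimators*, not the realism of any force field; on real data the
dominant errors (force-field bias, finite sampling of rare transitions) lie
outside what these tests can probe.

## Structural statistics

* **Dihedrals**: IUPAC right-handed sign convention, degrees in
  [−180, 180); the geometry (0,0,0), (1,0,0), (1,1,0), (1,1,1) gives +90°.
  Internally the projection ("praxeolitic") formula is used; the test suite
  cross-checks it against an independent atan2-of-cross-products
  implementation to 1e−6°.  Collinear quadruples give NaN and the affected
  feature columns are dropped with a logged count.  tICA input encodes each
  angle as a (sin, cos) pair to respect periodicity.
* **Helicity**: fraction of frames with φ ∈ (−100°, −30°) and
  ψ ∈ (−67°, −7°) sustained over ≥ 3 consecutive residues.  This is a
  backbone-only dihedral criterion (no hydrogen-bond assignment), chosen so
  it works on Cα/N/C toy data; the run-length rule suppresses single-residue
  noise.  Dispersion is the standard error across source files (independent
  runs).
* **Native contacts**: the reference is built from one chosen frame —
  heavy-atom pairs of residues separated by > 3 in sequence within 4.5 Å
  (a common native-contact convention).  Soft Q uses the logistic contact
  function 1/(1 + exp(β(r − λ·r⁰))) with β = 5 Å⁻¹, λ = 1.8; hard Q counts
  r < 1.2·r⁰.  Qᵢ restricts the same statistic to pairs involving residue
  i.  An empty reference defines Q ≡ 1 with a warning.
* **Conformational entropy**: Sᵢ = −R Σ p ln p over a 24×24 (15°) φ/ψ
  histogram, R = 1.987 cal·mol⁻¹·K⁻¹; empty cells contribute zero, bins are
  configurable, and residues with < 10 defined frames are flagged
  unreliable.  This plug-in estimator is biased low for undersampled
  histograms; it is reported as a per-residue *relative* flexibility
  measure, not an absolute thermodynamic entropy.
* **SASA**: Shrake–Rupley with a golden-spiral point lattice (default 960
  points; < 24 is refused), probe 1.4 Å, Bondi radii from a bundled
  element table.  Points strictly inside any other expanded sphere are
  occluded.  Different SASA dialects (radii sets, point counts) shift
  absolute values by a few percent; comparisons should stay within one
  convention.
* **RMSD**: optimal rigid superposition by Kabsch/SVD (batch over frames),
  with the raw (non-superposed) variant available.  Superposition needs
  ≥ 3 atoms.

## Markov model construction

* **tICA** solves C̃(τ)v = λC(0)v with C̃ = (C(τ)+C(τ)ᵀ)/2 — symmetrization
  by averaging rather than trajectory reversal, keeping eigenvalues real in
  (−1, 1].  Covariances use only frame pairs within a contiguous segment.
  A rank-deficient C(0) is regularized by adding 1e−10 to the diagonal with
  a warning.  Components are C(0)-orthonormal; the default output dimension
  is 4, matching common practice for portal-region dynamics.
* **Microstates**: k-means (Lloyd + k-means++, fixed seed, 5 restarts).
  The conventional 500 microstates are the default for real data; synthetic
  tests use 20–50, a deliberate scale-down matched to the toy state spaces.
* **Estimation**: transition counts at integer lag (sliding window, never
  across segment boundaries), restricted to the largest strongly connected
  component (excluded states are logged, never silently dropped).
  Non-reversible MLE is row normalization; reversible MLE is the standard
  detailed-balance fixed point on symmetric edge weights, iterated to an
  elementwise change below 1e−12, with π obtained in closed form from the
  converged weights.  Bayesian/posterior estimation is out of scope; only
  point estimates are produced.
* **Implied timescales**: t_k(τ) = −τ/ln λ_k(τ), eigenvalues sorted by
  modulus, Perron root excluded; complex eigenvalues contribute their
  modulus, non-positive real eigenvalues give NaN, and |λ| ≥ 1 gives ∞.
  `select_lag` proposes the smallest tabulated lag whose slowest timescale
  changes by < 10 % over the next two lags, falling back to the largest lag
  with a warning; it is advisory — the pipeline always accepts explicit
  lags, and the estimation lag and the kinetics (analysis) lag are
  independent settings because a model that is Markovian for estimation may
  still be analysed at a longer lag.
* **PCCA+**: right eigenvectors are obtained from the π-symmetrized matrix
  so the spectral problem is real; n_macro must not exceed the number of
  positive leading eigenvalues (the error lists the spectrum).  Memberships
  come from the Deuflhard inner-simplex construction, made feasible
  (rows sum to 1, χ ≥ 0) and then refined by Nelder–Mead maximization of
  the crispness criterion trace(diag(w)⁻¹ χᵀ diag(π) χ).  The crisp map is
  the row argmax with lowest-index tie-break; macrostates are relabelled by
  first occurrence for determinism, and populations are sums of π over
  crisp members (conserving probability exactly).

## Transition-path kinetics

* **Committors**: q⁺ from the interior linear system on T with boundary
  values; q⁻ from the time-reversed chain T̃_ij = π_j T_ji / π_i, which is
  exact for non-reversible models (the reversible shortcut q⁻ = 1 − q⁺ is
  used only as a test identity).  Unreachable sinks are detected by graph
  search and reported by state index rather than surfacing as a singular
  solve.
* **Fluxes**: gross flux f_ij = π_i q⁻_i T_ij q⁺_j (zero diagonal), net
  flux by pairwise rectification, total flux as the net outflow across the
  source cut.  Conservation holds to machine precision: zero net-flux
  divergence off S∪T, and the *signed* net flux (forward minus backward
  crossings) is identical across every cut separating S from T — the
  backward term vanishes only for the source cut.
* **Apparent barrier**: the only dimensionally consistent reading of the
  Eyring-type transform is used — the total flux becomes a per-conformation
  rate k = F_ST/(τ·N_total) in s⁻¹ and F* = −k_B·T·ln(k·h/(k_B·T)) — and
  each run's report records this reading explicitly.  Constants are CODATA
  values converted to kcal/mol (k_B·T = 0.5962 kcal/mol at 300 K); a J-based
  recomputation agrees to 1e−9 kcal/mol.  N_total (the number of sampled
  conformations) is an explicit input because it rescales all barriers by a
  constant; it defaults to the total frame count of the input.  Zero flux
  reports an infinite barrier.
* **MFPT**: direct solve of (I − T_CC) m = τ·1 with m ≡ 0 on the sink (the
  crisp member set of the sink macrostate; fuzzy-weighted sinks are
  rejected for determinism), one solve per sink reused over all sources;
  macrostate values use stationary source weights and are reported in µs.
* **Kinetic network**: macrostate nodes carry populations; all n(n−1)
  directed edges carry the barrier (kcal/mol) and MFPT (µs).  A two-basin
  partition is produced by single-link merging on the symmetrized pairwise
  barriers, mirroring the way barrier heights group metastable states into
  super-basins.

## Pipeline

One config (YAML or constructor) drives load → featurize → tICA → cluster →
estimate → PCCA+ → kinetics → reports.  Three input modalities: structural
(PDB + DCD/XTC), feature CSV, and pure discrete trajectories (the kinetics
half runs with no structural file at all).  Every stage persists its
artifact with the config hash; the report records seed, versions, stage
timings, and all warnings (connected-set restrictions, covariance
regularization, the barrier-formula reading).  Reruns with identical config
and inputs are byte-identical apart from the report timestamp.  Stage
failures abort with the stage name and leave a `FAILED_<stage>.txt` marker
next to the partial outputs.

## Problem sizes used in validation

Tests and the acceptance script use: 10⁶-step chains for transition-matrix
recovery (elementwise error ≲ 5e−3 at that length), 10⁵-walk Monte-Carlo
ensembles for committor/MFPT cross-checks (hitting-probability standard
error ≈ 2e−3), 10⁶-step Brownian runs with 30 microstates for the
triple-well pipeline, and 10⁵-frame toy-protein trajectories with 20
microstates for hidden-timescale recovery.  Statistical comparisons use
block standard errors (10 contiguous blocks) so that slow metastable
exchange is reflected in the uncertainty.

## Known limitations

* Only point estimates of T(τ); no posterior sampling, no error bars on
  MFPTs or barriers.
* No Chapman–Kolmogorov test beyond implied-timescale flatness.
* PCCA+ refinement is a local optimization; for near-degenerate spectra the
  inner-simplex initialization dominates the result.
* The helicity window, Q functional form, entropy estimator and SASA
  dialect are documented conventions of this package; other toolchains'
  absolute values will differ even on identical trajectories.
* The barrier transform depends on N_total and τ through an additive
  constant, so only barrier *differences* within one run are meaningful
  without fixing those inputs.
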