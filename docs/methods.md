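# Methods

This note documents the models implemented in `sterictrap`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Steric-trap thermodynamics

A doubly biotinylated membrane protein couples its spontaneous
denaturation equilibrium (K_D = [D]/[N]) to the binding of a second bulky
monovalent streptavidin (mSA): the second binding is attenuated by the
factor (1 + 1/K_D), giving an apparent dissociation constant
K_app = K_d,biotin·(1 + 1/K_D). Fitting the second binding phase
(a hyperbola in total titrant, valid because the titrant is in large
excess over protein in that regime) yields K_D and hence
ΔG°_N-D = −RT·ln(1/K_D).

Three signal models are provided:

- **single_site** — the tight-binding quadratic for 1:1 binding at
  comparable protein and ligand concentrations. The bound fraction is the
  physical root of the quadratic, clipped at a non-negative discriminant
  to absorb floating-point round-off at the stoichiometric corner.
- **competition** — the labeled/unlabeled mSA competition expression,
  transcribed verbatim from the original assay's fitting equation,
  including the placement
  of (C_T − P_T) and the affinity ratio K_unlabel/K_label. The expression
  is not algebraically re-derived or simplified; a transcription check
  against an independent symbolic construction is part of the test suite.
- **steric_trap** — the attenuated hyperbola above. At zero titrant the
  limit F₀ is returned.

### Fitting

Fits are per replicate, then averaged — matching how triplicate titration
experiments are reported (mean ± SEM, n = 3). Equilibrium constants are
fitted on a natural-log scale (they are positive and span decades);
initialization is a deterministic multi-start: K_D on a log grid over
[10⁻¹⁰, 1] (11 starts), amplitudes from the data extremes. The
lowest-SSR converged start wins; ties cannot occur because starts are
ordered.

**Error model.** The reported uncertainty of a fitted parameter combines
the across-replicate scatter with the propagated per-replicate fit
covariance in quadrature: σ = √(SEM² + mean(SE_i²)/n). A plain n = 3 SEM
systematically understates the uncertainty of the mean (a ±2·SEM interval
built from a 2-df scatter estimate covers the truth only ~82% of the
time); adding the covariance term restores conservative ≥95% coverage
without inflating errors when replicates genuinely disagree. For a single
replicate the covariance-based error is used directly. ΔG errors are
propagated from K_D by the delta method (dΔG/dK_D = RT/K_D) per replicate
before averaging.

Temperatures: experimental fits default to **298.15 K** (titrations are
incubated at 25 °C); the gas constant is R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹
and all logarithms are natural.

## Cooperativity profiling

ΔΔG°_WT-Mut = ΔG°_WT − ΔG°_Mut per subdomain probe and environment, with
quadrature error propagation. The propagation statistic
ΔΔΔG = ΔΔG^N − ΔΔG^C is classified five ways against cutoffs at ±RT and
±2RT ("regular") or ±RT/2 and ±RT ("narrow"). The conventional class ranges
overlap exactly at the cutoffs; this implementation resolves ties toward
the inner, more cooperative class (|ΔΔΔG| = RT is "cooperative",
ΔΔΔG = 2RT is "moderately localized"), which is tested explicitly at
boundary ± 10⁻⁹. By construction the narrow scheme satisfies
classify_narrow(x/2) = classify_regular(x).

**Slopes and Chow's test.** Environment comparisons regress bicelle ΔΔG
on micelle ΔΔG. Because a mutation with zero effect in one environment
should have zero effect in the other, the default is regression through
the origin (k = 1 regression parameter); a free-intercept mode (k = 2) is
selectable. Slope equality between two groups uses Chow's F statistic
from the pooled and per-group residual sums of squares, with
F(k, n₁+n₂−2k) giving the p-value and significance tiers at 0.05 (*) and
0.005 (**). Measurement errors do not weight the regression by default
(no weighting was used in the source analyses); a weighted mode is a
possible extension. OLS is delegated to statsmodels.

**Structure maps.** Classes are written into the B-factor column of a
copy of a PDB structure (codes: cooperative = 1, moderately-localized-N
= 2, localized-N = 3, moderately-localized-C = 4, localized-C = 5,
unassigned = 0), restricted to polymer (non-HETATM) residues so lipid
residue numbers cannot collide with protein numbering.

## Solvation dynamics

**Contacts.** q_i(t) is the number of heavy atoms of amphiphile i within
5 Å of any protein heavy atom (k-d tree per frame; an all-pairs oracle
backs this in the tests). Heavy atoms are identified by the atom-name
convention (names not starting with H), with an explicit element column
honored when present. Head/tail splits use editable atom-name lists
shipped with the package: DMPC tails C22–C214 and C32–C314, DDM tail
C1–C12, remainder = head. For the bulk (L·L) reference the same counting
runs between designated amphiphile pairs.

**Events.** A contact event is a maximal run of q > 0 tolerating internal
zero-gaps up to the gap tolerance, default **20 ns** — the bulk
amphiphile conformational relaxation time, which should in principle be
re-measured for a new system from the plateau onset of the RMSD(τ) curve.
Events are trimmed to their first/last contacting frame, and an event's
duration is (number of frames)·dt.

**Autocorrelation.** c(τ) averages ⟨q(t)·q(t+τ)/q²(t)⟩ (the asymmetric
normalization, kept verbatim; a symmetric variant exists behind a
non-default flag) over events with equal weight. The time average runs
over event frames with q(t) > 0, and q is taken as zero once the event
has ended — the contact no longer exists. This convention is what makes
a constant-q event of duration D contribute exactly max(0, 1 − τ/D), the
closed form used throughout the tests; a strict valid-pairs average
would stay at 1 for all τ < D and carry no decay information. c(0) = 1
identically.

**Residence time.** τ_R is the first downward crossing of c(0)/e,
linearly interpolated between lag samples. If the curve never crosses
(trajectory shorter than the decay), τ_R is solved from the
triple-exponential fit and flagged as extrapolated. The
triple-exponential fit constrains amplitudes to be non-negative and sum
to c(0) via a stick-breaking parameterization, fits decay times on a log
scale from a deterministic grid of log-spaced triples, and reports SDs
from the least-squares covariance mapped through the parameterization.
Degenerate solutions (two components converging to the same decay time,
which split the amplitude arbitrarily) are canonicalized by merging
components whose times agree within 1%. Components are ordered
t₁ ≤ t₂ ≤ t₃.

**Free energy.** ΔG°_Solv = −RT·ln(τ_R,P·L/τ_R,L·L) at **T = 310 K**
(the simulation thermostat temperature — deliberately different from the
experimental 298.15 K default). The off-rates are inverse residence
times, so the ratio is the solvation equilibrium constant. SDs propagate
by the delta method.

**Structural utilities.** Superposition is Kabsch (proper rotation,
det = +1, via scipy's align_vectors), with the RMSD computed from the
actually transformed coordinates rather than the solver's residual (the
latter loses precision near zero). RMSF aligns all frames to their mean
structure with one mean-recomputation pass — rigid-motion invariance is
therefore approximate at the 10⁻⁴ Å level, which is far below any
physical fluctuation of interest. RMSD(τ) superposes each molecule's
conformations pairwise at lag τ and weights molecules equally (outer
1/N_L sum), not (molecule, time) pairs. Periodic-boundary handling is
not applied by default: toy and synthetic frames are pre-imaged.

## Synthetic generators

All generators are deterministic under a fixed integer seed and emit a
truth record used by the recovery tests.

- `gen_isotherm`: steric-trap curves on a log-spaced titrant grid
  spanning K_app/100 to 100·K_app (12 points), Gaussian signal noise of
  2% of the amplitude, 3 replicates — the reporting conditions of the
  titration experiments. Defaults: ΔG_true = −7 kcal/mol,
  K_d,biotin = 52 pM (the weak-affinity mSA variant), quenching from 1
  to 0.
- `gen_mutation_table`: 37 mutated residues (the experimental design
  size), target ΔΔΔG drawn inside each planted class band, micelle ΔΔG_C
  uniform in a destabilizing 0.5–2.5 kcal/mol range, bicelle values
  = m_true·micelle + noise with m_true = 1.3 (the C-subdomain
  environment slope scale) and 0.1 kcal/mol measurement noise.
- `gen_contact_series`: operates directly in contact space (no
  coordinate round trip) for speed; events of fixed or exponential
  duration, inter-event gaps of (tolerance + dt) plus an exponential
  tail so segmentation at the stated tolerance recovers the planted
  events one-for-one, q constant or 1 + Poisson within events,
  dt = 0.5 ns.
- `gen_frames`: a protein blob with minimum-separation placement plus
  amphiphile chains planted at a known contact distance (3.5 Å, inside
  the shell) or parked in the bulk (30 Å); optional iid Gaussian jitter
  parameterized by the RMS 3-D displacement per atom, so the lagged RMSD
  of a jittered-static molecule plateaus near √2·σ.

What the generators do **not** emulate: real lipid diffusion and
force-field dynamics, correlated (non-iid) noise, photophysics of the
fluorescence readout, baseline drift, or incomplete equilibration.
Passing recovery tests therefore demonstrate estimator correctness under
the stated statistical assumptions, not robustness to every artifact of
real data.

## Problem sizes and numerical tolerances

The test suite runs desk-scale problems: 50-seed recovery studies for
the isotherm fit, 1000 null simulations for the Chow-test calibration,
500 events for the contact analytic law, and ~10-frame toy trajectories
for the geometric oracles. Key tolerances: noise-free fit round trips to
10⁻⁶ relative; superposition exactness to 10⁻⁸ Å; contact counts exact
against the O(N²) oracle; classifier boundaries exercised at ±10⁻⁹.

## Known limitations

- The competition isotherm is a verbatim transcription of the assay's
  fitting equation; any typographical quirk in that form is reproduced.
  Flagged for review rather than silently "corrected".
- Whether reported environment slopes come from through-origin or
  free-intercept regression is not documented in the source analyses;
  through-origin is the default here on physical grounds and both modes
  are exposed.
- Residence times can be read either from the raw 1/e crossing (default)
  or from the triple-exponential fit; for heterogeneous decays the two
  differ and both are provided.
- No binary trajectory formats in core; the multi-model PDB reader plus
  the contact-series TSV are the supported inputs, with an adapter hook
  as the extension point.
- The cumulative (per-shell × per-molecule) solvation difference is a
  derived illustration, not a computed output: its exact arithmetic
  depends on which shell-count and ΔG pairs are combined.
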