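# sterictrap

Analysis pipeline for membrane-protein folding thermodynamics measured by
**steric trapping**, with cooperativity profiling of residue interaction
networks and MD-derived **amphiphile solvation dynamics**. The package was
built around the rhomboid protease GlpG studied in bicelles (a DMPC bilayer
edge-stabilized by CHAPS) versus DDM micelles, but every stage is generic.

## Who this is for

Experimentalists fitting steric-trap titrations (fluorescence quenching upon
monovalent-streptavidin binding to doubly biotinylated protein) to extract
thermodynamic stabilities, and simulators quantifying how strongly lipids or
detergents solvate a protein surface from contact statistics of equilibrium
MD trajectories.

## The models

**Stability from the attenuated second binding.** With a biotin pair engineered
into one subdomain, the second mSA can bind only when the protein spontaneously
denatures. The second binding phase follows

    F = (F∞ − F₀) / (1 + K_app/[mSA]) + F₀,   K_app = K_d,biotin · (1 + 1/K_D)

where K_D = [D]/[N] is the denaturation equilibrium constant, and

    ΔG°_N-D = −RT · ln(1/K_D).

The unhindered biotin affinity K_d,biotin is measured separately by the
tight-binding quadratic (single-site) isotherm or chained through a
labeled/unlabeled competition isotherm. Fits are per replicate
(multi-start nonlinear least squares), then averaged.

**Cooperativity profiling.** A point mutation's stability change is measured at
two biotin-pair probes (N- and C-subdomain): ΔΔG°_WT-Mut = ΔG°_WT − ΔG°_Mut,
and the propagation statistic

    ΔΔΔG = ΔΔG°_WT-Mut^N − ΔΔG°_WT-Mut^C

is classified against thermal-energy cutoffs ±RT and ±2RT (RT ≈ 0.6 kcal/mol
at 298.15 K) into cooperative / moderately localized / localized classes,
optionally with narrow cutoffs (±RT/2, ±RT). Environment comparisons
(micelle vs bicelle ΔΔG scatter) use through-origin regression with
pairwise Chow's F tests for slope equality.

**Solvation free energy from residence times.** Heavy-atom contacts between
each amphiphile and the protein (5 Å cutoff) are segmented into contact
events (internal gaps up to the 20 ns bulk relaxation time are tolerated),
the per-event contact autocorrelation

    c(τ) = (1/N_c) Σᵢ ⟨qᵢ(t)·qᵢ(t+τ)/qᵢ²(t)⟩_t

is averaged over events, and the residence time τ_R is the 1/e decay lag
(triple-exponential extrapolation when unreached). Then

    ΔG°_Solv = −RT · ln(τ_R,P·L / τ_R,L·L)

compares residence on the protein against residence on bulk amphiphiles;
negative values mean the amphiphile prefers the protein surface.
Superposition (Kabsch), RMSD/RMSF, and the lagged conformational RMSD(τ)
equilibration check are included.

## Worked example

```python
import sterictrap as st

# 1. fit a noisy synthetic steric-trap titration (3 replicates, 2% noise)
data, truth = st.gen_isotherm(seed=2, dG_true=-7.0)
fit = st.fit_isotherm(data, "steric_trap",
                      fixed={"K_d_biotin": truth["K_d_biotin"]})
stab = st.stability_from_fit(fit, subdomain="N", environment="bicelle")
print(f"dG = {stab.dG:.2f} +- {stab.err:.2f} kcal/mol")

# 2. classify a mutation's propagation statistic
print(st.classify_cooperativity(1.5))          # localized_N (1.5 > 2RT)

# 3. solvation free energy from residence times (ns) at 310 K
lip = st.solvation_free_energy(90.0, 40.0, T=310.0)
ddm = st.solvation_free_energy(80.0, 20.0, T=310.0)
print(f"lipid {lip.dG_solv:.2f}  detergent {ddm.dG_solv:.2f} kcal/mol")
```

prints

```
dG = -6.99 +- 0.04 kcal/mol
localized_N
lipid -0.50  detergent -0.85 kcal/mol
```

The fitted stability recovers the −7.0 kcal/mol truth within its SEM-scale
error; the lipid's less negative ΔG°_Solv than the detergent's says the
bilayer solvates the protein surface more weakly than the micelle —
the thermodynamic driving force for stronger intraprotein packing in a
bilayer.

The same stages are scriptable from the shell:

```sh
sterictrap simulate isotherm --seed 2 --out demo/
sterictrap fit isotherm --csv demo/isotherm.csv --model steric_trap \
    --fix K_d_biotin=5.2e-11 --out demo/fit.json
sterictrap solvation dgsolv --tau-pl 90 --tau-ll 40 --out demo/dg.json
```

## Layout

- `sterictrap.thermo` — binding isotherm models, per-replicate fits, ΔG°_N-D
- `sterictrap.cooperativity` — ΔΔG/ΔΔΔG, classifier, slopes, Chow's test,
  structure coloring by class
- `sterictrap.solvation` — superposition, RMSD/RMSF/RMSD(τ), contacts,
  events, autocorrelation, residence times, ΔG°_Solv, first-shell census
- `sterictrap.synthetic` — seeded generators with machine-readable truths
- `sterictrap.io` / `sterictrap.pipeline` / `sterictrap.cli` — formats,
  orchestration, and the `sterictrap` command

See `docs/methods.md` for the modeling choices, defaults, and limitations.
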