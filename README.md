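# thermolead

Thermodynamic screening toolkit for selecting the **peptide leader of a
bi-substrate protein-kinase inhibitor**, with human CK2α as the model
target.

Bi-substrate inhibitors couple an ATP-competitive ligand with a peptide that
mimics the kinase's substrate consensus sequence. Before synthesizing the
conjugate, one wants to (i) find the peptide with the highest affinity for
the substrate site, and (ii) verify that peptide and ATP-site ligand bind
*independently*, so their free energies can add. `thermolead` implements
that screening workflow as a tested, reusable pipeline:

1. **Peptide library deconvolution** — enumerate positional libraries such
   as `[KGDE]-[DE]-[ST]-[DE]₃-NH₂` (128 hexapeptides), compute monoisotopic
   and average masses, group exactly isobaric sequences (the residue pair
   identity Thr+Asp = Glu+Ser, both C₈H₁₂N₂O₅, makes distinct sequences
   share a mass), assign ESI-MS peaks, and score pull-down enrichment
   between library, eluent and no-protein control runs.
2. **Relaxation-filtered NMR ranking** — global fit of the two-exponential
   decay `y(t) = A₁·e^(−R₂,f·t) + A₂·e^(−R₂,s·t) + y₀` across resonance
   regions (shared rates, per-region amplitudes); peptides are ranked by the
   fast, bound-averaged rate R₂,f.
3. **Single-site binding isotherms** — exact 1:1 mass-balance fraction
   bound, global fits of MST pseudo-titrations and nanoDSF 350/330 nm signal
   slices, melting-temperature extraction, and the thermodynamic conversions
   ΔG = RT·ln(K_d/1 M), ΔS = (ΔH − ΔG)/T with error propagation.
4. **ITC** — forward simulation and one-site fitting of the reverse
   titration (ligand in a 950 µl perfusion cell, protein injected as
   4 µl + 12×20 µl) with volume-displacement bookkeeping.
5. **Cross-dependency test** — a z-test on the log-K_d scale asking whether
   a ligand's K_d changes when the partner site is occupied
   (binary vs ternary complex), plus the coupling free energy
   ΔΔG = RT·ln(K_d,complex/K_d,apo).
6. **Dose–response potency** — global four-parameter-logistic IC₅₀ fits and
   fold-enhancement ratios between parent compound and conjugate.
7. **Synthetic data** — seeded generators that emulate each instrument at
   the published experimental designs, with the published fitted parameters
   as ground truth, so the whole pipeline runs and is testable without any
   instrument files.

## Worked example

Run the whole screening workflow on the synthetic presets:

```sh
thermolead pipeline --seed 0 --out report.json
```

Highlights of the report produced by that exact command:

- `nmr_ranking.top_peptide`: **KESEEE-NH2** — the global bi-exponential fits
  rank it first by R₂,f, i.e. it has the largest transiently bound
  population of all ten screened peptides.
- `binding.mst.KESEEE-NH2`: K_d = 0.402 mM (ΔG = −19.38 kJ/mol) from three
  jointly fitted MST pseudo-titrations of 50 nM labeled protein; the
  nanoDSF 25 °C signal slice gives 0.344 mM, and the extracted melting
  temperature falls from 52.4 °C to 44.1 °C as the peptide concentration
  rises to 10 mM (the peptide destabilizes the fold).
- `ternary`: both verdicts **independent** — the peptide's K_d is unchanged
  by the ATP-site ligand (MST) and the ligand's K_d (fitted 0.086 µM,
  ΔH = −27.9 kJ/mol by ITC) is unchanged by the peptide. Independence is
  what licenses fusing the two into one bi-substrate molecule.
- `potency`: IC₅₀ 0.55 µM for the bi-substrate conjugate vs 9.38 µM for its
  parent acid — a **17-fold** enhancement for this noise realization
  (exact fold varies with seed; the error-free ratio of the published
  values is 11.9).

Every number above is a fit to noisy synthetic data generated at the
published designs, which is why they scatter around the published values
(0.39 mM, 0.35 mM, 0.06 µM, −25.1 kJ/mol, 0.67/8.0 µM).

Individual stages are exposed both as library functions
(`enumerate_library`, `fit_biexp_global`, `fit_isotherm`, `fit_itc`,
`fit_ic50`, `test_independence`, …) and as CLI subcommands
(`thermolead library|nmr|bind|dsf|itc|ic50|ternary|synth`), all reading
plain CSV/YAML and writing CSV/JSON.

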