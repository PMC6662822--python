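# Methods

This note documents the models implemented in `thermolead`, the parameters
that matter, the numerical choices inside the fitters, and the scope of the
synthetic-data generators. No empirical claim is made here beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Peptide libraries and mass deconvolution

A positional library is an ordered list of residue sets with a fixed
C-terminal state; enumeration is the Cartesian product of the sets.
Residue elemental compositions and masses come from the standard amino-acid
table (via pyteomics); a free acid is residues + H₂O (18.010565 Da
monoisotopic), an amide is residues + NH₃ (17.026549 Da), and the
protonated ion adds 1.007276 Da (1.008 Da on the average-mass scale).
"Nominal" masses are protonated monoisotopic masses rounded to the nearest
integer — the convention that reproduces unit-resolution ESI-MS peak labels
such as 750/763/764 Da for the hexapeptide library. Average masses are also
computed, since peak lists of unknown provenance may use either convention;
the choice is an explicit argument everywhere.

Isobaric grouping has two policies. *Exact composition* groups by identical
elemental formula — an equivalence relation, and the only policy that
captures the Thr+Asp = Glu+Ser degeneracy (both residue pairs are
C₈H₁₂N₂O₅) without a tolerance parameter. *Mass tolerance* chains peptides
whose sorted monoisotopic masses differ by at most ε; every exact class is
contained in a tolerance class for any ε > 0. Peak assignment maps each
observed m/z to all classes within a tolerance (default 0.5 Da,
unit-resolution ESI); unmatched peaks are reported, never dropped.

Enrichment scoring normalizes each run (library, eluent, no-protein
control) to its total ion intensity and reports the eluent/library share
ratio per class. Classes whose control/library ratio exceeds a threshold
(default 1.5) are flagged unspecific — resin binders — and excluded from
the ranking; classes with zero library intensity get an undefined ratio and
are likewise flagged rather than silently ranked.

## Relaxation-filtered NMR

Signal versus filter delay follows a sum of two decays,

    y(t) = A1·exp(−R2f·t) + A2·exp(−R2s·t) + y0 ,

where R2f is the fast rate of the exchange-averaged, transiently
protein-bound population and R2s that of peptide that never senses the
protein. The fit is global: R2f and R2s are shared across all resonance
regions of a peptide while amplitudes and offset are per region (region
intensities differ by proton count and lineshape). The model is
parameterized as (R2f, dr = R2f − R2s ≥ 0), so the returned rates are
always in canonical order regardless of how the optimizer wanders; both
rates are bounded to [0, 500] s⁻¹.

Initialization is data-driven: a log-linear fit of the late-time tail gives
(R2s, A2), the log-linear slope of the early-time residual gives (R2f, A1).

The per-region offset is kept as a free parameter but carries a weak
zero-centred prior with standard deviation equal to 5% of the region's peak
intensity, implemented as an extra whitened residual. The reason is
identifiability, not taste: with a 200 ms maximum delay and slow rates of
1–3 s⁻¹ the slow exponential decays by only 20–60%, so an unconstrained
offset can absorb the tail while a spurious, arbitrarily fast component
fits early-time noise — rate estimates then scatter over an order of
magnitude. Physically, a transverse-relaxation filter drives
baseline-corrected intensities to ~0 at long delay, so a small offset is
the correct prior belief. Data residuals are whitened with per-region noise
levels estimated from a first, unpenalized pass; for noise-free data the
estimated noise floor vanishes and the prior has no effect (recovery is
exact to 1e-6), while for noisy data the prior weight is commensurate with
the measurement error. Rate standard errors come from the least-squares
covariance (with the usual residual-variance rescaling); 95% intervals use
the t quantile at the residual degrees of freedom. Ranking is by descending
R2f with the R2f/R2s ratio as tie-breaker. Conversion of R2f to an absolute
bound fraction would require the protein's own R2 and is out of scope;
the output is a ranking.

## Single-site binding

The bound fraction for 1:1 binding is the exact mass-balance root,

    [RL] = 2·R·L / (b + sqrt(b² − 4·R·L)),   b = R + L + Kd ,

written in the cancellation-free form so that tight binding (Kd ≪ R + L)
is computed accurately; a bisection solver on the mass balance serves as an
independent oracle in the tests (agreement to 1e-10 over a
10×10×10 log-grid).

Titration signals are modeled as linear interpolation between free and
bound end states: S = S_free + (S_bound − S_free)·fraction_bound. For MST
this is the standard minimal two-state thermophoresis model; for nanoDSF it
is applied to the 350/330 nm ratio sliced at a fixed temperature (25 °C for
the native state, 75 °C for the unfolded state). Fits are global across
replicates: Kd (optimized as log₁₀Kd, bounds 10⁻¹²–1 M) and the amplitude
are shared, the free-state baseline is per replicate (instrument baselines
jitter between runs). Five restarts spread over the sampled concentration
range guard against local minima; a Kd landing on a bound flags the fit.
An optional concentration cutoff drops points where high ligand
concentrations unfold the receptor and corrupt the raw signal.
σ_Kd is ln(10)·Kd·SE(log₁₀Kd); confidence intervals are formed on the log
scale, where Kd errors are approximately symmetric.

Free energies use the 1 M reference state, ΔG = R·T·ln(Kd/1 M) with
R = 8.314 J/mol/K, T = 298.15 K for 25 °C (348.15 K for 75 °C);
σ_ΔG = R·T·σ_Kd/Kd, ΔS = (ΔH − ΔG)/T with errors added in quadrature. These
conventions reproduce every printed (Kd, ΔG) pair to within the rounding of
the printed Kd itself.

Melting temperatures are the extremum of the Savitzky–Golay-smoothed first
derivative of the ratio–temperature curve (window 11 points, polyorder 3),
refined by parabolic interpolation around the grid maximum. A curve whose
derivative extremum does not stand out threefold above the median derivative
magnitude (e.g. a flat or purely drifting baseline) raises a no-transition
error instead of returning a number.

## ITC

The forward model mirrors the reverse-titration design: the low-mass ligand
sits in the cell (default 950 µl), protein is injected as a 4 µl
pre-injection followed by 12 × 20 µl. Each injection instantly mixes and
displaces an equal volume of *pre-injection* cell content out of the active
volume (the standard perfusion-cell correction); concentrations are then
updated and the equilibrium complex is the exact one-site quadratic with
apparent stoichiometry n (binding sites per cell-species molecule). The
heat of injection i is

    Q_i = ΔH · V_cell · ( [C]_i − [C]_{i−1}·(1 − dV_i/V_cell) )

in µJ. Because the binding pair enters the quadratic symmetrically, which
species is titrant does not affect Kd. The fitter estimates
(log₁₀Kd, ΔH, n, baseline) by least squares over the usable injections
(pre-injection excluded by default — its heat is corrupted by diffusion at
the syringe tip), jointly over multiple runs, with restarts over a log₁₀Kd
grid. A c-value (n·[cell]/Kd) outside [1, 1000] triggers a warning because
the isotherm shape then constrains Kd poorly. ΔG and ΔS are derived from
the fitted Kd and ΔH. The ternary condition (ligand titrated into
protein–peptide complex, peptide present in cell and syringe at 500 µM) is
modeled as apparent one-site binding with its own (Kd, ΔH), not as an
explicit three-species equilibrium — the same reduction the instrument
software applies. Default concentrations 5 µM cell / 40 µM syringe (the
middle of the 4–10 / 20–60 µM ranges used experimentally), configurable.

## Cross-dependency (ternary) test

Whether occupancy of one site alters binding at the other is decided on the
log-Kd scale, where multiplicative Kd errors are additive:

    z = |ln Kd_apo − ln Kd_complex| / sqrt( (σ_a/Kd_a)² + (σ_c/Kd_c)² )

with verdict "independent" iff z < z₁₋α/₂ (default α = 0.05). The coupling
free energy ΔΔG = RT·ln(Kd_complex/Kd_apo) is reported with its propagated
error; it changes sign under swapping the two conditions while z and the
verdict are invariant. Zero-error inputs with unequal Kd yield an infinite
z and are flagged. Note the verdict is a significance test, not an
equivalence test: with very precise inputs it will resolve arbitrarily
small couplings, and at level α it reads "coupled" for a fraction α of
noise realizations even when the truth is identical.

## Dose–response

Luminescence-type inhibition data follow the descending four-parameter
logistic y(c) = bottom + (top − bottom)/(1 + (c/IC₅₀)^hill), fit globally
across replicates with IC₅₀ on the log₁₀ scale, hill bounded to [0.3, 4]
(free by default; plateaus can be fixed instead of fitted). At least five
distinct concentrations are required, and data whose pooled response range
is below three times the replicate noise raise an unidentifiability error
before any fitting. Potency gains are parent/conjugate IC₅₀ ratios with
quotient error propagation. The estimate is invariant under response
rescaling and equivariant under concentration unit changes.

## Synthetic data

Each generator reproduces the corresponding experimental design — 18 filter
delays (0–200 ms) over six resonance regions; 16-point MST titrations
(100 nM–10 mM ligand, 50 nM receptor) in triplicate; a 20–80 °C nanoDSF
ramp at 0.25 °C steps over a 300 nM–10 mM peptide grid with 2.5 µM protein;
the 4 µl + 12×20 µl ITC schedule in duplicate with ±20% concentration
variation between runs; 7 log-spaced inhibitor concentrations (1 nM–1 mM)
in triplicate — and uses the published fitted parameters as ground truth.
Noise is Gaussian with standard deviation expressed as a fraction of each
curve's dynamic range (defaults: 2% NMR, 3% MST plus a 5%-of-amplitude
baseline jitter between MST replicates, 0.5% DSF ratio, 8% ITC, 5%
dose–response, 5% MS intensities). The ITC default is deliberately the
largest: it is calibrated so that the fitted relative Kd uncertainty
(~50%) matches the uncertainty actually reported for that experiment at
this high-c design; with unrealistically clean heats the ternary z-test
would resolve the small difference between the binary and ternary truth
values that the real experiment could not. The DSF generator couples
peptide binding to the fold in reduced form: Tm decreases with the native
bound fraction (up to 8 °C), and the native/unfolded baselines shift with
the bound fractions at the two states' distinct affinities (native Kd from
the published table, unfolded Kd ≈ 1 mM).

What the generators do *not* emulate: raw spectra and lineshapes, peak
picking, capillary scans, thermogram baselines, charge states beyond
singly protonated ions, LC retention, titration-schedule errors, and any
systematic (non-Gaussian) instrument drift. Passing recovery tests
therefore demonstrate the correctness and calibration of the estimators
under the stated noise model, not robustness to raw-data artefacts.

Identical configurations produce identical tables; changing only the seed
changes the noise realization, never the design.

## Problem sizes in the validation suite

The stochastic recovery checks use 20–40 independent noise realizations per
scenario and verify both point recovery (median across seeds) and 95%
confidence-interval coverage (≥ 90% of seeds). Property suites run the
bound-fraction oracle on a 10×10×10 grid, the ITC heat oracle on the full
13-injection schedule, and library-enumeration properties on 100 random
specifications.

## Known limitations

- The bi-exponential model assumes fast exchange and exactly two spin
  populations; R2f is a ranking statistic, not a bound fraction.
- The relaxation offset prior trades a small bias in y0 for identifiability
  of the slow rate; rate pairs closer than ~3-fold at 2% noise remain
  poorly determined (their intervals say so).
- MST and nanoDSF fits use the minimal linear two-state signal model; the
  exact instrument-software signal equations are not public.
- ITC fitting assumes integrated per-injection heats as input; raw power
  traces, thermogram integration and competitive-displacement models are
  out of scope.
- No Cheng–Prusoff Ki conversion: ATP concentration relative to its Km is
  not modeled.
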