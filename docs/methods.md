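# Methods

`halfcam` packages the quantitative analyses behind the proposal that a
half-calcified calmodulin species (Ca₂/CaM, Ca²⁺ bound only at EF-hands 3 and
4 of the C-lobe) preassociates with the Ca_V_1.2 L-type calcium channel at
resting Ca²⁺ and primes it for opening and Ca²⁺-dependent inactivation (CDI).
This note records the models, the assumptions behind them, the defaults that
matter, and what the synthetic-data generators do and do not emulate.

## Coupled Ca²⁺ / CaM / IQ equilibria (`equilibria`)

The IQ-bound CaM pool is modelled as a two-step macroscopic Ca²⁺ ladder:
apoCaM-IQ → Ca₂/CaM-IQ (C-lobe, constant K₁) → Ca₄/CaM-IQ (N-lobe, K₂).
Each step binds `n_per_step` Ca²⁺ ions as one cooperative unit; the default is
2 because each lobe's pair of EF-hands loads as a unit, and it is configurable
to 1 for a non-cooperative reading. The species weights are the terms of the
binding polynomial Z = 1 + K₁c^n + K₁K₂c^{2n}, evaluated in log space so
constants of order 10¹⁴ M⁻² do not overflow. The microscopic constants behind
published occupancy profiles are not hard-coded anywhere; they are inputs
(`BindingScheme`), because the literature values they derive from are not
recoverable to full precision.

Single-lobe saturation uses the hyperbola Y = c/(c + K_D^app). The linkage
cycle K_D^app = K_D(Ca, free CaM) × K_D(IQ, Ca-loaded)/K_D(IQ, apo) expresses
how IQ binding sharpens the apparent Ca²⁺ affinity; a 10-fold IQ-affinity
ratio turns a 1 µM lobe into a 100 nM lobe, which is what places the C-lobe
half-loaded at the ~100 nM resting Ca²⁺ of a cardiomyocyte or neuron.

Temperature handling: kelvin internally, R = 1.98720425 cal mol⁻¹ K⁻¹.
Van't Hoff scaling assumes a temperature-independent ΔH over the 10 K span it
is used for; with ΔH = −15 kcal/mol it gives K_D(310.15 K)/K_D(300.15 K)
= 2.25, and ΔC_p is the finite difference of the two calorimetric enthalpies.

## ITC forward model and fitting (`itc`)

The forward model is the per-injection heat of a perfusion (overflow) cell:
every injection of volume v into cell volume V₀ dilutes both titrand and
accumulated injectant by (1 − v/V₀), so total concentrations after injection
i are M_i = M₀d^i and X_i = X_s(1 − d^i) with d = 1 − v/V₀. Bound injectant
is the root of the binding polynomial — a closed-form quadratic for one class
of sites, a bracketed Brent solve (relative tolerance 10⁻¹², absolute
tolerance scaled to the bracket so nanomolar roots stay resolved) on the
strictly monotone free-ligand equation for two independent classes. The heat
of injection i is V₀ Σ_c ΔH_c (B_{c,i} − d·B_{c,i−1}), normalised per mole
injected. The "two-site" model means two independent site classes, the
parameterisation under which per-component (N, K, ΔH) triplets are reported
by the standard instrument software; it is not a sequential/cooperative
scheme. Because bound material is carried out with the overflow, the
cumulative raw heat matches N·M₀·V₀·ΔH only in the strongly saturating limit
(<1% with a large injectant excess, ~2.5% under the published 37 °C
schedule) — the conservation test uses the saturating limit and the exact
bookkeeping is pinned against an independent mole-tracking oracle.

Fits are bounded trust-region least squares (`scipy.optimize.least_squares`)
with the association constant on a log scale for conditioning across
10⁴–10¹³ M⁻¹; stoichiometry floats by default. Standard errors are asymptotic
(Gauss–Newton covariance); the ka error is delta-method transformed from the
log scale. A fit is flagged non-converged rather than raising when the
optimiser fails or log-ka is undetermined to worse than ±5 (flat, ΔH ≈ 0
data). Two-class fits are returned in canonical descending-ka order to remove
the label-swap degeneracy, and carry an identifiability warning when the two
association constants are within a factor of 3. The apparent K_D of a
two-class fit is 1/K of the stoichiometric component (n nearest 2
Ca²⁺/protein); the other, non-stoichiometric component absorbs sample
heterogeneity. First-injection deletion drops the first remaining point while
keeping 1-based injection indices, so the molar-ratio axis of the surviving
points is unchanged.

Default heat noise is 0.1 kcal per mole of injectant, a typical single-digit
µcal integration scatter for these cell volumes; it is configurable.

## Fluorescence polarization (`fp`)

Polarization is P = (I_v − gI_h)/(I_v + gI_h). The default binding analysis
is the field's hyperbolic fit Y = B·X/(K_d + X) on baseline-subtracted
polarization (baseline = the zero-titrant point when present). With the
100 nM fluorescein-labeled peptide these assays require, a nanomolar binder
consumes a large fraction of the titrant, so the module also offers the
depletion-exact fit, which replaces the hyperbola with the quadratic bound
fraction [PL]/L; the two agree when L ≪ K_d and the hyperbolic K_d is biased
upward by roughly L/2 otherwise. Free titrant follows the depletion identity
free = total − L × (fractional saturation), floored at zero with a warning.

When binding is too tight to resolve, the titration still carries an upper
bound: `kd_upper_bound` declares a plateau when the last three
baseline-subtracted points each lie within `saturation_tol` (default 5%, a
declared choice) of their mean, and returns the smallest titrant
concentration from which the signal stays within tolerance of that plateau
level. The plateau level is taken from the data rather than from the
extrapolated fitted maximum B, because the extrapolated hyperbolic B
overshoots the depletion-limited plateau by ~15% for tight binders and would
then never declare saturation. Known structural limitation, stated plainly:
the bound fraction cannot exceed total/L, so with a 100 nM probe this rule
cannot return a bound much below ~100 nM however tight the binder is, and for
a 16 nM binder the plateau onset (hence the bound) sits near 300 nM. The
rule recovers the qualitative "saturation ⇒ tight binding" argument, not a
sharp estimate of K_d.

## Whole-cell metrics (`ephys_wholecell`)

Inward current is negative in files; metrics use magnitudes. r300 is the
current remaining 300 ms after depolarization onset (a 5 ms mean centred at
300 ms, configurable, since the published definition does not state a window)
divided by the peak magnitude before that time; values above 1 flag
facilitating traces. CDI is f300 = r300(Ba) − r300(Ca) and VDI = 1 −
r300(Ba), so f300 + r300(Ca) = r300(Ba) holds exactly by construction. Peak
current density divides the per-potential peak inward current by cell
capacitance; normalisation divides by |I_max|. Leak and capacitance
transients are assumed already subtracted, as in the standard acquisition
workflow.

## Single-channel analysis (`ephys_singlechannel`)

The generative model is k independent two-state Markov channels with exact
exponential dwell sampling, superposed, scaled by the unitary current,
low-pass filtered with a 4-pole Bessel (2 kHz on 10 kHz samples, the
cell-attached acquisition standard; steady-state initial conditions avoid a
startup transient) and overlaid with white Gaussian noise. Default close
rate 50 s⁻¹ (20 ms mean open dwell, long-mode L-type openings, two orders of
magnitude above the filter risetime so missed events are negligible);
unitary current −1.2 pA (110 mM Ba²⁺, 0 mV); default noise SD |i|/5 (SNR 5).

Idealization is the half-amplitude criterion generalised to multiple levels:
thresholds at (m − ½)·i, minimum event duration equal to the filter risetime
0.3321/f_c with shorter events merged into their longer neighbour, event
boundaries on the sample grid (no sub-sample interpolation). Before
thresholding, the trace is conditioned with a centred odd boxcar (default
~2.5 risetimes, 5 samples at 2 kHz/10 kHz) — the digital smoothing
conventionally applied ahead of automated event detection. A centred odd
boxcar leaves the half-amplitude crossing samples of isolated rectangular
events in place, while suppressing the white-noise excursions past the next
half-level that would otherwise fabricate brief simultaneous-opening events
and inflate the channel count. No missed-event correction beyond
minimum-duration merging is applied; this is a known downward bias source at
low SNR or with fast gating.

The channel count k is the maximum simultaneous open level observed across
all sweeps — reliable for k < 4 (a warning marks larger estimates) and an
undercount when simultaneous openings are rare, which is why the recovery
tests use sweep counts that make multi-level sojourns near-certain. NP_o is
the duration-weighted mean open level; P_o = NP_o/k. The mean ensemble
average is the pointwise mean across sweeps, whose plateau converges to
k·P_o·i for stationary gating.

## Structure metrics (`structure_metrics`)

Superposition is the closed-form Kabsch fit (SVD with determinant correction;
collinear selections are rejected). Ensemble precision superposes every model
on an iteratively recomputed mean structure over a backbone selection
(N, CA, C, O by default; N, CA, C offered, since depositions differ) and
reports both the mean RMSD to the mean structure and the mean pairwise RMSD —
the former is the common deposition convention, the latter is always ≥ by a
Jensen-type inequality. Residue ranges are inclusive in author numbering.
RDC analysis fits the five independent Saupe tensor elements by linear least
squares (D_i = Σ_ab S_ab v_ia v_ib, S symmetric traceless), back-calculates
couplings, and reports Q = RMS(D_meas − D_calc)/RMS(D_meas). PDB ensembles
are read through gemmi (MODEL/ENDMDL; alternative conformations removed).

## Synthetic data (`synthetic_data`)

Every generator is a pure function of (configuration, seed); presets pin the
study conditions (titration schedules and fitted constants for the ITC
scenarios, the 100 nM-probe FP regimes, the 900 ms/−60..+50 mV whole-cell
protocol with a bi-exponential decay that is faster for Ca²⁺, the
2 s/10 kHz/2 kHz cell-attached protocol, and a jittered rigid scaffold whose
expected precision is √3·σ·√((M−1)/M) for M models). What they do not
emulate: raw thermogram power traces (heats arrive already integrated),
instrument drift or dilution-heat baselines, FP g-factor calibration,
series-resistance and leak artefacts (assumed subtracted), modal gating or
correlated channel behaviour, and real conformational heterogeneity in
ensembles (jitter is isotropic and residue-independent). Tests passing on
these generators therefore demonstrate correctness of the estimators under
the stated statistical assumptions, not robustness to every pathology of
real recordings.

## Problem sizes

Stochastic recoveries use 20 noise seeds per scenario (medians reported);
single-channel recovery uses 80 sweeps of 2 s per condition (150 at
P_o = 0.05, where open events are scarce) over P_o ∈ {0.05, 0.2, 0.5} ×
k ∈ {1, 2, 3}; synthetic ensembles use 10 models × 30 residues. These sizes
give estimator noise comfortably inside the published uncertainties they are
compared against.
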