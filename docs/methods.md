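# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want spelled
out. All thermodynamic arithmetic uses Kelvin and kcal/mol internally
(R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹); Celsius appears only at I/O
boundaries.

## Footprinting quantification

The chain is strictly ratiometric: per peptide,
`Oxi% = I_oxi/(I_oxi + I_naked)` with the unmodified ("naked") partner
matched by peptide sequence and start position within the same
condition × temperature × replicate; then
`Relative Oxi% = Oxi%_O/(Oxi%_C + Oxi%_F)` with the two controls summed
without renormalisation; then `FC = RelOxi%(4 °C)/RelOxi%(30 °C)`,
pairing replicate r at 4 °C with replicate r at 30 °C. Controls are
taken from the same temperature as the oxidised sample. Residue-level
values sum intensities over all covering singly-oxidized peptides
before ratioing. Peptides with ≥2 oxidations are discarded (site
attribution would need localisation scoring, deliberately out of
scope); their unmodified partners are kept as denominators for the
singly-oxidized forms.

Calling uses strict inequalities — FC > 1.20 "more exposed",
FC < 0.83 "more buried", everything else "unchanged" — because the
±20% window exists to absorb replicate-level variability; a value *on*
the boundary has not cleared it. Both cutoffs are arguments everywhere
they appear. A fold change of 0.87, for instance, reads as "unchanged"
under the defaults even though it is a real 13% drop; narrowing the
window (e.g. lower cutoff 0.90) flips it to "more buried". Replicate
aggregation defaults to FC-per-replicate then mean ± s.e.m. (s.e.m.
reported only for ≥2 detections); a pooled mode (sum intensities, one
FC) is available via `aggregate="pooled"`.

### Synthetic intensity model

MS1+MS2 summed intensities are positive and roughly log-normal. The
generator factorises the noise into a run-level log-normal factor with
CV = `noise_cv`, shared by every form quantified in the same
condition × temperature × replicate run, and an independent per-record
measurement factor with CV = `noise_cv/3`. This mirrors label-free DIA
practice, where injection, ionisation and handling dominate variability
and affect all precursors of a run together, while per-precursor
integration error is smaller. Because the oxidized and naked forms share
their run factor, `Oxi%` cancels it exactly — which is precisely why
ratio-based footprinting tolerates instrument-level CVs that would
swamp absolute intensities. At CV 0.1 with 3 replicates the residue FC
error averages ≈0.03, comfortably inside the ±20% calling window.

Defaults: oxidized-condition efficiency 0.30 at 30 °C, control
efficiency 0.05, nominal intensity 10⁶, 3 biological replicates, one
covering peptide of ±4 residues per monitored site, temperatures fixed
at 4/30 °C (configurable). The planted FC multiplies the 4 °C
oxidised-condition efficiency, making the planted value the exact
population value of the full chain; at zero noise the pipeline returns
it to machine precision. What the generator does **not** emulate:
missing peptides, charge states, retention-time drift, localisation
ambiguity, or interference — so a green test suite demonstrates the
arithmetic and calling logic, not robustness to those failure modes.

## Gating thermodynamics

Open probability is the recorded current over the saturating-menthol
(1 mM) current, assuming menthol opens every channel. P_o is clipped to
(ε, 1−ε), ε = 10⁻⁴, to keep ln K_eq finite; clipped points are flagged,
logged and excluded from fitting by default. Currents below −25% of
the menthol maximum raise (polarity/leak); smaller negative excursions
are ordinary noise around a closed channel and are clipped.

K_eq = P_o/(1−P_o) is the conventional two-state open/closed constant.
`vant_hoff_fit` is exactly the stated construction — least squares of
ln K_eq on 1/T, slope −ΔH/R, intercept ΔS/R — with optional
inverse-variance weights. For noisy ramps `fit_current_trace` defaults
to `method="direct"`: a nonlinear fit of
`i(T) = i_max/(1+exp(ΔH/RT − ΔS/R))` to the raw currents, which is the
maximum-likelihood estimator when the recording noise is additive
Gaussian on current. The linearisation is kept (`method="linearized"`,
weights w = [P_o(1−P_o)]², the inverse variance current noise induces
on ln K_eq) and initialises the direct fit; the two agree to machine
precision on noiseless data. The linearised route alone is markedly
less efficient because ln amplifies noise wherever P_o nears 0 or 1:
at 5%-of-i_max noise its ΔH error is several-fold that of the direct
fit. Cold activation yields ΔH, ΔS < 0; no sign flipping anywhere.

Generator defaults ΔH = −100 kcal/mol, ΔS = −0.357 kcal/(mol·K) put
half-activation near 7 °C, and the default 4–20 °C ramp keeps P_o
inside the fittable window across the grid.

The ΔC_p model `ΔG(T) = ΔH₀ + ΔC_p(T−T₀) − ΔS₀T − TΔC_p ln(T/T₀)` has
d²ΔG/dT² = −ΔC_p/T: positive ΔC_p bends ΔG downward into a dome whose
two falling flanks are the cold- and heat-activated regimes; negative
ΔC_p inverts it. dΔG/dT at T₀ equals −ΔS₀.

## Spectroscopy

`[θ]_MR = 100·θ/(C·N·l)` is evaluated literally (θ in millidegrees, C
molar, l in cm). The melt model is a two-state van't Hoff unfolded
fraction, `f_u(T) = 1/(1+exp[(ΔH/R)(1/T − 1/T_mid)])`, mixing two
*linear* baselines; the unfolding ΔC_p is fixed at 0 (optional
extension). f_u(T_mid) = 1/2 by construction. The default melt signal
is the 222 nm helical band over a 10–50 °C scan in 2 °C steps.

Two numerical facts shape the fitter:

1. **Sign symmetry.** Negating ΔH while swapping the two baselines
   reproduces the identical curve, so the sign of ΔH is a labelling
   convention, not a measurable. `fit_two_state_melt` canonicalises to
   the cooling-populated branch (ΔH ≤ 0) by default
   (`populated_on="heating"` gives the mirror).
2. **Information limit.** With free linear baselines, a 21-point melt
   whose transition (|ΔH| = 44 kcal/mol) spans ≈18 °C of a 40 °C window
   determines ΔH only to an asymptotic sd of ≈10 kcal/mol at noise 3%
   of the transition amplitude (Fisher-information calculation,
   reproduced by simulation). Single-fit scatter of that size is
   therefore intrinsic to the design, not an optimiser defect; the
   estimator is unbiased in the median (−45 vs −44 over 100 melts) and
   T_mid is far better determined (median within 0.05 °C). Precision
   like "±2 kcal/mol" comes from replicate melts, not one scan.

The optimiser multistarts over |ΔH| ∈ {10…200}, both signs, both
baseline pairings and three midpoint guesses, keeping the lowest SSE —
without this, tilted-baseline local minima capture a noticeable
fraction of noisy fits. Flat signals and midpoints escaping the data
range raise `DegenerateFitError`. Confidence intervals are asymptotic
(1.96·√diag cov).

Emission peaks are located by a quadratic fit over ±3 points around the
argmax, applied to log intensity when the window is positive (exact for
Gaussian bands, hence sub-0.1 nm recovery of off-grid peaks); a flat
plateau of equal maxima resolves to its centroid, and an edge maximum
(monotone spectrum) raises. Shifts are reported against the
highest-temperature spectrum, negative = blue.

## Hydrophobicity scan

Built-in scales ship as package data with citations: the Hessa
translocon ΔG_app scale and the Moon–Fleming side-chain water-to-bilayer
transfer scale (values overridable via `from_tsv`; published variants
of these scales differ in detail). Both are oriented so hydrophobic
residues carry lower values, which makes "exposed site ⇒ positive
ΔH-vs-SCH slope" the hypothesis-consistent direction. Slope factors are
plain OLS; ≥2 distinct scale values are required, and shared-value
degenerate sets raise. Quadrant classification is by the signs of
(FC−1) and the slope; FC exactly 1 or slope exactly 0 is indeterminate
and excluded from proportions but counted. Threshold filtering uses
|slope| by default (`signed=True` available) because both signs carry
hypothesis-consistent sites.

## Hydration energetics

Energy brackets are linear: n waters × bonds-per-water × [1.5, 9.5]
kcal/mol per hydrogen bond (both bracket ends configurable), scaled by
the subunit count for a homotetramer. Fractional water counts
(trajectory averages) are accepted. Sufficiency compares the bracket's
upper end with the *magnitude* of the gating enthalpy (≥ at the
boundary), since cold-activation ΔH is negative. This is an order-of-
magnitude device, not a free-energy calculation; explicit-solvent or
force-field energetics are out of scope.

## Ensemble descriptors

Snapshots are rigidly superimposed on the fixed reference (first model
by default) with the Kabsch algorithm — proper rotations only, so
mirror-image inputs keep a documented residual rather than being
inverted; collinear references raise. RMSF follows the fluctuation
formula per subunit position, then averages the equivalent positions of
the tetramer. Fractional change is (cold − warm)/cold with a ±20%
band separating specific rigidification from uniform thermal scaling;
zero-cold-RMSF residues are NaN and never flagged. The radial profile
is the mean perpendicular distance to the channel axis (default z)
through the per-snapshot Cα centroid; cold-minus-warm deltas are
negative where residues pack inward. Water contacts count water oxygens
strictly inside the cutoff (default 3.5 Å, the first hydration shell;
the literature leaves this choice open) of the residue Cα, averaged
over subunits and snapshots.

Finite-size note: superposition absorbs 6 rigid-body degrees of
freedom, shrinking RMSF by ≈√(1−2/N_atoms); the isotropic closed form
σ√3 is met within 2% once the system has ≳100 atoms. Desk-scale
ensembles are Cα-only on a deliberately coarse ring geometry (default
ring radius 25 Å, axial spacing 12 Å) whose residue separations exceed
the water cutoff, so planted contact counts are exact; planted waters
co-move with their residue, bulk decoys sit beyond the cutoff. The
generator emulates none of the correlated, anharmonic motion of a real
trajectory — descriptor arithmetic is what the tests certify.

## Pipeline

`run_pipeline` executes simulate → footprint → thermo → scan →
hydration → ensemble from one config. The global seed fans out through
`numpy.random.SeedSequence.spawn` in a fixed order (study, cold
ensemble, warm ensemble), so runs are bit-reproducible and stages can
be regenerated in isolation. The bundled study generator plants every
site in agreement with the hypothesis (exposed ⇒ FC > 1 and positive
slope; buried ⇒ FC < 1 and negative slope, with all mutants
half-activating at 12.5 °C so every ramp stays fittable), which pins
the end-to-end consistency proportion at 1.0 — an integration oracle,
not an empirical claim. Report TSVs carry full-precision values; the
JSON manifest lists exactly the files produced.

## Problem sizes

Default desk-scale sizes — 3 replicates, 17-point ramps, 21-point
melts, 6-site × 5-mutant studies, 10⁴-snapshot Gaussian ensembles for
the RMSF limit and 50-snapshot ensembles elsewhere — were chosen so
every stage's estimator operates in the regime its contracts describe
while the full suite and the reproduction script each run in well under
a minute of compute per study.
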