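# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that were genuinely open.

## LUV permeabilization kinetics

Liposomes loaded with a dye/quencher pair report pore formation as a
fluorescence rise. Normalization is anchored to the plate's own controls:
F₀ is the **minimum** reading across all buffer wells over the entire assay
(the darkest the plate ever gets) and F₁₀₀ the **mean** across all 1% CHAPS
wells (full solubilization). Because F₁₀₀ is a mean, normalized samples can
legitimately exceed 100%; normalization therefore never clips. Clipping to
[0, 1] happens only where fractions are required, at the synergy stage.

Kinetics follow the asymmetric five-parameter sigmoid
y = B + (T−B)/(1+(E/x)^H)^S with box constraints 0 < S ≤ 10, H ∈ (0, 20],
E ∈ (0, 10·t_max]. T ≥ B is enforced structurally by fitting the rise
amplitude T−B on [0, ∞) rather than rejecting iterates. Initialization:
B₀ = min(y), T₀ = max(y), E₀ = half-rise time by linear interpolation,
H₀ = S₀ = 1; trust-region reflective least squares with tight tolerances
(1e−15) so that zero-noise roundtrips are exact to machine precision.

The model is singular at x = 0 but plate readers emit a t = 0 read; by
default that first timestamp is reassigned to the midpoint of the first
read interval (configurable: `midpoint` / `keep`, where `keep` evaluates
the model at its x→0⁺ limit B).

The maximal rate (slope at the inflection point) is computed in closed
form; it exists only when H·S > 1, and requesting it otherwise is an error
rather than a NaN. The closed form is continuously verified against a
brute-force numerical oracle (central-difference derivative maximized over
a log-spaced grid with bounded refinement) in the tests and the acceptance
script. When differencing numerically, the derivative must be taken on the
transition term y − B: differencing the full model about a large offset B
suffers catastrophic cancellation at small x and can fabricate spurious
maxima.

**Replicates.** Instruments report technical replicates; whether to average
before or after fitting is an open choice. The default fits the replicate
mean (averaging suppresses noise where the model is most sloppy);
`average_replicates=False` fits each well separately.

**Identifiability.** The 5PL is a sloppy model: E, H and S trade off along
near-flat directions of the residual surface. At per-reading noise of 2% of
the rise amplitude on a 90-point grid, the asymptotic (Cramér–Rao) floor on
the median relative error of S is on the order of 10% for every realistic
curve shape, and the fitter attains that floor (the acceptance script
measures ≈ 13–14% for the worst parameter at the standard assay design,
with B and T recovered to fractions of a percent and E, H to 3–5%). Per-
parameter inference on S from a single trace at this noise level is
therefore not meaningful; derived quantities (endpoint, maximal rate) and
the amplitude/scale parameters are the robust readouts.

## Bliss synergy

Responses are fractions; the per-cell reference is e = a + b − a·b from the
cell's own row/column monotherapy margins, and the matrix score is
100 × mean excess over cells with both doses > 0. Margin and vehicle cells
never enter the summary. This is the plain Bliss model: response-surface
tools layer smoothing corrections on top, so scores are comparable to such
tools in sign and ordering, not guaranteed numerically identical. Dose axes
must be strictly ascending and include 0 first, which also makes duplicate
vehicle rows unrepresentable.

## FLAMBE polarization

Traces are treated non-parametrically: the readouts are Tmax (argmax time)
and EP (final reading) of the replicate-averaged trace, normalized per
metric to the free-peptide (0) and protein-vehicle (1) controls, with the
shift distance Δs = √(ΔTmax² + ΔEP²) between paired conditions and a
control-normalized trapezoidal AUC using the same 0/1 affine convention
(the convention for AUC normalization was an open choice; matching the
metric convention keeps all normalized quantities on one scale).

The "no binding kinetics → Tmax := 0" rule needs an amplitude criterion.
Default: a trace whose dynamic amplitude (max − min) is ≤ 10% of the
protein-control's dynamic amplitude is flagged and gets Tmax = 0; the flag
is always reported so the rule is auditable. Amplitude is measured max −
min rather than max − first-reading because with fast association (k_a ≳
1/30 s⁻¹ at 30 s read intervals) binding completes before the first read
and a first-reading convention would misflag genuine binders. Tmax is
normalized in seconds; on a uniform grid, cycle-index normalization gives
identical normalized values.

The generator's rise–decay model P(t) = P_free + A(1−e^(−k_a t))e^(−k_d t)
is a convenience with a controllable analytic peak time
t_peak = ln(1 + k_a/k_d)/k_a (k_d = 0 gives a saturating binder); the
analysis never assumes it.

## MST

One-phase decay fit restricted to a stated window (default 5–35 s after
IR-on) to avoid the temperature-jump transient and late convection; K ≥ 0
is enforced and a fit collapsing to zero decay or zero amplitude is flagged
non-decaying rather than rejected. The single-point inversion
K = −ln((y−Y_plateau)/(Y₀−Y_plateau))/x is exact on model points up to
float cancellation, which becomes visible when K·x ≳ 20 (the ratio
underflows toward the plateau); instrument-realistic K (≲ 0.3 s⁻¹ over a
35 s window) is well conditioned.

The temperature jump is mean(post-window) − mean(pre-window) with defaults
−1–0 s and 0.5–1.5 s around IR-on (instrument timing varies; both windows
are configurable). EC50 comes from a four-parameter log-logistic fit with
EC50 parameterized on log₁₀ scale for conditioning; a Wald 95% CI is
propagated from the log-EC50 standard error, and EC50s outside the tested
concentration range are flagged extrapolated. The concentration-response
slope is OLS on a linear concentration axis by default (`log_x=True` is
available; which axis a given instrument report uses is not standardized).

## NMR chemical-shift perturbations

Δδ = √((Δ¹H² + 0.2·Δ¹⁵N²)/2). A residue is measured only if assigned in
both spectra; prolines (no backbone amide) and missing/overlapped residues
carry statuses and never enter the mean/SD. Thresholds are mean + 1·SD and
mean + 2·SD over measured residues with **sample** SD (n−1) by default
(`population` available; the convention is reported in the output).
Classification uses strict exceedance, and a residue above both thresholds
takes the higher class. For titration series, Δδ is averaged per residue
over the tables where it is measured, and thresholds may be computed either
per concentration or on the averaged table — both modes are exposed because
either is defensible; the CLI thresholds the averaged table.

## Thermal shift

Tm = temperature of maximal dF/dT, central differences after a
moving-average smooth (default window 5 points ≈ 2 °C at a 0.5 °C step;
window 1 = raw). Smoothing-before-differentiation trades a slight peak
broadening for noise suppression; at 2% amplitude noise the estimator stays
within 2 grid steps of the true midpoint (measured across 200 simulations
in the acceptance script). Derivative maxima at the ramp boundary and flat-
derivative ties are flagged; a curve with no positive derivative raises a
no-transition error. Tm is invariant under affine rescaling of
fluorescence, so vendor normalization does not matter. Statistical tests
across replicate ΔTm values are out of scope; per-replicate Tm values are
exported for external statistics.

## Synthetic data: what it does and does not emulate

Generators draw from exactly the model family the corresponding stage
assumes, plus additive i.i.d. Gaussian noise per reading (a plate-reader
shot-noise approximation). Defaults mirror the real assay formats: LUV
plates read every 55 s for 90 min with buffer/CHAPS controls; FLAMBE plates
every 30 s for 60 min with free-peptide and protein-vehicle controls; MST
traces with a pre-IR window and a 35 s heated phase; 25→95 °C melts at
0.5 °C steps; ~190-residue peak lists with prolines, missing assignments
and an injected perturbed set.

Not emulated: heteroscedastic or correlated noise, baseline drift,
evaporation and edge effects, vesicle-to-vesicle heterogeneity, photo-
bleaching, aggregation artifacts in MST, multi-transition melts, and peak
overlap/tracking in spectra (inputs are assigned peak lists). Passing the
recovery tests therefore shows the pipeline is correct and well calibrated
under its own model assumptions — it does not certify robustness to every
real-instrument artifact, which is what the flags (degenerate, boundary,
tie, non-decaying, extrapolated, no-binding) are for on real data.

Generators are pure functions of (spec, seed); a titration series of peak
lists can share one reference draw while varying jitter via a separate
jitter seed.

## Problem sizes

Verification runs use the assay-native sizes: 90–98-point kinetic traces,
5×5 dose matrices, 120-point polarization traces, 400-point MST traces over
9 concentrations, 141-point melts, 60–192-residue peak lists; Monte-Carlo
statements use 200 seeded replicates, and the closed-form/oracle sweep uses
1000 random parameter sets.
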