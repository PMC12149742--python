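# Methods

This note documents the models, numerical choices and open design
decisions behind `ephysdecomp`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The neuron model

A single isopotential compartment:

    C dV/dt = I_inj − g_Na m³h (V − E_Na) − g_DR n⁴ (V − E_K)
                     − g_A a³b (V − E_K) − g_L (V − E_L)

Units are the patch-clamp set throughout: pF, nS, mV, pA, ms (so I/C is
directly mV/ms).  The sodium (m³h) and delayed-rectifier (n⁴) rate
functions are the classic Connor–Stevens forms.  All m/h/n rates are
slowed by a global factor `TEMP_RATE_SCALE = 0.5`, a Q10-style correction
that represents room-temperature recording and widens the action potential
into the 1–3 ms range typical of cultured cortical neurons.

The A-type conductance keeps the Connor–Stevens a³b structure but uses
steep Boltzmann steady-state curves (activation V½ −35 mV / slope 10 mV on
the gate, giving a half-activation of the peak conductance a³ near −21 mV;
inactivation V½ −70 mV / slope 7 mV; τa ≈ 0.4–1.5 ms, τb = 15 ms).  Two
properties motivated this over the original Connor–Stevens voltage
dependence: (i) the CS A-current carries a large steady-state "window"
conductance near rest, so the resting potential moves by more than 10 mV
when g_A is scaled — which would conflate the A-current's spike-level
effect with a resting-state confound; (ii) with the steep curves the
window conductance is negligible, the resting potential is insensitive to
g_A, and increasing g_A monotonically narrows the spike, which is exactly
the phenomenology of a 4-AP-sensitive transient current that the analysis
chain is meant to quantify.  τb (15 ms) is slower than a spike but much
faster than a 0.5-s step, so the A-current is transient under voltage
clamp (captured by the `peak` statistic) while the delayed rectifier
dominates the `steady` statistic.

Default parameters were fixed once, by scanning against a behavioral
envelope rather than any recorded data: C = 100 pF, g_Na = 5000 nS,
g_DR = 300 nS, g_A = 200 nS, g_L = 8 nS, E_Na = +55 mV, E_K = −90 mV,
E_L = −64 mV.  The envelope: resting potential in [−75, −60] mV (realized:
−65.0 mV), rheobase inside the −200…400 pA step grid (realized: 150 pA),
AP peak above 0 mV (realized: ≈ +51 mV), FWHM 1–3 ms (realized ≈ 1.5 ms),
f–I rates increasing over the first suprathreshold steps, and FWHM
strictly decreasing over g_A ∈ [default, 2× default].  E_L sits slightly
above the realized resting potential because the standing delayed-rectifier
current at rest must be balanced by a small depolarizing leak.  No
capacitance or conductance magnitudes are available from recordings, so
these defaults are free choices constrained only by that envelope.

## Integration and recording

Current clamp uses classic RK4 on the full state (V, m, h, n, a, b) at a
fixed internal step of 0.005 ms.  First-order schemes (exponential Euler)
were rejected because their operator-splitting error makes the recorded
trajectory inconsistent with the recorded channel currents by several
percent of the peak outward current during the AP upstroke, which would
defeat the charge-balance oracle below.  Voltage clamp integrates only the
gates, with exponential updates that are exact for piecewise-constant
command voltages; the clamp is ideal (no series-resistance error, no
capacitive transient) — experimental recordings compensate these, and the
idealization is the cleaner target for subtraction analyses.

Output is decimated to the protocol sampling grid (50 kHz default).  Each
sweep is preceded by 300 ms of unrecorded settling at the holding command.
Recording noise is additive Gaussian on the recorded signal only (defaults
0.2 mV / 5 pA); the dynamics are deterministic and the ground truth
(per-channel currents, noise-free voltage, true rheobase from 0 mV
upward crossings, generated event times/amplitudes) is returned noise-free.
Every stochastic generator takes an explicit seed; there is no hidden
global randomness.

## Derivative estimation

One shared Savitzky–Golay utility provides dV/dt, with two parameter sets
for two jobs:

- **slope-threshold detection and AP features** (10 mV/ms onset, 20 mV/ms
  threshold): window 21 samples (0.42 ms at 50 kHz), order 3.  At 0.2 mV
  recording noise this keeps derivative noise well under 1 mV/ms.
- **net-current reconstruction** (−C dV/dt): window 7, order 5, a
  near-interpolating stencil.  The wide detection window would bias the
  ~0.3 ms upstroke by tens of percent; the short stencil tracks the summed
  simulated channel currents to ≪ 1% of the peak outward current (the
  tests assert < 2%).

A single moving-average+central-difference setting cannot serve both
purposes at 50 kHz; this split is deliberate and is asserted by the
charge-balance tests.

## Feature definitions and conventions

- AP onset: first sample of a contiguous run with smoothed dV/dt above
  10 mV/ms whose excursion reaches the validation level (−20 mV default);
  the slope rule alone fires on noise.  Onsets closer than 2 ms to the
  previous accepted onset are rejected.
- FWHM is referenced to the *onset* voltage: the duration at half of
  (peak − onset), measured from the onset-side crossing.  The alternative
  reference (half of peak − baseline) is not used.
- "Decay time at 37%" is read as the e-fold convention: time from the peak
  until the voltage has completed 63% of the drop toward the post-spike
  minimum, i.e. reached the 37%-remaining level.
- The amplitude baseline is the mean voltage over the 50 ms before step
  onset.  Latency runs from step onset to the first AP *onset* (not peak).
- Adaptation index: mean of (ISIᵢ₊₁ − ISIᵢ)/(ISIᵢ₊₁ + ISIᵢ) after
  discarding the first two ISIs; undefined (NaN) with fewer than four
  ISIs.  The raw pairwise statistic (no skip) is antisymmetric under
  sequence reversal, which the property tests exploit.
- The 10-ms passive pulse is shorter than the membrane time constant, so
  ΔV_ss is taken from the fitted single-exponential asymptote rather than
  the last sample; R_in = |ΔV_ss| / 50 pA.
- All level crossings use sub-sample linear interpolation.

## AP current decomposition

The analysis window runs from 1 ms before onset to the post-spike minimum.
The raw form −C·dV/dt (which still contains the injected step) and the
injection-corrected form −C·dV/dt + I_inj are both computed; on simulated
data they differ by exactly the step amplitude, quantifying the
approximation made when the correction is omitted.  The inward (Na⁺) lobe
is measured between onset and 0.5 ms past the peak, the outward (K⁺) lobe
between peak and post-spike minimum; peaks (pA) and charges (pC) are both
reported, since practice varies in which of the two is quantified.
Capacitance must be supplied; no estimation from the trace is attempted.

## Voltage-clamp analysis

Baseline (holding) current — the mean over the 20 ms before step onset —
is subtracted per sweep; there is no P/N leak protocol.  The `steady`
statistic is the mean over the last 50 ms of the 0.5-s step, `peak` the
largest baseline deviation within the first 50 ms; the A-type current
defaults to `peak` and the delayed rectifier to `steady`, and both
statistics are always available since reporting conventions differ.
Pharmacological subtraction is samplewise on sweep families (or pointwise
on I/V curves); for the linear `steady` statistic, measuring then
subtracting commutes with subtracting then measuring, and the tests assert
it.  Conductance is g = I/(V − E_rev) with a 10 mV driving-force guard;
E_rev defaults to the K⁺ Nernst potential of the standard solutions
(5 mM out / 130 mM in → −83.7 mV at 25 °C).  Activation is fitted in the
standard single-slope form g_norm = 1/(1+exp((V½−V)/k)); the equivalent
gating charge is derived afterwards as z = RT/(F·k) with RT/F = 25.7 mV
at 25 °C, because fitting z and a separate thermal factor jointly would
be unidentifiable.  Fits are multi-start
least squares from a fixed grid (deterministic given the data), with the
95% CI on V½ from the asymptotic standard error.  Junction potentials are
*not* subtracted from command voltages (matching the recording
convention); the `ljp` module reports the correction for optional
post-hoc use.

## Synaptic event detection

Scaled-template (Clements–Bekkers) detection: at every sample a
bi-exponential template (unit peak; length = rise + 6 decay constants) is
fitted to the following window by least squares with free offset and
scale, and the score is scale / SD of the fit residuals.  With this
normalization the score of a true event approximates its amplitude in
noise-SD units, and pure-noise scores essentially never reach the default
criterion of 3.5 — false positives are controlled by construction rather
than by tuning.  Events are one per contiguous supra-criterion run of the
score (at the run's score maximum), with long runs split at prominent
interior peaks at least one template rise time apart.  The template is
derived from stated kinetics, never learned from data, for determinism.
On current-clamp traces, epochs from 2 ms before to 20 ms after each
detected AP onset are excluded and the excluded time is removed from the
frequency denominator.  Recordings shorter than 2 min trigger a warning,
not an error.

## AIS quantification

Profiles are consumed as two-column (distance, intensity) tables; imaging
and tracing are upstream.  The profile is smoothed with a 1 µm moving
average, baseline-subtracted (baseline = mean of the first and last 10% of
samples, robust to soma bleed-through), normalized to its maximum, and
thresholded at 0.33 of the normalized peak — the threshold convention of
the widely used AIS-quantification scripts; start and end are the first
and last crossings with sub-grid interpolation.  Calls are exactly
invariant to intensity scaling and equivariant to translation, and raising
the threshold can only shorten the called length.  Profiles that do not
return below threshold at both ends are rejected as clipped.  The
synthetic generator produces a plateau with Gaussian-smoothed edges whose
threshold crossings have the closed form start + σ·Φ⁻¹(f) (Φ the standard
normal CDF), used as the oracle.

## Liquid junction potential

Two implementations over one ion table: the Henderson closed form and a
numerical stationary Nernst–Planck boundary-value solver (constant fluxes,
local electroneutrality, zero net current, shooting on the fluxes — the
model behind the common LJP calculator software).  For the recording
solutions here the two agree to ≈ 0.3 mV, and both reproduce textbook
closed forms (bi-ionic KCl dilution; KCl‖NaCl ≈ +4.4 mV).  The sign
convention is φ(bath) − φ(pipette), positive for a potassium-gluconate
pipette in a NaCl bath.

Speciation rules: salts dissociate fully; Mg-ATP → Mg²⁺ + ATP²⁻;
Na-GTP → 2 Na⁺ + GTP²⁻; EGTA is divalent-anionic at pH ≈ 7.2; HEPES
(pKa ≈ 7.5) is 50% anionic, with the titrated charge balanced by the
hydroxide counter-cation (KOH / NaOH); sugars are neutral and excluded.
Limiting equivalent conductivities (25 °C, S·cm²/eq) are frozen in
`MOBILITY_TABLE`: K⁺ 73.5, Na⁺ 50.11, Cl⁻ 76.35, Mg²⁺ 53.06, Ca²⁺ 59.5
(standard tables), gluconate⁻ 24.3 and HEPES⁻ 22.05 (the values used by
the JPCalc family of calculators, 0.33 and 0.30 of K⁺), and nominal 24–25
for the nucleotide and chelator anions, whose sub-millimolar to few-mM
concentrations make the result insensitive to them.

For the stated pipette/bath pair these choices give 14.6 mV (Henderson)
and 14.9 mV (stationary Nernst–Planck) at 298.15 K.  A sensitivity scan
over the chemically defensible speciation variants (HEPES 0–100% anionic,
ATP⁴⁻/EGTA⁴⁻ with extra titration, MgATP²⁻ complexation, untitrated bath
buffer) spans roughly 14.4–15.7 mV, and a 1% perturbation of any single
compound moves the result by well under 0.5 mV.  Values much above this
range would require an unsupported mobility for the dominant slow anion
(gluconate well below 20 S·cm²/eq).  Published junction potentials for
this solution class vary by 1–2 mV across calculators precisely because
of such table and speciation differences; the package reports what its
documented constants produce rather than tuning them to any external
number.

## Statistics

Per-feature group comparisons are gated by per-group Shapiro–Wilk tests at
α = 0.05; any non-normal group routes the *whole* comparison
non-parametric (the conservative convention).  Parametric:
unpaired t-test (two groups) or one-way ANOVA with Tukey HSD; otherwise
Wilcoxon rank-sum or Kruskal–Wallis.  Grouped f–I (and I/V) designs use a
two-way mixed ANOVA (treatment between cells, current level within, via
pingouin) with Šídák-corrected per-level contrasts,
α′ = 1 − (1 − α)^(1/m).  The analysis unit is the cell; per-culture
averaging is available (`aggregate="culture"`) for figure-style summaries.
The routed procedure's empirical size under Gaussian nulls is asserted
≤ 0.07 at nominal α = 0.05 in the acceptance suite (2000 replicates,
n = 10/group).  The test statistics themselves are scipy/statsmodels/
pingouin implementations; the package owns only the routing and the
contrast table.

## The synthetic experiment pipeline

`run_pipeline` models the chronic-blockade effect solely as a g_A
multiplier per treatment group (with optional AIS-profile lengthening for
the AIS stage), cell-to-cell variability as 5% lognormal jitter on the
conductances, and derives every seed deterministically from the experiment
seed.  It makes no claim of reproducing measured effect sizes from
recordings — group contrasts in the synthetic experiment are direction
checks (higher g_A → narrower spikes) plus null-calibration runs.  Outputs
(feature tables, f–I tables, AIS measures, Boltzmann fits, statistics) are
hashed into a manifest so reruns can be verified byte for byte.

## What the synthetic data does and does not show

The generator reproduces the statistical and dynamical structure the
analyses assume: stiff AP waveforms at 50 kHz with known underlying
currents, step families on the stated grids, Poisson event trains with
bi-exponential kernels and log-normal amplitudes, Gaussian-edged intensity
plateaus, and additive Gaussian recording noise.  It does not emulate
electrode artifacts (series resistance, bridge imbalance, capacitive
transients), drift, non-stationary noise, channel stochasticity,
multicompartment morphology, temperature gradients, or correlated synaptic
bombardment.  Passing tests therefore demonstrate correctness of the
measurement definitions and pipelines under the stated model, not
robustness to every artifact of real recordings.

## Problem sizes

The test and acceptance runs use: full 13-sweep step families at 50 kHz
for detection/feature oracles; 16-sweep 0.5-s voltage-clamp families for
the subtraction chain; ≥ 20 APs over eight random parameter draws for the
charge-balance oracle; 200 noisy G/V curves for Boltzmann recovery; one
120-s event trace plus 50 one-minute noise traces for detection recovery
and false-positive control; and 2000 Gaussian-null replicates at
n = 10/group for the size of the routed statistics.  These sizes were
chosen so each check is statistically meaningful while the whole suite
runs comfortably on a laptop-class single core.

## Known limitations

- The model is a point neuron: AIS geometry enters only through the
  profile-analysis module, never through the voltage dynamics, so
  AIS-position effects on excitability are out of reach by design.
- The junction-potential result depends on the frozen mobility/speciation
  table (documented above); activity corrections and pH titration curves
  are not modeled.
- The Boltzmann CI is asymptotic (from the least-squares covariance), not
  profile-likelihood based.
- Event detection assumes a known template shape; grossly wrong kinetics
  degrade recall before they inflate false positives.
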