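# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic data can show. Units follow the clinical conventions:
concentrations in µg/mL (propofol effect site), times in seconds, EMG
amplitudes in µV, frequencies in Hz.

## Pharmacokinetic model

Plasma and effect-site propofol follow the covariate-adjusted Schnider
three-compartment model with an effect compartment:

    dA1/dt = R(t) − (k10 + k12 + k13) A1 + k21 A2 + k31 A3
    dA2/dt = k12 A1 − k21 A2
    dA3/dt = k13 A1 − k31 A3
    Cp = A1/V1,   dCe/dt = ke0 (Cp − Ce)

with V1 = 4.27 L, V2 = 18.9 − 0.391(age − 53) L, V3 = 238 L,
Cl1 = 1.89 + 0.0456(wt − 77) − 0.0681(LBM − 59) + 0.0264(ht − 177) L/min,
Cl2 = 1.29 − 0.024(age − 53) L/min, Cl3 = 0.836 L/min, and lean body mass by
the sex-specific James equations. All constants live in one table
(`pkpd.SCHNIDER_CONSTANTS`). The effect-site rate constant is fixed at
ke0 = 0.456 min⁻¹, the value used by the published effect-site model and by
common TCI pumps; the protocol description does not print it, so it is an
explicit, configurable assumption (`pk_ke0_per_min`).

The infusion protocol is zero-order: 3.3 mL/kg/h of 1% (10 mg/mL) propofol,
i.e. 0.55·weight mg/min, started at t = 0 and stopped at the first aRASS −5
assessment. Remifentanil is held as a constant covariate (effect-site target
2.5 ng/mL, assumed equilibrated before baseline) and is never simulated —
the analysis never uses it as a variable.

**Integrator.** Fixed-step classical Runge–Kutta at dt = 0.1 s. The system
is linear and only mildly stiff at these rate constants; a fixed step keeps
reruns bit-identical, and the suite checks convergence (halving dt moves
Ce(t_end) by < 0.1%), mass balance (compartments + eliminated = infused
within 0.5%), the one-compartment closed form (0.1%), and the long-run
plasma steady state Cp → R/Cl1 (1%; the 238-L deep compartment makes this an
hours-long limit, checked at dt = 2 s). Tiny negative round-off amounts are
clipped to zero. Age is drawn within [18, 100] because the Schnider V2
becomes non-positive above age ≈ 101.

## Synthetic sessions

Each patient is a draw of demographics (age 61 ± 13 y, weight 72 ± 11 kg,
height 162 ± 9 cm, 64% female — the studied cohort's composition) and three
abolition thresholds: Ce at loss of R2 (1.45 ± 0.85), loss of R1
(2.99 ± 1.19) and loss of responsiveness (4.22 ± 1.24 µg/mL). Each
threshold is marginally a normal truncated below at 0.1 µg/mL with those
moments.

**Threshold dependence.** The three thresholds share a latent
drug-sensitivity factor through an equicorrelated Gaussian copula
(ρ = 0.9 by default): a patient who loses R2 at a low concentration tends
to lose R1 and responsiveness at low concentrations too. This choice keeps
the cohort-level marginal means and SDs exactly at their calibrated values
for any ρ — an alternative scheme that draws the three thresholds
independently and rejects unordered triples (`threshold_sampling=
"independent"`, available for reference) inflates the conditional mean at
LORP to ≈ 4.65 µg/mL and the LORP−LOR1 gap to ≈ 1.70 µg/mL, well away from
the cohort summaries it is meant to emulate, because ordering rejects ~38%
of triples asymmetrically. ρ = 1 (a single latent factor) is avoided
because it collapses patient heterogeneity to one dimension: effect-site
concentration plus any amplitude-tracking feature would then reconstruct
the sedation class exactly and the pooled multinomial fit has no finite
MLE. Note one inherent offset: truncating N(1.45, 0.85²) below at
0.1 µg/mL raises its mean to 1.552 — visible as a ~+0.1 µg/mL shift in
cohort LOR2 statistics under any sampling scheme honoring that floor.

**Sweeps.** 2000 samples at 10 kHz (200 ms). Each sweep is 20-Hz
high-passed (4th-order Butterworth, zero-phase) white Gaussian noise
(default SD 2 µV) plus the two component bursts. A burst is a
Gaussian-envelope cosine: R1 onset 10.5 ms, envelope SD 1.5 ms, carrier
150 Hz, baseline amplitude 80 µV; R2 onset 32 ms, envelope SD 12 ms,
carrier 60 Hz, 50 µV. `latency` is the component *onset* (the clinical
marking convention); the envelope is centred two envelope SDs after onset,
which keeps > 99% of R1 energy inside the 10–25 ms analysis window and
> 99% of R2 energy inside 25–200 ms. A small Gaussian latency jitter
(SD 0.3 ms) decorrelates repeats. Component amplitude scales as
max(0, 1 − Ce/Ce_abolition)^γ with γ = 1 (linear fade, analyzable) and the
abolition thresholds tied to the patient's drawn LOR2/LOR1 concentrations,
so the component-loss endpoints are calibrated by construction. No stimulus
artifact is synthesized: the analysis windows start at 10 ms, so it would
be invisible to the pipeline.

**Sedation staircase.** aRASS score −k is assigned when Ce ≥ f_k · Ce_LORP
with fractions (0.45, 0.62, 0.78, 0.92, 1.00). At the cohort mean
thresholds, loss of R2 (34% of the LORP concentration) happens at score 0
and loss of R1 (71%) at score −2, matching the cohort's median scores at
those endpoints; −5 is reached exactly at Ce_LORP. Assessments share the
6-s stimulus cadence; four drug-free baseline sweeps precede the infusion.
The recorded trace is monotone because Ce is nondecreasing while the
infusion runs and the session ends at the first −5.

**What the generator does not emulate:** habituation of R2 across repeated
stimulation, bilateral recording, stimulus-intensity titration, EMG
artifacts and non-stationary noise, neuromuscular-blockade effects, and any
remifentanil–propofol interaction. Passing the calibration tests therefore
shows internal consistency of the pipeline under the stated statistical
structure, not performance on operating-room data.

## Preprocessing and features

Fixed conditioning order per sweep: subtract the mean (DC removal), remove
the least-squares line, average the four most recent sweeps (sliding
window, one averaged record per stimulus, preserving the 6-s cadence), cut
half-open windows T1 = [10, 25) ms and T2 = [25, 200) ms (the 25-ms sample
belongs to T2), and rectify/normalize *only* for the two time-domain
features. Spectral features are computed on the detrended, un-rectified
window: rectification folds the spectrum and would destroy the
physiological frequency content; this is a documented interpretation, since
the processing description does not state on which branch the PSD was
taken.

The Welch PSD uses Hamming-tapered segments at 50% overlap with the segment
length chosen so the window yields exactly 8 averaged periodograms
(388 samples for T2; nfft = 512, density scaling, so Σ power × Δf equals
the window variance). T1 (150 samples) cannot support that split and falls
back to a single Hamming periodogram zero-padded to nfft = 256. Feature
definitions follow the standard EMG conventions; three details are fixed
here because they admit variants: f_median and P_fmean interpolate linearly
between bins; P_bandwidth is the span between the *outermost* half-power
crossings (not the main-lobe −3 dB width); SNR uses a median-bin noise-floor
estimate, 10·log10(P_total / (n_bins · median power)). Spectral entropy is
Shannon entropy of the PSD normalized by log2(n_bins), so 0 is a single
occupied bin and 1 a flat spectrum. All powers are reported in linear
units; only SNR is in dB.

## Prediction probability

Pk is computed by exhaustive cross-class pair counting on observations
pooled over patients (O(n²) is fine at these sizes); pairs tied on class
are ignored, indicator ties count half. Classes are ordered numerically
(aRASS 0 > −1 > … > −5). Because published tables report Pk ≥ 0.5 even for
negatively correlated features, the direction-folded value max(Pk, 1 − Pk)
is reported alongside the raw one. The standard error is a delete-one
jackknife over observations (computed incrementally from per-observation
pair counts); replicates whose leave-one-out subset degenerates to a single
class are skipped with a warning. Correlations default to an automatic
choice — Pearson if both variables pass a Kolmogorov–Smirnov normality test
at 0.05, Spearman otherwise.

## Multinomial model

aRASS is modelled as a nominal multinomial logit with the most-awake level
present as the reference class, so the deepest level keeps its own logit.
Fitting is Newton–Raphson on the full block Hessian with step-halving
(likelihood ascent is guaranteed); convergence at max |score| < 1e-6 or
relative log-likelihood change < 1e-10. Probabilities use log-sum-exp.
Predictors are *not* standardized: the published fixed-coefficient logit is
expressed in raw units, and its slope of 1441.537 on a [0, 1]-ranged
entropy shows why a raw-unit divergence cap would misfire. Separation is
therefore detected on the standardized scale (|slope| × predictor SD > 500
during iteration) plus a post-convergence check: a fit that classifies
every observation with probability ≈ 1 has its MLE at infinity regardless
of where the iteration stalled. Model building screens features by the
dual rule (folded Pk > 0.700, strictly, and |R with Ce| > 0.500), prunes
exactly collinear columns (V_diff = 1 − V_mean; P_mean ∝ P_total at fixed
bin count), and — in the umbrella pipeline — drops a named separating
predictor and refits rather than aborting, since near-deterministic
synthetic features can separate small cohorts.

Diagnostics: overall LR χ² against the intercept-only model; Nagelkerke
R² = R²_CS / (1 − exp(2 LL₀/n)) with R²_CS = 1 − exp(2(LL₀ − LL₁)/n);
in-sample accuracy with probability ties broken toward deeper sedation;
per-predictor LR tests (df = classes present − 1 for a single column, 5 for
the full six-level scale). The published unresponsiveness logit is treated
exactly as printed — a binary logit for P(aRASS = −5) with 8 fixed
coefficients shipped in `data/published_logit.json` — and only evaluated;
how it relates to the six-level multinomial fit is not stated in its
source, and its frequency-feature units are passed through as-is.

## Endpoint detection

Component presence on an averaged sweep is automatic (no expert marking):
the window's peak |amplitude| must exceed mean + k·SD of the 0–9 ms
pre-reflex baseline of the same average, k = 6 by default. The calibration
is extreme-value arithmetic: the expected peak of 1750 white-noise samples
(the T2 window) is ≈ 4 SD, so small k would flag noise constantly, while a
burst worth a few noise SDs per sweep still clears 6 SD easily after
4-sweep averaging halves the noise. A zero-variance (noise-free) baseline
falls back to an absolute floor just above the baseline's own peak.
Presence is evaluated on the *raw* average: global detrending redistributes
a sliver of the R1 burst's mean/slope across the whole record, which
otherwise masquerades as late R2 energy.

Two conventions handle the 6-s interval censoring. First, when the average
following the last present one is absent, only the oldest constituent of
that last present average can still carry the component, so the last-seen
*stimulus* is that constituent; "absent" is confirmed by a run of 4
consecutive absent averages, which makes isolated late false positives
harmless (one noise peak persists in at most 4 overlapping averages).
Second, the component actually vanished between the last-seen stimulus and
the next one, so the reported endpoint time/Ce is the midpoint of that
bracketing pair — mean-unbiased when Ce rises locally linearly, and never
more than half an inter-stimulus increment past the true threshold. LORP is
likewise the midpoint between the last responsive record and the first −5
record. The raw last-seen values stay on the record for inspection. Under
the default noise floor the detected abolition Ce is biased low (a fading
burst drops below detectability before it is gone); noise-free sessions
recover the generating thresholds to within one inter-stimulus increment,
which is what the calibration checks assert.

Cohort summaries report mean ± SD for endpoint times and concentrations,
median [min, max] for aRASS, the mean within-patient Ce gap LORP − LOR1,
and paired comparisons (Ce at LORP vs LOR1; the three endpoint times
pairwise) choosing paired t vs Wilcoxon signed-rank by a KS normality
pre-test on the differences; zero-variance comparisons are flagged as
degenerate rather than crashed.

## Reproducibility and I/O

Every run derives all randomness from a master seed; patient i uses the
stream seeded by (seed, i), so extending a cohort never changes earlier
patients. Pipeline artifacts are UTF-8 comma-delimited text with a stamp
line (seed + configuration hash); floats are written as %.17g and parsed in
round-trip mode, so a rerun is byte-identical. Delimited text is the sole
interchange format; sweeps travel in long format (sweep_id, sample_idx,
amplitude_uv, plus stimulus metadata).

## Problem sizes used in the checks

The calibrated-cohort checks simulate 1000 patients with noise-free sweeps
(detection then measures the thresholds, not the noise floor) — about 15 s;
the ordering robustness check runs 200 default-noise sessions; parameter
recovery for the multinomial fit uses n = 5000 with six classes, and the
consistency sweep n ∈ {500, 2000, 8000} with six replicates each. These
sizes give sampling error comfortably below the asserted tolerances.

## Known limitations

- The synthetic noise is stationary and Gaussian; real EMG baselines are
  neither, and the k·SD presence criterion would need re-calibration on
  real recordings.
- The fade law is linear in Ce by design; real amplitude–concentration
  relations are sigmoidal, so detected-vs-true threshold bias under noise
  will differ in shape on real data.
- Pk pooling across patients ignores within-patient correlation; the
  jackknife SE treats observations as exchangeable, which understates
  uncertainty for strongly clustered data.
- The multinomial model is nominal, not ordinal; a proportional-odds model
  would use the aRASS ordering but is out of scope.
- aRASS at the LOR endpoints is read from the sedation record at the
  last-seen stimulus index (records and stimuli share the cadence); expert
  marking of component boundaries is replaced by the automatic criterion
  throughout.
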