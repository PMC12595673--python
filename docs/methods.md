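# Methods

`assrkit` analyses single-channel rodent ECoG along two complementary
axes: spontaneous oscillatory power in canonical frequency bands, and
auditory steady-state responses (ASSRs) — oscillations entrained by
periodic click trains at 10/20/40/80 Hz. On top of the signal metrics it
provides the inferential layer such studies use: within-animal drug
contrasts (ketamine vs saline), male/female group comparisons with
Shapiro–Wilk-routed test selection, and test–retest reliability via the
absolute-agreement intraclass correlation. Because the motivating
recordings are not publicly deposited, the package ships a synthetic
cohort generator with fully known ground truth, and its validation is
property-based: every analysis output is checked against a closed form or
an independent Monte-Carlo oracle.

## Signal model and units

All amplitudes are microvolts; spectral densities are one-sided µV²/Hz.
Epochs span [−1, +1) s around stimulus-train onset at 2 kHz sampling
(1 s trains, 1 s inter-stimulus intervals). Time zero is train onset;
windows are half-open `[t0, t1)` and the sample at exactly t = 0 belongs
to the post-stimulus side. Data are stored as float32 (bundle format) and
analysed in double precision.

## Spontaneous spectra (multitaper)

Power spectral density is estimated on the pre-stimulus window
t ∈ [−0.9, −0.2] s — i.e. 0.2–0.9 s before the next train, keeping a
0.2 s guard on both sides of the preceding train's offset. Each trial
segment is demeaned, tapered with Slepian (DPSS) sequences, and the
eigenspectra are combined with concentration-ratio weights normalised to
unit sum, then averaged over trials. Defaults: half-bandwidth W = 2.9 Hz
on the 0.7 s window (NW ≈ 2, 3 tapers, all concentrations ≥ 0.90). The
calibration is such that the integral of the density over [0, fs/2]
equals the variance of the analysed segments; unit-variance white noise
at fs = 2000 Hz therefore reads 1/(fs/2) = 0.001 µV²/Hz.

Bands: delta 2–4, theta 4–8, alpha 8–12, beta 12–30, low gamma 30–45,
high gamma 55–90 Hz, each half-open `[low, high)`, with the AC/mains band
45–55 Hz excluded from any band average. A variant with high gamma
spanning 45–90 Hz (still minus the AC exclusion) is available, since both
definitions circulate. Band summaries are the *mean* density over the
included bins (not the integral), keeping µV²/Hz units comparable across
bands of different width. A caveat at the resolution limit: the delta
band holds roughly one independent spectral estimate per trial at these
window/taper settings; variance is controlled by trial averaging, and the
wider bands are preferred for precision-sensitive work (this is why the
ICC-recovery validation uses log beta power).

## ASSR metrics (Morlet time–frequency)

Trials are convolved with L2-normalised complex Morlet wavelets
(n_cycles = 7 at all frequencies; integer 1–100 Hz grid by default, or
any subset). Per stimulation rate, metrics are averaged over the analysis
bands 8–12, 18–22, 38–42, 78–82 Hz (grid bins inclusive of the printed
endpoints) and the stimulation window t ∈ [0.2, 0.9] s; the pre-stimulus
baseline window is t ∈ [−0.5, −0.1] s.

* **Phase-locking factor (PLF)**: at each (f, t) bin, the magnitude of
  the across-trial mean unit phase vector; the reported value is the mean
  over band × window bins. Exactly amplitude-invariant. For N trials with
  uniform phases its expectation is the Rayleigh floor √(π/(4N)).
* **Induced power ratio**: per trial, band-mean power in the stimulation
  window over the baseline window; then averaged across trials.
  Phase-blind and scale-invariant. Note an intrinsic property of this
  estimator: because the per-trial baseline is itself noisy, the mean of
  per-trial ratios carries a finite-window Jensen bias (≈ +18% for pure
  noise at the default windows). The bias is condition-independent and so
  cancels in drug contrasts; a `ratio_of_means` variant, which is
  unbiased under stationarity, is provided for sensitivity analyses.
* **Evoked power**: trials are averaged sample-wise first, then
  transformed; the value is band × window mean power of the average (µV²
  under the L2 wavelet normalisation, so scale-dependent through the
  wavelet length). Only the phase-consistent response survives averaging:
  with uniform phases it falls by ~1/N relative to perfect coherence —
  the mechanism that dissociates it from the induced ratio.
* **Harmonic response**: the same PLF/evoked computation on the band
  [2f−2, 2f+2] Hz, for entrainment at the first harmonic of the train
  rate (e.g. 80 Hz during 40 Hz stimulation).

Edge handling: wavelet support is truncated at ±4 Gaussian SDs; bins
closer than 2.5 SDs to an epoch edge are flagged as contaminated and
excluded from window means. At 10 Hz (σ_t ≈ 111 ms) this trims the tail
of the stimulation window; at 40 Hz it is immaterial. Whether published
PLF maps include such bins is generally unknowable from figures alone;
flag-and-exclude is this package's documented choice.

## Reliability: ICC(A,1)

From the two-way ANOVA of an animals × days table (MSR rows, MSC
columns, MSE residual):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

with F = MSR/MSE on (n−1, (n−1)(k−1)) df and the McGraw–Wong
absolute-agreement 95% CI. Estimates map to the conventional bands poor
(< 0.5), moderate (0.5–0.75), good (0.75–0.90), excellent (≥ 0.90); the
joins are upper-open (0.90 → excellent, 0.75 → good), a documented
resolution of the ambiguous printed notation. Negative estimates are
reported as computed, not floored. Missing cells are never imputed:
strict mode raises naming the offending animal/day, lenient mode drops
the animal and reports the count.

## Inference routing

Normality is assessed by Shapiro–Wilk at α = 0.05 — on the differences
for paired designs, per group otherwise. Normal → paired/unpaired t;
otherwise Wilcoxon matched-pairs (zero differences dropped, exact null
for n ≤ 25 without ties) or Mann–Whitney U (exact for combined n ≤ 20
without ties, tie-corrected normal approximation otherwise). All tests
are two-sided; p-values are reported raw, with Holm adjustment available
but off by default. Drug effects are per-animal deltas, value_KET −
value_SAL, so reductions under ketamine are negative. Sex comparisons
first average each animal across its recording days, then compare the
per-animal means between groups.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biophysics of auditory cortex:

* **Background**: spectrally shaped Gaussian noise — deterministic
  amplitude envelope √S(f) with uniform random phases, inverse
  transformed. S(f) is piecewise-constant at per-band target densities
  (defaults at the µV²/Hz scale of awake mouse A1 ECoG: δ 62, θ 54.6,
  α 17.2, β 2.76, Lγ 0.185, Hγ 0.075), 1/f²-decaying above 90 Hz, zero
  outside the 1–1000 Hz passband. The realised epoch variance equals the
  density integral by construction.
* **Entrainment**: an additive sinusoid at the train rate (plus a 2f
  harmonic at 0.3 amplitude fraction), gated to the 1 s train with 10 ms
  raised-cosine ramps, its per-trial phase von Mises with concentration
  κ. The mean resultant length I₁(κ)/I₀(κ) is then the exact
  infinite-trial PLF target. Default κ per rate (0.65/1.1/1.6–1.2/0.72
  at 10/20/40/80 Hz; the 40 Hz values are sex-split, males higher) and
  amplitudes calibrated once against the analysis chain so baseline
  induced ratios land at the published scale (≈1.5 at 20 Hz, ≈2.4/2.0
  male/female at 40 Hz, ≈2.2 at 80 Hz). A known limitation: an additive
  oscillation cannot produce phase locking without adding power, so the
  reported combination of substantial 10 Hz PLF with an induced ratio
  near 1 (phase reset of ongoing alpha) is not reproducible; the 10 Hz
  default favours a moderate induced ratio (≈1.5) and correspondingly
  modest PLF.
* **Hierarchy**: animal, day, and session effects are Gaussian on the
  log of band densities and entrainment amplitude (defaults σ_animal
  0.45, σ_day 0.05, σ_resid 0.14), so the intended ICC of any log-scale
  session metric is exactly σ_a²/(σ_a²+σ_d²+σ_r²) = 0.90, matching the
  good-to-excellent reliability such recordings show. Day effects are
  shared across animals (true column effects, penalised by absolute
  agreement). These σ values are calibration choices, not measured
  facts — the source study publishes no variance decomposition.
* **Ketamine**: phenomenological multipliers on band densities
  (δ 0.64, θ 0.70, α 0.61, β 0.72, Lγ 1.57, Hγ 1.87 — the ratios of the
  published saline/ketamine band tables) and on 40 Hz entrainment
  (amplitude ×0.61, κ ×0.7). No pharmacokinetics, no circuit model.
* **Mains**: an additive 50 Hz sinusoid (2 µV) followed by the recording
  notch (Q = 35), so the AC-band exclusion is exercised; optional.
* **Reproducibility**: every session derives its RNG stream from
  (seed, animal, day, rate, condition); identical spec + seed gives
  bit-identical data, and any session can be regenerated in isolation.
  The realised parameters (multipliers, κ, per-trial phases) are
  serialized as a ground-truth JSON next to the dataset.

What passing the validations does and does not show: the generator
realises exactly the model the metrics assume (additive entrained
sinusoid, stationary 1/f-ish background, log-normal hierarchy), so the
checks verify the *analysis chain*, not robustness to real-data
pathologies (movement artifacts, non-stationarity, electrode drift,
phase-reset entrainment, estrus-linked structure beyond generic day
variance).

## Validation problem sizes and decisions

All validations run at desk scale on one CPU (`assrkit self-check
--full`, `scripts/acceptance.py`, and the acceptance test suite):

* PLF–κ link: 1000 trials per κ ∈ {0.5, 1, 2, 4, 8} at high entrainment
  SNR; tolerance 0.03 (the Monte-Carlo SD of a 1000-trial resultant is
  ≈ 0.02 at low κ).
* Rayleigh floor: 500 replicates of 100 uniform-phase trials; ±0.01.
* Spectral calibration: 200 white-noise trials; 10%.
* ICC: the 4×2 hand-ANOVA matrix to 1e-10; 50 random matrices against an
  independent reference implementation to 1e-6; recovery of variance
  ratios {0.5, 0.75, 0.9} from full simulated cohorts (30 animals ×
  5 days, 20 seeds each) within ±0.08 using log beta power — beta is
  wide enough that estimation noise attenuates the recovered ICC by only
  ≈ 0.03 at 32 trials/session.
* Type-I error: 1000 routed comparisons of exchangeable normal samples
  (n = 30/30), rejection rate required in [3.5%, 6.5%] at α = 0.05.
* Induced/evoked dissociation: κ 0 vs 8 at equal amplitude, 100 trials,
  20 replicates; induced equal within Monte-Carlo error, evoked drop
  within a factor 2 of N.
* Qualitative pattern recovery: 100 cohorts of 10 animals/sex, 24
  trials/session; baseline = 2 days × 4 rates with the 40 Hz sex effect
  configured (κ 4 vs 2, amplitude ratio 1.6); drug = saline + ketamine
  40 Hz sessions from sex-equal baselines with sex-equal multiplicative
  effects. Required in ≥ 95/100 seeds: a significant male > female 40 Hz
  PLF difference with male-directed induced/evoked; the 40 Hz PLF effect
  size exceeding every other rate's, with no other-rate metric crossing
  a stringent screen; all twelve spontaneous-band delta signs correct;
  all six 40 Hz ASSR reductions present; and no delta crossing the
  stringent sex-difference screen.

Two design points in the pattern run deserve explanation. First,
"no difference" components are screened at a family-wise 1% level
(Bonferroni over the 18 null comparisons) rather than per-test p > 0.05:
eighteen independent null tests would spuriously "find" a difference in
about 60% of seeds at the 5% level, making a per-seed all-clear criterion
unattainable by construction under its own null. Second, group-level
delta signs are assessed by the *median* per-animal delta: animal effects
are log-normal, so the raw-scale mean delta is dominated by the largest
animals and flips sign in a few percent of seeds from session noise
alone; the median respects the multiplicative size structure. The drug
cohort starts from sex-equal saline baselines because multiplicative
suppression of sex-different baselines would itself create sex-different
absolute deltas — exactly the confound the delta-equality component must
exclude. All cohort parameters and thresholds were fixed from this power
analysis, not adjusted to test outcomes.

## Numerical and degenerate-input choices

* Epoching collects all boundary violations and reports the offending
  onsets together; events mixing train rates are rejected.
* A constant ratings matrix, zero-variance paired differences, a trial
  with zero baseline power, and an all-excluded band each raise a typed
  error naming the offender; nothing is silently imputed.
* PLF bins with zero coefficient magnitude contribute zero unit vectors.
* EDF storage quantizes to 16 bits over a symmetric physical range;
  bundles round-trip exactly at float32.
* The 2f harmonic band must sit below the analysis ceiling (100 Hz
  default), so 80 Hz trains have no in-range first harmonic.

## Limitations

* Single-channel only; no montage, source, or connectivity analysis.
* Drug conditions are categorical labels; no dose–response or kinetics.
* The generator's effects are phenomenological multipliers; estrus-cycle
  biology appears only as generic day-level variance.
* The additive entrainment model ties phase locking to added power (see
  above); induced ratios below 1 with nonzero PLF are outside its range.
* Day-5-vs-day-1 contrasts are the only longitudinal analysis; no
  mixed-effects trajectory modelling.
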