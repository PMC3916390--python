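# Methods

This note documents the generative model behind `erpoverlap.synthetic_data`,
the numerical choices made throughout the pipeline, and what the test suite
does and does not establish.

## 1. The simulated experiment

Each trial presents a prime word for 200 ms and a target word 500 ms after
prime onset (SOA 0.5 s). Subjects judge the pair related/unrelated by button
press. In the **speeded** condition they respond as fast as possible with a
1 s deadline; in the **delayed** condition a colour cue 1 s after target onset
triggers the response. Target onsets are spaced 3.2 s apart with a 2 s
lead-in, so the −0.1..1.5 s analysis epochs of neighbouring trials never
overlap.

### Behaviour

Per subject, with association strength AS ∈ {0..100}:

| parameter | default | meaning |
| --- | --- | --- |
| `rt_intercept` | 0.67 s (between-subject sd 0.04) | speeded RT at log AS = 0 |
| `rt_logas_slope` | −0.042 s (sd 0.007) | RT change per unit log AS |
| `rt_noise_sd` | 0.125 s (sd 0.01) | trial-to-trial RT noise |
| `bias_slope`, `bias_midpoint` | 0.7, −1.3 | logistic P(related) in latent log-association |
| `zero_as_latent` | −2.8 | latent log-association assigned to AS = 0 pairs |
| `miss_rate` | 0.03 speeded / 0.006 delayed | no-response probability |

Speeded RT = intercept + slope·log(max(AS,1)) + noise, clipped to
[0.15 s, deadline]. Delayed RT ~ N(1.26 s, 0.131 s) from target onset,
independent of AS, confined to the post-cue window.

The RT parameters are calibrated so that 8 equal AS-sorted bins span
bin-mean RTs of ≈0.49 s (strongest associates) to ≈0.67 s (unrelated pairs).
The response model is calibrated to related-response ratios of ≈0.98 (top
bin) falling to ≈0.26 (unrelated bin). A logistic purely in log(max(AS,1))
cannot produce the sharp drop between the AS≈1 bin (ratio ≈0.75) and the AS=0
bin (≈0.26), because log 1 = 0 places them adjacently on the predictor scale.
The generator therefore assigns AS=0 pairs — random word pairings absent from
the association norms — a *latent* log-association of −2.8, well below AS=1
pairs: being entirely unassociated is qualitatively different from being
weakly associated. This is a deliberate design choice of the generator, not a
fitted quantity.

### EEG components

The recording is a sum of smooth fixed-topography components on a 32-channel
extended 10-20 montage (plus an EOG channel), in microvolts:

| component | waveform | latency | peak amplitude (at topography max) |
| --- | --- | --- | --- |
| P2 (prime and target) | Gaussian, σ = 50 ms | onset + 250 ms | +4 / +5, fronto-central |
| N400 | Gaussian, σ = 80 ms | target + 400 ms | −4 + 0.7·log(max(AS,1)), centro-parietal (Pz max) |
| P3 (speeded only) | Gaussian, σ = 120 ms | RT + N(0, 50 ms) | +8, posterior, slightly left |
| NS (negative slope) | linear ramp over 300 ms | ending at the button press | −2, central-frontal |
| MP (motor potential) | biphasic (Gaussian derivative), σ = 50 ms | button press | 3, left-posterior(+)/central-frontal(−) dipole |
| cue P2 (delayed only) | Gaussian, σ = 60 ms | cue + 300 ms | +5, anterior-right |

The N400 amplitude rule makes low-AS pairs more negative; at Pz the injected
contrast between AS ≤ 1 and AS ≥ 18 trials is ≈ −2.5 µV before filtering.
The P3-latency/RT coupling uses additive Gaussian jitter (sd 50 ms): latency
and RT are strongly correlated but not equal. No decision-locked P3 is
injected in the delayed condition by default; components can be freely
re-specified per `ComponentSpec`.

### Noise and artifacts

* **1/f background**: spectrally shaped Gaussian noise with exponent 1,
  scaled to 13.5 µV broadband RMS per channel — a typical resting-EEG
  magnitude; channels are independent (real EEG noise is spatially
  correlated, see Limitations).
* **Alpha**: 8–12 Hz narrowband noise, 3 µV RMS at Oz, posterior-weighted.
* **Ocular artifacts**: Gaussian blinks (~150 µV, sd 60 ms) at quasi-Poisson
  times (0.15 /s, 0.5 s refractory) on the EOG channel, leaked into EEG
  channels with front-to-back decaying gains (0.35 at Fp down to 0.01
  occipitally).

The raw simulation rate is 512 Hz (configurable up; kept low so the
0.1–50 Hz filter + 256 Hz resampling stage is exercised at test-friendly
cost).

Ground truth (true P3 latency, true N400 amplitude, response onset) is
recorded for every trial. Component placement and noise draw from separate
seeded substreams, so re-simulating with noise disabled reproduces the
identical clean component sum — the pipeline's injected-waveform reference.

## 2. Preprocessing

Fixed chain, each stage logged in the container history: 0.1–50 Hz
band-pass → resample to 256 Hz → EOG regression → 0.5–15 Hz band-pass →
stimulus-locked epochs (−0.1..1.5 s) → baseline (−0.1..0 s) → no-response
rejection.

Numerical choices:

* Both offline band-passes are 3rd-order Butterworth applied forward and
  backward (zero net phase, squared magnitude response), with reflect padding
  of 3 × sfreq/low_hz samples.
* Resampling is polyphase; event indices are remapped by the rate ratio with
  round-half-away-from-zero, so an event at raw sample 1024 (512 Hz) lands
  exactly on sample 512 (256 Hz).
* EOG regression estimates OLS leakage coefficients of each EEG channel on
  the demeaned EOG over the whole recording and subtracts the fit. Channel
  means (DC) are deliberately preserved — the 0.5–15 Hz filter removes them.
* Epoch and baseline windows are half-open in sample space; t = 0 is the
  sample at/after the lock event.
* "Too late" responses are the generator's concern (RTs are clipped to the
  deadline; misses are flagged); the pipeline honours only the `missed` flag.

## 3. Single-trial P3 latency (iterative template matching)

Defaults: Pz; 0.5–6 Hz 3rd-order zero-phase Butterworth pre-filter; ±0.5 s
template; search window 0.35–0.9 s post-stimulus; 4 iterations; score =
Pearson correlation between the template and the signal segment centred on
the candidate sample.

* **Edge handling**: where the template support exceeds the epoch, the
  correlation uses the overlapping support only (re-centred and
  renormalised); in raw dot-product mode the dot is rescaled by the overlap
  fraction.
* **Peak picking**: local maxima are derivative sign changes (rising then
  non-rising); the largest *positive* one wins; ties break to the earliest
  sample; window endpoints are never peaks.
* **Fallback**: a trial with no positive local maximum keeps its previous
  estimate and is flagged; flagged trials still enter the next template, so
  the template is always an average over all trials.
* **Template re-use** (delayed condition): a supplied template drives the
  first matching pass; the remaining iterations rebuild it from the data.
  Without usable inits, fallback trials in that first pass sit at the window
  midpoint.

Two structural properties worth knowing:

* **Translation invariance.** The loop estimates latency relative to its
  seeding: if every initial estimate is offset by a constant, that offset is
  a fixed point. RT-seeding works because the latency–RT jitter is zero-mean.
* **Sensitivity to overlapping graded components.** The score landscape is
  shaped by *everything* in the window. With the default AS-graded N400 and
  no P3 at all (delayed condition), estimated "P3 latencies" correlate with
  AS (measured r ≈ −0.2) purely through the N400's influence on the
  correlation profile. A flat-N400 world is the true null for the estimator.
  This is the contamination problem itself, seen from inside the estimator.

### Accuracy vs noise (measured)

With the default 1/f noise model, 200+ trials and RT-coupled inits
(latencies uniform 0.4–0.8 s):

| condition | r(est, true) | MAE |
| --- | --- | --- |
| noise off (grid latencies) | 1.0 | ≤ 1 sample |
| P3 amplitude = 2× in-band (0.5–6 Hz) noise RMS | ≈ 0.80 | ≈ 50 ms |
| P3 amplitude = 1× in-band noise RMS | ≈ 0.45 | ≈ 100 ms |
| ideal clean-template matched filter, 1× | ≈ 0.36 | ≈ 115 ms |

At unit in-band SNR the limit is physical, not algorithmic: an ideal matched
filter given the true template does no better, because 1/f noise concentrates
its power exactly in the band the P3 occupies. Spectrally flat in-band noise
at the same RMS roughly doubles accuracy (r ≈ 0.7–0.8). Single-trial latency
estimates at realistic SNR should be treated as noisy covariates — they
remain useful for group construction and regression, where errors average
out, not as per-trial measurements.

## 4. Trial matching

* Scoring function: L1, `score = |rt − rt_target| + |p3 − p3_target|`,
  both targets 0.65 s by default (late enough that a P3 centred there no
  longer overlaps the 400–500 ms N400 window); weights configurable.
* Competition groups: AS ≤ 1 & latency ≤ 0.5 s vs AS ≥ 18 & latency ≥ 0.6 s
  (thresholds configurable), restricted upfront to subject/pair combinations
  present in both conditions, sizes equalised by seeded random discard;
  delayed mirrors share the subject/pair identities exactly.
* Fixed-latency groups: per subject, the 75 lowest-scoring low-AS trials,
  each greedily matched (ascending anchor score, without replacement, ties to
  the lower trial id) to the high-AS trial minimising the score against the
  anchor's own RT and latency. Without-replacement matching is what makes two
  groups of 10 × 75 = 750 *distinct* trials possible.

## 5. Mixed-effects statistics

All models share one random structure: correlated by-subject intercept and
slope for the single fixed effect, and by-word-pair intercepts; estimation is
REML. Group contrasts enter as a ±1 coding vector. Log-AS models exclude
AS = 0 trials (log 0 undefined; the AS = 0 block carries no graded
association information).

The solver profiles out the residual variance and optimises the four relative
covariance parameters (subject 2×2 Cholesky, pair sd) by Nelder–Mead from
four starts (both signs of the intercept–slope correlation) with a BFGS
polish; all linear algebra runs through a Schur complement on the diagonal
word-pair block of I + UᵀU, so a 10 × 800 fit takes well under a second.
It reproduces `statsmodels` MixedLM to ~1e-6 where that converges, and attains
an equal-or-higher REML criterion value on every dataset tried. p-values use a
t approximation with n − 2 degrees of freedom in place of MCMC; with the
trial counts in play here (thousands) the approximation is immaterial, and
the method string in every result records it.

Small-sample caveat: with 10 subjects the subject-slope variance component
occasionally collapses to the boundary, which narrows the fixed-effect CI
below the level needed to cover the *population* slope (it still covers the
realized mean slope of the simulated subjects). This is inherent to REML
variance components at small group counts, not specific to this solver.

## 6. What the synthetic world does and does not establish

The generator emulates: the stimulus-list composition, RT and response-ratio
gradients in log AS, deadline misses, a P3 latency-coupled to RT, graded
N400, motor potentials, a cue-evoked P2, 1/f + alpha noise, and blink leakage
with known gains. A green test on this world shows the pipeline measures what
was injected — including the headline sign reversal: the low-vs-high AS
contrast at Pz (400–500 ms) is *positive* in the speeded condition (the
P3-latency effect wins) and *negative* for the same subject/pair combinations
in the delayed condition, and fixed-latency matching recovers ≈96% of the
injected N400 contrast.

It does **not** establish robustness to: spatially correlated noise, non-
stationary alpha, component topography variability across subjects, latency
variability of stimulus-locked components, RT distributions with lapses/fast
guesses, or real ocular dynamics (saccades, slow drifts). Real-EEG import is
out of scope by design.

## 7. Reproducibility

Every random draw descends from one global seed through named per-stage
substreams (`pipeline.stage_seed`). A run directory contains a
`manifest.json` with the full configuration echo and SHA1 of every artifact;
identical config + seed reproduces every TSV byte-for-byte.
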