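# Methods

`hypersync` implements the full analysis chain for triadic fNIRS
hyperscanning in a multi-speaker ("cocktail-party") conversation — one
listener attending to one of two simultaneously talking speakers — together
with a synthetic-data generator whose ground truth makes every stage
verifiable. This note documents the models, the conventions chosen where the
methodology is genuinely open, and the limits of what the synthetic
validation shows.

## The INS-increase statistic

Interpersonal neural synchronization (INS) between two people's
oxy-hemoglobin (HbO) time series is quantified by squared wavelet transform
coherence (WTC),

    R²(s, t) = |S(W_xy / s)|² / ( S(|W_x|² / s) · S(|W_y|² / s) ),

with `W_x` the Morlet (ω₀ = 6) continuous wavelet transform and `S` the
Torrence–Webster smoothing operator. The per-pair statistic is

    Δz = arctanh( ⟨R²⟩_{0.1–0.4 Hz, time} (task) ) −
         arctanh( ⟨R²⟩_{0.1–0.4 Hz, time} (rest) ),

an 11 × 11 matrix per dyad — LA (listener–attended speaker), LU
(listener–unattended), AU (attended–unattended) — per task. The 0.1–0.4 Hz
band excludes cardiac pulsation (~1 Hz) and other fast physiology. Fisher's
arctanh is applied to the band-time-averaged coherence value itself (clipped
at 1 − 10⁻⁶); whether the transform should act on the R or R² scale is not
determinate from the field's descriptions, so the R²-scale convention is
used consistently and the choice only rescales Δz monotonically.

### Wavelet conventions

* ω₀ = 6, 12 voices per octave; default scale ladder 2·dt to n·dt/4.
  Analyses restricted to a band use a grid covering the band plus a
  0.4-octave margin so the scale smoother is unbiased at the band edges.
* Mean removal only before the CWT — no filtering or detrending; WTC is
  amplitude-normalized per window, so slow drifts and spikes mostly cancel.
* FFT convolution with L2-normalized analytic daughters, zero-padded to the
  next power of two.
* Smoothing: Gaussian in time with SD = s at scale s (frequency-domain
  kernel `exp(−(sω)²/2)`, the width used by the Grinsted wavelet-coherence
  package), then a 0.6-octave boxcar over scales. Both passes renormalize by
  the in-window kernel mass, so a constant field is a fixed point and edges
  are attenuation-free (though lower-dof).
* Cone of influence: e-folding time √2·s from either record edge. COI
  points are *included* in band/time averages by default (`exclude_coi`
  flips this); hyperscanning band averages conventionally include them.
* Null bias: smoothed coherence of independent series does not vanish — the
  effective degrees of freedom per smoothing window are finite. Under the
  conventions above the deep-interior null mean is ≈ 0.34 at ordinary
  scales, higher near the record edges (in-COI mean up to ≈ 0.5) and in the
  near-Nyquist octave, where spectral truncation of the analytic wavelet
  lengthens its time envelope. The bias is common to task and rest and
  cancels in expectation in Δz; tests bound it empirically rather than
  assuming a smaller nominal figure.

### Performance conventions

Study-scale pipelines (121 pairs × 2 dyads × 2 sessions × 21 groups) accept
two throughput options, validated against the exact path in the tests:
single-precision coefficients, and block-averaging of the (auto/cross)
spectra in time by a factor of 5 before smoothing — legitimate because the
narrowest smoothing kernel at in-band scales (SD ≈ 18 samples) is much wider
than a block. Together they change Δz by < 10⁻³, two orders below its
sampling noise.

## Synthetic study design

The generator reproduces the study geometry: 21 groups × 3 subjects
(listener, two speakers, one randomly attended) × 11 channels at 10 Hz;
280 s rest and task sessions (already trimmed; `trim_session` implements the
40 s/40 s task trim and centered rest trim for raw-length inputs). Signal
model per channel:

* neural background: unit-variance, zero-phase 4th-order Butterworth
  band-passed (0.1–0.4 Hz) Gaussian noise;
* coupling: channels named in a coupling share a band-limited latent,
  `x = a(t)·latent(t − lag) + √(1 − a(t)²)·private`, with `a(t) = √strength`
  so the band-passed correlation of the pair equals the strength (measured
  0.72–0.76 at strength 0.8 after noise dilution). Rest sessions carry no
  coupling.
* physiological noise: 1/f background (amplitude 0.5), cardiac ~1 Hz and
  Mayer ~0.1 Hz sinusoids (amplitude 0.3) with random phases per subject —
  independent across subjects, so physiology cannot create inter-subject
  coherence;
* pre-response boost: the coupling gain is multiplied by
  `1 + amplitude·K(t)`, K a Gaussian kernel (SD `width_s`) centered
  `lead_s` before each verbal response. The measured signal expresses the
  kernel `hemo_delay_s` (6 s) later — the fNIRS delay-to-peak — which the
  1 Hz time-course analysis then removes, recovering the kernel at its
  neural time;
* events: verbal/non-verbal responses as a 1 Hz point process with a hard
  21 s minimum spacing (epochs of ±10 s never overlap) and a 12 s edge
  margin; the listener speaks 5–9 s from each verbal onset (~10% of
  frames);
* speech envelopes: nonnegative 10 Hz series `clip(1 + 0.5·m, 0)` where `m`
  mixes a 0.6–1.0 Hz shared component into the envelope, the speaker's own
  IFC-like channel, and (for the attended speaker only) the listener's
  sensorimotor/auditory channels. The brain's envelope-band component is
  present in *both* sessions at equal variance — only its shared fraction is
  task-specific — so the rest-control comparison is spectrally unconfounded;
* quality scores: `clip(1 + 4·LA-strength + N(0, 0.3), 1, 5)`, averaging the
  listener's and attended speaker's five-point ratings in spirit.

Randomness is split per (group, purpose, subject, channel) with
counter-based `SeedSequence` spawn keys: any series is reproducible
independently of generation order.

What the generator does *not* emulate: hemodynamic response convolution
(couplings act directly on band-limited signals), motion artifacts, optode
coupling loss, non-stationary speech statistics, and any real anatomical
channel structure. Passing recovery tests therefore demonstrates the
*pipeline's* correctness and calibration, not that real recordings would
show these effects.

## Scenario designs used in validation

Fixed once, as study designs (seeds are the only variable input):

* **Contrast recovery** — LA-only coupling 0.8 at pair (3,3); the
  BH-corrected paired LA-vs-LU map over all 121 pairs must flag exactly
  that pair, and nothing on null studies.
* **Permutation** — role-preserving reassignment of all participants into
  new triads, excluding any pseudo triad that re-unites a listener with a
  speaker of their original group (such pairs would carry true coupling);
  each speaker keeps their original attended/unattended label. Group-mean
  Δz at (3,3) per iteration; add-one empirical p. Uniformity of p is
  checked on reduced 8-group null studies (uniformity does not depend on
  the group count), detection on coupled ones, 99–200 iterations.
* **Lag** — coupling with a 2 s listener-lead; the ±10 s lag profile (1 s
  steps, truncation not wrap-around, rest baseline unlagged) must peak at
  1–3 s on the listener-precede side.
* **Event-locked** — base strength 0.3 with boost amplitude 2.5, lead 5 s,
  width 2 s. Expected: group-mean epoch curve peaking at −5 ± 1 s. The WTC
  time smoothing (SD 2.4–9.7 s at in-band scales) necessarily spreads the
  significant cluster over roughly ±4–5 s around the peak, so the cluster
  is pre-response but wider than the kernel itself; "significant" means a
  significant *increase* (positive t) — a strong boost slightly elevates
  the no-response baseline, making far-from-event offsets sit consistently
  *below* it.
* **Quality link** — per-group LA strength ~ U(0.1, 0.6) drives quality;
  boost amplitude 0.9, width 3 s, 1.7 verbal responses/min. The per-offset
  correlation uses baseline-subtracted curves (the pre-response INS increase
  relative to the group's no-response index), which removes group-level
  nuisance variance shared across offsets; Šídák family = the 10
  pre-response offsets.
* **Speech dissociation** — envelope coupling 0.8; speaker-channel
  coherence vs the rest-control must be significant (p < 0.0005, the
  reporting convention for this comparison) at scales around 0.7–0.8 Hz and
  nowhere under the null, while toggling the envelope coupling changes the
  0.1–0.4 Hz Δz at (3,3) by < 0.02 (by stream design, not at all). The
  speech grid spans 0.8 Hz down to the quarter-record period (~0.014 Hz for
  280 s); slower scales carry no usable coherence.
* **Decoder** — FLDA with shrinkage toward the diagonal of the pooled
  covariance (λ = 0.5 default; p = 121 ≫ n = 42 makes the pooled matrix
  singular), midpoint threshold, leave-one-row-out by default
  (leave-group-out available). At the validation conditions (one feature
  shifted 0.5 vs noise SD 0.15) the measured mean LOOCV accuracy is ~0.84.

## Statistics

All tests two-tailed. The 2×2×2 repeated-measures ANOVA computes each 1-df
effect as a ±1 within-group contrast, so F = (paired t)² with df (1, n−1) —
an exact identity, tested to 10⁻¹⁰. LA-vs-LU channel maps default to paired
tests across groups (matching df = n−1 designs with 21 groups; an unpaired
mode exists). BH-FDR families are the 121 combinations of one map, the 21
offsets of one epoch curve, or the 21 lags of one profile; quality
correlations use Šídák over the offsets tested. The ANCOVA is a
difference-score regression on mean-centered covariates, testing the
intercept with F(1, n−1−k); with no covariates it reduces exactly to the
paired t². Permutation p-values use the add-one convention.

## Numerical choices and degenerate inputs

R² is clipped to [0, 1] and to 1 − 10⁻⁶ before arctanh; all-zero series and
empty time masks raise instead of returning NaN; event categories with no
events yield empty stacks (a warning-level condition, not an error); epochs
crossing a record edge or the NaN tail left by the delay adjustment are
dropped and logged. TSV floats carry 6 significant digits, making text round
trips bit-exact after the first write.

## Known limitations

* The coherence null bias is scale- and edge-dependent; Δz inherits a small
  variance penalty near the cone of influence that the tests bound but do
  not remove.
* Near-Nyquist scales (periods < ~0.5 s) have systematically longer wavelet
  time envelopes than the analytic formula assumes; the analysis bands never
  include them.
* The event-cluster width is smoothing-limited (see above): analyses should
  interpret the *peak* location, not the cluster extent.
* Monte-Carlo sizes in the validation suite are desk-scale (typically 2–16
  replicate seeds per scenario at full study size); rates quoted from them
  carry binomial error of order ±10–20 percentage points.
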