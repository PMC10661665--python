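# Methods

This note documents the models, parameters and design choices behind
`stvrepol`: what the estimators compute, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## The STV statistic

`stv()` computes `Σ |D_{n+1} − D_n| / (n_pairs · √2)` over consecutive
usable beat pairs. The brackets are absolute values (a signed sum would
measure drift, not variability, and is deliberately not offered). Missing
determinants (excluded, unmeasurable or flagged beats) break consecutiveness:
pairs spanning a gap are dropped and the denominator uses the retained pair
count. A `strict` mode instead demands exactly `n_beats_stv` (default 31)
consecutive usable values — the protocol reading in which a clean 31-beat
segment is selected rather than a gapped one re-normalized; both modes are
exposed because segment selection conventions differ between labs.

Useful identities, all enforced by tests: constant series → 0; alternating
±1 ms → √2; unit ramp → 1/√2; `stv(D + c) = stv(D)`;
`stv(c·D) = |c|·stv(D)`; for iid Gaussian jitter of sd σ,
`E[STV] = σ√(2/π)` (from `E|X−Y| = 2σ/√π` for iid Gaussians, divided by √2).

## Automatic ARI measurement

Per beat, anchored on the ventricular sense `s` with beat-specific interval
`RR`:

1. analysis window `[s + blanking, s + RR − guard)`; defaults
   `blanking = 200 ms` (QRS exclusion) and `guard = 50 ms`. The window end
   is RR-minus-a-constant rather than RR-proportional: the guard's job is to
   keep the next complex out at any heart rate, and a constant does that
   without shrinking the T-segment at slow rates. The last beat, having no
   successor, uses the record's median RR.
2. first difference of the windowed samples (× fs, mV/s). No smoothing
   kernel by default — the simplest faithful derivative; noise-heavy signals
   should be filtered upstream, as device front-ends do.
3. squaring — all points positive, slope changes emphasized, and the
   measurement exactly invariant under `signal → c·signal`, `c ≠ 0`.
4. running (rectangle-rule) cumulative area, mirroring a device accumulator;
   a trapezoidal mode exists for cross-checks. The ARI offset is the time
   at which the running area reaches `auc_fraction` (default 0.60) of its
   total, linearly interpolated between the bracketing samples to remove
   sampling-rate bias; `interpolate=False` emulates a device that reports
   whole samples. Both interpolation and accumulation conventions are
   config-gated because device internals at this level are not public.

Flags per beat: `window_truncated` (RR too short for a usable window, or
the window leaves the record), `noisy` (zero derivative energy),
`low_t_amplitude` (windowed peak-to-peak < `t_amp_min_mV`, default 0.5 mV —
the beat keeps its value but is marked), `pacing_interference` (a detected
stimulus artefact inside the beat's T-segment, i.e. anywhere between the end
of blanking and the next sense; the artefact's extent, ±5 ms around its
centre, counts). The interference region deliberately ignores the window
guard: an atrial pace spike precedes the next QRS by roughly the guard
width, so testing against the guarded window would make the decision a
coin-flip on sampling phase.

## Fiducial segment averaging

Three alignment stages (R peak, QRS onset, T-wave end), each: iterate over
beats; for each beat build the average of all *other* beats at their current
shifts (leave-one-out template, recomputed every sweep), and pick the
integer-sample shift within `±search_radius` (default 20 ms) maximizing
zero-mean unit-norm cross-correlation. Ties break toward the smallest
absolute shift, then the negative one — this also anchors the global
translation degeneracy of the problem. The sweep repeats until no shift
changes or `max_iters` (default 10); the shift set is finite so termination
is guaranteed.

Window half-widths (R 60 ms, QRS onset 40 ms, T-end 80 ms) are stated
defaults, chosen to contain the respective deflection plus jitter at porcine
heart rates; they are parameters of `FSAConfig`, not claims.

The template landmarks (QRS-onset and T-end offsets relative to R) may come
from ground truth, an annotation file, or an automatic estimate from the
average beat (5 %-of-peak threshold rule). Any template error is shared by
every beat: it biases all QT values equally and cancels exactly in STV.
Integer-sample alignment also leaves each stage a sub-sample global anchor
offset; per-beat errors on noise-free signals stay within one sample period.
Instead of the visual alignment check a manual workflow would use, beats
whose final leave-one-out correlation falls below 0.8 are flagged `noisy`.

## Beat sensing

Sensing is an input to the analysis, not a contribution; the built-in
detector exists so the pipeline runs end to end and can be bypassed with
annotations. Default mode thresholds the rectified derivative of a 5 ms
moving-average-smoothed waveform at `threshold_frac` (0.5) times its 99th
percentile — depolarization slew exceeds T-wave slew by an order of
magnitude, which a pure amplitude threshold cannot exploit (an `amplitude`
mode with a 95th-percentile threshold is kept for signals with small
T-waves). Percentile thresholds make detection invariant under amplitude
scaling and robust to a single artefact spike. Senses are refined to the
local rectified-waveform maximum within 50 ms, with detected pace-spike
samples masked so paced beats are timed on the R peak; a 250 ms refractory
(below the shortest plausible porcine RR here) suppresses double detection.
Caveat: the pace-spike masker uses an absolute 1 mV/ms slope criterion, so
sensing on paced records is scale-invariant only over the physiological
amplitude range.

## Supporting metrics

* **QTc (Bazett):** `QT / √(RR/1000)`, both in ms.
* **ST-deviation:** per beat, mean amplitude over 10 ms starting 60 ms
  after the sense minus the mean over 20 ms ending 80 ms before the sense
  (PR-segment isoelectric reference); the record value is the median over
  beats. The operating points are stated defaults standing in for a
  caliper measurement.
* **EGM channel selection:** channels ordered most-apical first; the first
  pole with T-wave amplitude ≥ 0.5 mV and |ST-deviation| ≤ 0.3 mV wins.
  The tip pole typically fails the ST ceiling (injury current). The 0.3 mV
  ceiling quantifies "free of significant ST-deviation" and is
  configurable.
* **Ectopy exclusion:** each ectopic beat is removed with its predecessor
  and two successors, clipped at the ends; paced beats are additionally
  removed for T-wave-based determinants.
* **Segment quality:** noise RMS from pre-QRS gaps, morphology stability as
  mean correlation of beat windows with their average, ectopy fraction, and
  a pacing-present flag; a segment is measurable for T-wave metrics when
  stability ≥ 0.9, ectopy ≤ 10 % and no pacing — the automated counterpart
  of selecting segments "free of noise, with stable morphology and little
  ectopy".

## Agreement analysis

Spearman's rho is the Pearson correlation of mid-ranks (ties averaged; none
expected for continuous STV), with an exact permutation p-value for n ≤ 9
and the t approximation above. Bland–Altman limits are
`bias ± 1.96·sd(differences)` with the n−1 sd, hence exactly symmetric:
`loa_low + loa_high = 2·bias`. The cross-timepoint report converts both STV
series to percentage change from baseline; by default Spearman runs on the
percentage changes and Bland–Altman on the raw ms values — the pairing that
matches how such results are usually plotted — and both choices are
flag-controlled because the alternative pairing is equally defensible.

## Synthetic generator

The generator emulates the *signal statistics* relevant to beat-to-beat
repolarization analysis, not torso or membrane biophysics: no 12-lead
projection, respiration, or ischaemia electrophysiology. Beat morphology is
a piecewise analytic template with closed-form landmarks, so every
estimator has an exact oracle:

* QRS: difference of two Gaussians (dominant lobe σ = 7 ms at the R peak,
  smaller opposite lobe 14 ms later) — biphasic, smooth, differentiable.
* T-wave: asymmetric raised cosine (55 % rise / 45 % fall of `t_width`,
  default 160 ms) with compact support. The exported T-end is the
  1 %-of-peak point of the falling lobe — unambiguous and
  resolution-independent — and the template is placed backward from the
  programmed repolarization interval so truth is exact by construction.
* ST segment: cosine-tapered plateau of height `st_deviation` between QRS
  end and T foot.
* Ectopic beats: twice-widened QRS, inverted T, coupling interval
  `0.6·rr_mean` — visually and spectrally distinct so quality gates can be
  exercised.
* Pace spikes: 1 ms-σ Gaussian of twice the QRS amplitude, 20 ms before
  QRS onset; pacing raises the rate by `rate_offset_bpm` (default +20/min)
  above the sinus rate.

Per-beat repolarization intervals follow
`mean + trend·k + alternans·(−1)^k + N(0, jitter_sd)`; RR intervals are
Gaussian around `rr_mean`. A drawn RR that cannot contain its beat's
repolarization interval raises a generation error naming the beat. One
seeded generator per call; identical configurations are bit-identical.

Default conditions mirror the study setting: ECG-style records at 1200 Hz
(lead V2), EGM-style at 1000 Hz (poles I1–I3, the tip pole carrying a
0.8 mV injury-current ST offset), `rr_mean = 750 ms` and
`repol_mean = 400 ms` (inside the reported porcine ranges), T amplitude
0.8 mV (above the 0.5 mV measurability gate), 31-beat STV windows. The demo
scenarios ramp `repol_jitter_sd` 1 → 2 → 3 → 4 ms across baseline,
occlusion, 1 min before VT/VF and just before VT/VF, with ST-deviation
climbing 0 → 0.15 mV; all timepoints and both modalities share one base
seed, so the jitter is a common standardized sequence scaled by each
timepoint's σ — the programmed STV then increases strictly with the ramp
and the two modalities see the same latent variability, which is what the
agreement analysis assumes. Demo noise floors are 5 µV (ECG) and 1 µV
(EGM): intracardiac signals are recorded close to the source and
device-filtered, and the unsmoothed squared-derivative accumulates noise
energy across the whole window, so the raw-derivative ARI assumes a clean
EGM. What passing tests show, therefore, is correctness of the estimators
under the generator's assumptions (template morphology, stationary noise,
exact truth); they do not certify performance on real recordings with
baseline wander, morphology drift or non-Gaussian noise.

## Numerical conventions

All times are ms from record start, sample indices 0-based, windows
half-open `[start, end)`. The 60 %-area crossing interpolates linearly
between samples; exact ties in the alignment score resolve to the smallest
absolute, then negative, shift; `searchsorted` semantics make the area
crossing the *earliest* qualifying sample. Degenerate inputs (flat
channels, zero-energy windows, too-short RR, fewer than 3 beats) yield
empty results or typed errors, never silent NaNs.

## Problem sizes

Statistical checks use 2000 simulated 31-beat series (direct Gaussian
recovery), 40 synthetic electrogram records through the full measurement
chain, 100 random smooth windows against a 100 kHz integration oracle, and
10,000 randomized ectopic placements — sizes at which the Monte-Carlo
standard errors are several times smaller than the assertion tolerances.

## Known limitations

* Integer-sample alignment bounds FSA precision at half a sample period per
  fiducial; sub-sample interpolation is future work.
* The ARI derivative is unsmoothed by default; on noisy electrograms the
  60 %-area point destabilizes (see generator discussion above).
* The automatic template-landmark estimate can sit a few ms off the true
  T-end; the offset is common-mode and harmless for STV but makes absolute
  QT values template-dependent.
* No U-wave handling, no tangent-method T-end, no arrhythmia
  classification; waveform I/O is CSV-based.
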