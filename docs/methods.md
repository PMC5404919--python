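# Methods

## Sharp-wave-ripple detection

The detector operates on a single-channel voltage trace (µV) sampled
uniformly, nominally at 10 kHz.

1. **Ripple band.** The raw trace is band-pass filtered 150–250 Hz with a
   4th-order Butterworth applied forward–backward (zero phase). The filter
   family and order are our choice — phase preservation matters because
   event boundaries are read off time-aligned wavelet power.
2. **Detection signal.** A centred 5 ms sliding RMS of the band-passed
   trace (window shrinks at the recording edges). 5 ms sits between one
   ripple cycle (4–6.7 ms) and the shortest acceptable event (10 ms).
3. **Background.** Mean and SD of the RMS signal over the *whole*
   recording. A robust option (median, 1.4826·MAD) is available by flag.
   Note a consequence: strong events inflate the background moments and
   thereby raise the threshold, so false-positive rates fall as true event
   content rises.
4. **Candidates.** Each excursion of the RMS above mean + 4 SD yields one
   candidate at the RMS maximum within the excursion (optionally at the
   maximum of the rectified filtered trace). Candidates closer than 50 ms
   are merged, keeping the larger peak.
5. **Boundaries.** A ±100 ms window of the *unfiltered* trace around the
   candidate is Morlet-transformed (ω₀ = 6, 100–300 Hz in 2 Hz steps).
   Baseline mean/SD are taken from the power at 250 Hz in the window's
   first 50 ms; boundaries are the edges of the supra-threshold run
   (ripple-band mean power > baseline mean + 2 SD) containing the window
   centre. No run near the centre ⇒ the candidate is dropped. Which power
   trace carries the crossings (band mean, the 250 Hz row, or the peak
   frequency row) is genuinely ambiguous; band mean is the default because
   it is the most stable, and the alternative readings are config options.
6. **Measurement.** Peak frequency = argmax over frequency of the
   time-averaged wavelet power inside the boundaries (lowest frequency on
   ties); amplitude = peak-to-trough of the band-passed trace inside the
   boundaries; mean RMS = boundary-average of (RMS − background mean)/SD;
   duration = boundary span.
7. **Rejection.** Events with duration < 10 ms or mean RMS < 1.5 SD are
   flagged rejected (kept in the event table with a reason); the summary
   (count, incidence = count/duration, mean frequency/amplitude/duration)
   covers accepted events.

### Known limitations

* **Wavelet temporal smearing.** At ω₀ = 6 and 200 Hz the wavelet's
  temporal width is σ_t ≈ 4.8 ms, and boundary crossings use an absolute
  threshold, so measured durations grow with event signal-to-noise: a
  high-SNR 30 ms ripple measures ~25–40 ms, and a high-SNR 8 ms transient
  measures above 10 ms more often than not. The duration-based rejection
  rule therefore cannot remove *loud* short transients, only quiet ones.
* **Noise floor.** On pure 1/f noise the pipeline accepts roughly 10
  events per minute: an excursion that crosses the 4 SD bar has, by
  selection, high RMS inside its boundaries, so the 1.5 SD rule rarely
  removes it, and wavelet smearing lifts its duration past 10 ms. In
  recordings with real events the inflated background moments suppress
  this floor (measured FDR ≤ 2% on the benchmark traces).
* Peak-frequency estimates on single events scatter by ±10 Hz (the
  wavelet's spectral width is f/ω₀ ≈ 33 Hz); means over tens of events are
  accurate to a few Hz.

### Evaluation against ground truth

Detections match implanted events when centres agree within ±20 ms, greedy
one-to-one in order of time difference. Sensitivity = matched/implanted,
FDR = unmatched detections/detections.

## Gamma spectra and unit/burst tiers

Spectra use the first 400 s of recording (shorter input is an explicit
override), Welch with 2 s Hann segments and 50% overlap (0.5 Hz
resolution). Whitening multiplies power density by frequency — the reading
of "1/f normalisation" that flattens a pink background — and the z-score
uses the mean/SD of the whitened spectrum over 3–300 Hz. The gamma peak is
the z maximum within 20–60 Hz (wide enough for normal ~35 Hz gamma and the
slowed rhythms of pathological tissue); the 20–60 Hz mean z is also
reported since group figures may use either summary.

Unit/burst detection high-passes the trace at 300 Hz and scales thresholds
by the RMS of the result (equal to its SD at zero mean, so counts are
invariant to gain). Local peaks of the rectified trace ≥ 1 ms apart are
units when their height is in [3, 10) RMS and bursts at ≥ 10 RMS; bursts
within 20 ms collapse to the larger one. A raw 3 SD amplitude criterion
fires on ~0.3% of Gaussian noise samples, so unit counts include a noise
floor and are comparative, not absolute.

## Biomarker statistics

ROC curves sweep cutoffs over midpoints between consecutive distinct
values plus ±∞ sentinels; AUC is the trapezoidal area, which equals the
Mann–Whitney U statistic over n₁n₂ with ties counted ½ (tested against the
brute-force oracle to 1e-9). Markers run in either direction (NPTX2 falls
in disease, tau rises); direction "auto" orients the curve so AUC ≥ 0.5
and the orientation is recorded. The Youden cutoff maximises J with ties
broken by higher accuracy then lower cutoff, making output deterministic.
Correlations are Pearson product–moment with pairwise-complete deletion
(each analyte–score pair carries its own n, as in published correlation
tables) and two-sided p from the t transform on n−2 df. Group comparisons
default to Student's pooled-variance t (Welch by flag); when both groups
are constant and different the statistic diverges and (±inf, 0) is
returned explicitly. No multiple-testing correction is applied by default,
matching how such tables are usually reported; a Benjamini–Hochberg column
is opt-in.

## Synthetic data

The LFP generator is a statistical emulator, not a biophysical model. Its
background is Gaussian noise FFT-shaped to 1/f^β (β = 1 default, slope
exact by construction, SD 5 µV — chosen so the default ripple amplitude
sits ~8× above the ripple-band noise RMS, the regime where detection is
reliable). Ripples are Hann-windowed sinusoids (carrier uniform in
180–220 Hz around the ~190–200 Hz peaks seen in slices; duration
26.6 ± 1.4 ms and peak-to-trough amplitude 17.9 ± 2.3 µV, the published
slice statistics) riding a negative Gaussian sharp wave (σ = duration,
12 µV). Event times are homogeneous Poisson (default 0.5 events/s, inside
the published 0.3–1.5 Hz incidence range) with a 200 ms refractory gap so
ground truth never overlaps; an exact-count mode places a fixed number of
events for benchmarks. Gamma is a continuous tone (default benchmark
amplitude 0.3 µV, set so the z-scored peak spans the published range of
group means, ~2–5 at half that amplitude and saturating near √N_bins ≈ 24
for loud tones — a pure tone concentrates power in one bin, unlike real
broadband gamma). Units are 1 ms biphasic spikes at 5× and bursts 5 ms
Hann-windowed 600 Hz packets at 12× the high-passed background RMS; the
600 Hz carrier is what lets a 5 ms packet survive the 300 Hz high-pass.
Because background noise adds ±1 RMS at an event's peak, a 12× burst
occasionally measures below the 10× tier — real threshold classifiers
share this property.

What passing tests on this generator do *not* show: robustness to
movement or line artifacts, non-stationary backgrounds, overlapping
events, multi-channel structure, or the waveform diversity of real SWRs.

The cohort generator draws analytes and cognitive scores from a Gaussian
copula within each diagnostic group (requested Pearson correlations hold
in expectation; ±1 handled by eigendecomposition), then scales to
group-specific means/SDs. NPTX2 means are the published ELISA values
(control 1067, AD 296 pg/ml); the SDs (350/130) give the moderate overlap
typical of CSF markers (AUC ≈ 0.98); the other analytes, score parameters
and regional volumes (control HOC ≈ 0.8, case ≈ 0.6) are synthetic,
literature-typical values. Analytes and volumes clip at zero — the assay
floor — which leaves <1% of mass affected at the defaults; correlation
targets are applied within group because pooling groups with different
means changes the pooled r mechanically.

## Numerical choices

* Morlet CWT is evaluated exactly in the frequency domain (unit-peak
  Gaussian response per analysis frequency, analytic — negative
  frequencies zeroed), L1-normalised so equal-amplitude tones have equal
  power at every frequency; inputs are zero-padded by four wavelet widths
  against circular wrap-around.
* Welch spectra drop the DC bin (meaningless after detrending and unusable
  at f = 0 in log or whitened form).
* Text LFP files are written at %.17g and parsed with round-trip float
  precision; time axes with jitter beyond 1 ppm of the sampling interval
  are rejected rather than resampled.
* All generators take an integer seed; identical (config, seed) gives
  bit-identical traces, ground truth and cohorts.

## Benchmark problem sizes

The recovery benchmark uses 100 s traces with 50 implanted ripples over
ten seeds (500 events); the gamma benchmark 400 s per amplitude; tier
recall 60 s at 1 unit/s and 0.3 bursts/s; ROC oracle checks 200 random
datasets of ≤ 30 per class; cohort checks n = 5000 per group (Fisher-z SE
~0.011 for the r = 0.467 target); null calibration 1000 simulations.
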