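# Methods

This note documents the models and numerical choices behind the
package, in the order the pipeline applies them.

## Calibration and segmentation

ADC counts are mapped to absolute pressure by the linear chain

    p[Pa] = counts / 2^(B-1) * V_fs / (10^((S+G)/20) * 1e6)

with bit depth `B` (16 canonical, 24 accepted), full-scale voltage
`V_fs`, hydrophone sensitivity `S` in dB re V/uPa and gain `G` in dB.
The deployed hydrophones have `S = -174.5`; recorder gain and full-scale
voltage are configuration inputs with defaults 0 dB and 1 V, since the
hardware documentation specifies neither.  With these defaults a
full-scale 16-bit sample corresponds to ~531 Pa.  Segments with any
sample at or above 99 % of full scale are flagged clipped but still
processed.  Streams are cut into consecutive non-overlapping 2-minute
windows; a trailing partial window is dropped rather than zero-padded,
because padding would bias downstream mean-square levels low.

## Third-octave band levels

Band centers follow base-2 ratios (2^(1/3) between neighbours) anchored
at 1 kHz, labelled with the conventional nominal values 16 Hz ... 16 kHz
(31 bands); nominal 31.5 Hz therefore sits on the exact center
31.25 Hz.  Band edges are center x 2^(+-1/6), so adjacent bands tile
the axis exactly.  Per 2-minute file, band power is a Welch averaged
periodogram (Hann window, 1 s segments, 50 % overlap — both exposed in
configuration) integrated between the band edges, and

    SPL = 10 log10(P_band / (1 uPa)^2)   [dB re 1 uPa rms].

A 1 Pa rms tone injected at any exact band center reads back
120.00 +- 0.01 dB, and leakage two bands away is > 40 dB down; these
bounds are enforced in the test suite.  Digital silence yields -inf,
which propagates as a missing value.

Averaging of SPL values (circadian bins, site summaries) happens in the
linear mean-square-pressure domain and is back-transformed to dB.  The
standard deviation is likewise computed linearly (ddof = 1) and
reported as 10 log10(sd / 1 uPa^2); zero spread maps to -inf, a single
value to NaN.  An amplitude-domain (pressure rather than
pressure-squared) mean is available via `domain="amplitude"` because
the convention is ambiguous in parts of the literature; outputs record
which was used.

## Impulse detectors

Both detectors share one pipeline: optional anti-aliased polyphase
decimation, a zero-phase equiripple band-pass, the Teager-Kaiser
operator psi[n] = x[n]^2 - x[n-1] x[n+1], and thresholded peak
counting.

* Fish pulses: decimate to 2 kHz, band-pass 100-800 Hz.
* Shrimp snaps: native rate, band-pass 4-9 kHz (this also excludes
  low-frequency fish pulses and photosynthesis bubble noise).

Filters are order-20 FIR (21 taps) designed with the Parks-McClellan
algorithm, transition bands at 20 % of each edge and a 2:1 stopband
weight: at 21 taps the equal-weight design achieves under 10 dB of
stopband rejection, which defeats the purpose of the band split, while
the weighted design reaches ~13 dB per pass (26 dB after the
forward-backward application) at a passband cost of under 2 dB.  The
achieved attenuation is logged at design time so this modest
selectivity stays visible.  Filtering is forward-backward so event
times are not shifted.

Counting is peak-based: local maxima of the TK energy above the
threshold are merged by a greedy refractory rule — a peak within
`min_gap_s` of the current event's first peak joins that event,
otherwise it opens a new one — and each event is timed at its cluster's
largest peak.  Because peak positions do not depend on the threshold,
the count is provably non-increasing in the threshold (an alternative
excursion-based rule fails this property: raising the threshold can
split one excursion into two).  The refractory gaps default to the
event durations they must bridge: 0.15 s for fish (pulses last
50-150 ms) and 6 ms for snaps (< 5 ms); both are configuration.

Thresholds are absolute TK energies in Pa^2, one per detector kind
across all sites.  `fit_threshold` selects them on a labelled
calibration scene by scanning a 50-point log grid between the median
and the maximum of the energy trace and maximising pooled F1 against
ground truth at 10 ms matching tolerance.  Validation uses greedy
nearest-neighbour matching (each truth event used at most once) and
reports accuracy = 100 TP/(TP+FP+FN) together with precision and
recall, since count-level agreement alone cannot distinguish the three.

## Synthetic soundscape generator

The generator emulates the statistical structure the analysis relies
on, not the physics of propagation:

* Background noise is a single spectral synthesis combining a white
  floor (0.004 Pa rms default), wind noise (power tilted -10 dB/decade
  above 20 Hz with a steep roll-off past 500 Hz, so its energy sits in
  the 125-250 Hz bands; rms rising 3 dB per Beaufort step by default)
  and a narrowband 28-35 Hz tide component with rms linear in tide
  height.  The three are independent Gaussians, so drawing one
  complex-Gaussian spectrum against the combined PSD is exactly
  equivalent to summing three streams.
* Fish pulses are exponentially damped sinusoids (carrier uniform
  150-600 Hz, duration 50-150 ms, decay constant duration/4, peak
  0.5 Pa default).
* Shrimp snaps are 5 ms Hann-windowed linear chirps sweeping the snap
  band.  At the full 48 kHz rate that band is 4-9 kHz; at reduced rates
  used for fast day-long scenes the band scales into the available
  spectrum (0.9-3.5 kHz at 8 kHz) so snap energy still lands in the
  1-2 kHz analysis bands.
* Event times come from an inhomogeneous Poisson process with hourly
  rates (events/min); diel profiles are Gaussian bumps at the peak
  hours (defaults 06:00 and 18:00).  Amplitudes carry log-normal
  jitter (sigma 0.3 default).  An optional minimum separation thins
  the process for validation scenes that require well-isolated events.

Every injected event is logged with its exact time; identical
(config, seed) reproduce audio and logs bit for bit.

Canonical scenes: the **validation scene** is 20 min at 48 kHz with
flat rates of 35 fish pulses/min (0.3 s minimum separation) and 130
snaps/min (20 ms separation), ~15 dB SNR — sized so it always carries
at least 500 pulses and 2000 snaps.  The **calibration scene** is an
independent 6-minute draw under the same conditions, used only for
threshold fitting.  The **diel experiment** is 7 sites x 24 h at
8 kHz: per-site hourly Beaufort random walks (0-6), a semidiurnal tide
cycle spanning the observed 0.43-1.63 m range, and dusk/dawn chorus
profiles (fish 3->30 events/min, shrimp 40->160).  The 8 kHz rate keeps
a full day of seven sites tractable on one CPU; it cannot represent the
4-9 kHz snap band, which is why the snap band scales with sample rate.

What the generator does *not* emulate — propagation loss, reverberation,
overlapping choruses from distinct species, boat noise, recorder
self-noise structure — bounds what passing tests show: they demonstrate
that the pipeline recovers known structure under the stated noise
model, not that field recordings of arbitrary quality would yield the
same accuracy.

## Temporal aggregation

Files are binned by the local hour of their start time (2-minute files
started on the hour never straddle bins; if one does, the start hour
wins).  Hourly wind/tide series are matched by nearest-hour lookup.
Sites with under 24 h of recording are excluded from circadian and
biological analyses but retained in plain SPL summaries.

## Statistics

* Spearman rank correlation with average ranks for ties; two-sided
  p-values by exact enumeration for n <= 8, seeded Monte-Carlo
  permutation (10,000 draws) for n <= 30, and the t approximation
  above.  A constant series yields an undefined rho, flagged as NaN.
* The additive model is Gaussian with identity link, fitted by mgcv
  through `Rscript`: penalized cubic regression splines (`bs="cr"`,
  k = 8) for wind and the two biophony counts, a cyclic cubic spline
  (`bs="cc"`, k = 10, knots pinned to [0, 24]) for hour, and GCV
  smoothness selection.  Basis size is capped below the number of
  unique covariate values.  The cyclic constraint is verified by
  evaluating the fitted hour smooth on a closed 0-24 grid.  Deviance
  explained and per-smooth effective df are returned; convergence
  failures raise.
* Kruskal-Wallis uses the tie-corrected H with a chi-square reference
  (k-1 df); an all-identical input returns H = 0 rather than an error.
* Wilcoxon-Mann-Whitney reports the tie-corrected normal-approximation
  Z with a two-sided p.
* No multiple-testing correction is applied; the correlation table
  carries an `n_tests` attribute so consumers can see how many
  band x covariate tests were run.

Both rank tests hold their nominal type-I error (simulated rejection
rate within [0.03, 0.07] at alpha = 0.05 over 1,000 null replicates in
the test suite).

## Habitat layer

Fish counts standardize to fishes per 10 m: per transect the mean of
the two swims divided by transect length times 10, averaged over
transects; a missing swim falls back to the available one with a
warning.  Turtle density is count x 10,000 / site surface (m^2).  The
abundance classes partition the half-line as low [0, 2), moderate
[2, 4), high [4, inf) — the printed "2-3.9" interval is read as
[2, 4) so no density is unclassifiable.  Site summaries use sample
standard deviations (ddof = 1).  Turtle counts sum sighted and captured
animals without cross-day deduplication of sightings (tags prevent
double-counting captures only) — a known limitation of the survey
design this layer reproduces.  The curved-carapace-length comparison
consumes per-turtle CSVs and is exercised on synthetic lengths, as no
per-animal sizes are published.

## Problem sizes and determinism

Default problem sizes are chosen so the full test suite and the
acceptance script each run on a single CPU in minutes: the detector
validation processes ~23 min of 48 kHz audio, and the diel experiment
5,040 two-minute files at 8 kHz.  All randomness flows from explicit
seeds through `numpy.random.SeedSequence`; scene segments are seeded
individually so any single file can be re-rendered in isolation, and
reruns produce byte-identical CSV outputs.

## Known limitations

* The order-20 filters are deliberately weak; strong out-of-band
  interferers (e.g. broadband boat noise) would leak into both
  detectors.  The design routine reports achieved attenuation rather
  than hiding it.
* A single global threshold per detector assumes comparable event
  source levels across sites; the log-normal amplitude jitter in the
  generator probes this only mildly (sigma 0.3).
* Field SPL tables from the original deployments cannot be reproduced
  here: the recordings are not public and the original analysis
  software's windowing is unspecified, so cross-site absolute levels
  are validated only qualitatively (ordering and significance, not
  absolute dB).
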