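# reefscape

Soundscape analysis of shallow-water green-turtle foraging habitats.

Passive acoustic monitoring of tropical neritic sites produces long
sequences of 2-minute hydrophone recordings whose content mixes
geophony (wind-driven turbulence, tide), biophony (fish pulse choruses,
snapping-shrimp snaps) and occasional anthrophony.  This package
implements the full desk side of such a study for ecologists working
with these recordings:

* **Calibration** — ADC counts to absolute pressure via hydrophone
  sensitivity (dB re V/μPa), gain and full-scale voltage.
* **Band levels** — sound pressure level per 1/3-octave band,
  SPL = 10·log10(P̄/p₀²) dB re 1 μPa rms with p₀ = 1 μPa, for the 31
  nominal centers 16 Hz–16 kHz (Welch periodogram, Hann 1 s windows),
  with dB↔Pa averaging done in the linear domain.
* **Impulse detection** — fish pulses (decimate to 2 kHz, 100–800 Hz
  equiripple FIR band-pass, order 20) and shrimp snaps (4–9 kHz
  band-pass at native rate), both through the Teager–Kaiser energy
  operator ψ[n] = x[n]² − x[n−1]·x[n+1] and a global per-kind
  threshold, validated against ground truth.
* **Circadian aggregation** — hour-of-day SPL profiles per site/band,
  with a minimum-coverage rule (≥ 24 h) for diel analyses.
* **Statistics** — Spearman correlations of band SPLs with wind
  (Beaufort), tide and biophony counts; a Gaussian GAM
  SPL ~ s(hour, cyclic) + s(wind) + s(fish) + s(crustaceans) fitted by
  mgcv; Kruskal–Wallis across sites; Wilcoxon–Mann–Whitney for
  two-group contrasts.
* **Habitat layer** — standardized fish counts (per 10 m of transect),
  turtle densities per 10,000 m² and the low / moderate / high
  abundance classification (< 2 / 2–3.9 / ≥ 4).
* **Synthetic soundscapes** — a calibrated scene generator (wind, tide,
  diel fish/shrimp choruses with exact ground-truth event logs) that
  stands in for the unpublished field recordings and makes every stage
  testable end to end.

## Worked example

Validate the impulse detectors on the canonical synthetic scene —
thresholds are fitted on a labelled 6-minute calibration scene, then
both detectors run over a held-out 20-minute, 48 kHz scene:

```sh
python analysis/03_detector_validation.py
```

prints (seed 1):

```
thresholds: fish 0.00866 Pa^2, shrimp 0.000461 Pa^2
validation scene: 565 fish pulses, 2520 snaps
accuracy 99.94% (precision 0.999, recall 1.000)
```

i.e. of the 3,085 injected events, all were recovered within 10 ms and
2 spurious detections occurred; pooled accuracy is
100·TP/(TP+FP+FN).  The habitat layer reproduces the survey summary:

```sh
python analysis/04_habitat_abundance.py
```

```
8 sites: 2 high / 3 moderate / 3 low abundance
max depth 5.0 +/- 1.9 m; fish per 10 m 2.0-15.8
```

The day-long multi-site experiment (`analysis/01_simulate_sites.py`
then `analysis/02_band_levels_and_stats.py`, ~10 min) analyzes 5,040
two-minute files from seven synthetic sites and recovers the expected
soundscape structure — per-site Spearman correlations (min / median /
max across sites, all p < 0.001):

```
band_center_hz covariate      min  median   max
31.5           tide_m        0.94    0.98  0.99
125.0          beaufort      0.92    0.99  1.00
500.0          fish_count    0.35    0.67  0.85
2000.0         shrimp_count  0.98    0.98  0.98
GAM (500 Hz band) deviance explained: 78%-98% across sites
```

with chorus profiles peaking at dusk and dawn at every site.

A `reefscape` CLI exposes the same stages over directories of WAV
files (`reefscape synthesize | spl | detect | profile | stats |
habitat | run`); see `reefscape --help`.

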