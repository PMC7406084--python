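"""Third-octave band sound pressure levels.

Band levels are the workhorse descriptor of an underwater soundscape:
the mean-square pressure within each 1/3-octave band, expressed in
dB re 1 uPa rms.  The ladder spans the 31 bands with nominal centers
16 Hz ... 16 kHz; exact centers follow base-2 ratios (2^(1/3) between
neighbours) anchored at 1 kHz, which is why nominal 31.5 Hz sits on the
exact center 31.25 Hz.

Band power is estimated with a Welch averaged periodogram (1 s Hann
windows, 50 % overlap by default) and PSD-bin summation between the band
edges ``center / 2^(1/6)`` and ``center * 2^(1/6)``.

Averaging convention: field practice reports band levels averaged in the
linear (pressure-squared) domain and back-transformed to dB, which keeps
the mean faithful to acoustic energy; :func:`average_spl` implements
that, with an amplitude-domain option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio_io import CalibratedSegment

P_REF_PA = 1e-6  # 1 uPa
_REF_SQ = P_REF_PA**2

#: Nominal third-octave center labels, 16 Hz .. 16 kHz (31 bands).
NOMINAL_CENTERS_HZ: tuple[float, ...] = (
    16, 20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400,
    500, 630, 800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300,
    8000, 10000, 12500, 16000,
)

#: The six bands retained for diel and covariate analysis.
SELECTED_BANDS_HZ: tuple[float, ...] = (31.5, 125, 250, 500, 1000, 2000)


def exact_center(nominal_hz: float) -> float:
    """Exact base-2 center for a nominal label (2^(k/3) ladder through 1 kHz)."""
    if nominal_hz <= 0:
        raise ValueError("center frequency must be positive")
    k = round(3 * np.log2(nominal_hz / 1000.0))
    return 1000.0 * 2.0 ** (k / 3.0)


def third_octave_band_edges(center_hz: float) -> tuple[float, float]:
    """Lower/upper band edge for a given center: center * 2^(+/-1/6)."""
    if center_hz <= 0:
        raise ValueError("center frequency must be positive")
    half = 2.0 ** (1.0 / 6.0)
    return center_hz / half, center_hz * half


@dataclass
class ThirdOctaveSpectrum:
    """Per-band SPL (dB re 1 uPa rms) for one segment."""

    center_freqs_hz: np.ndarray  # nominal labels
    spl_db: np.ndarray
    site_id: str = ""
    start_time: object = None

    def band(self, nominal_hz: float) -> float:
        idx = np.nonzero(np.isclose(self.center_freqs_hz, nominal_hz))[0]
        if idx.size == 0:
            raise KeyError(f"band {nominal_hz} Hz not in spectrum")
        return float(self.spl_db[idx[0]])


def _welch_psd(
    segment: CalibratedSegment, window_s: float, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    nper = int(round(window_s * segment.sample_rate_hz))
    nper = min(nper, len(segment.pressure_pa))
    freqs, psd = signal.welch(
        segment.pressure_pa,
        fs=segment.sample_rate_hz,
        window="hann",
        nperseg=nper,
        noverlap=int(nper * overlap),
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> float:
    df = freqs[1] - freqs[0]
    mask = (freqs >= low) & (freqs < high)
    return float(np.sum(psd[mask]) * df)  # Pa^2 within the band


def band_spl(
    segment: CalibratedSegment,
    center_hz: float,
    *,
    window_s: float = 1.0,
    overlap: float = 0.5,
    nominal: bool = True,
) -> float:
    """SPL (dB re 1 uPa rms) in one third-octave band.

    ``nominal`` means ``center_hz`` is a ladder label and the exact base-2
    center is used internally.  A band whose upper edge exceeds Nyquist is
    an error; digital silence yields ``-inf`` (propagated as missing
    downstream).
    """
    center = exact_center(center_hz) if nominal else center_hz
    low, high = third_octave_band_edges(center)
    if high > segment.sample_rate_hz / 2:
        raise ValueError(
            f"band centered {center_hz} Hz exceeds Nyquist "
            f"({segment.sample_rate_hz / 2:.0f} Hz)"
        )
    freqs, psd = _welch_psd(segment, window_s, overlap)
    power = _integrate_band(freqs, psd, low, high)
    if power <= 0:
        return float("-inf")
    return 10.0 * np.log10(power / _REF_SQ)


def spectrum(
    segment: CalibratedSegment,
    centers_hz: tuple[float, ...] = NOMINAL_CENTERS_HZ,
    *,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> ThirdOctaveSpectrum:
    """Third-octave spectrum over the requested nominal centers.

    One Welch PSD is computed and integrated per band, so the full
    31-band spectrum costs the same as a single band.
    """
    freqs, psd = _welch_psd(segment, window_s, overlap)
    nyq = segment.sample_rate_hz / 2
    spls = []
    for nominal in centers_hz:
        center = exact_center(nominal)
        low, high = third_octave_band_edges(center)
        if high > nyq:
            raise ValueError(f"band centered {nominal} Hz exceeds Nyquist ({nyq:.0f} Hz)")
        power = _integrate_band(freqs, psd, low, high)
        spls.append(10.0 * np.log10(power / _REF_SQ) if power > 0 else float("-inf"))
    return ThirdOctaveSpectrum(
        center_freqs_hz=np.asarray(centers_hz, dtype=float),
        spl_db=np.asarray(spls),
        site_id=segment.site_id,
        start_time=segment.start_time,
    )


def average_spl(values_db, *, domain: str = "power") -> tuple[float, float]:
    """Mean and SD of SPL values, averaged in the linear domain.

    dB values are back-transformed to linear units (mean-square pressure
    for ``domain="power"``, pressure amplitude for ``domain="amplitude"``),
    the arithmetic mean and sample SD (ddof=1) are taken there, and both
    are re-expressed in dB.  A zero linear SD maps to ``-inf`` dB; a
    single value has undefined SD (``nan``).
    """
    vals = np.asarray(values_db, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("average_spl of empty list")
    if domain == "power":
        lin = 10.0 ** (vals / 10.0)
        back = lambda x: 10.0 * np.log10(x)
    elif domain == "amplitude":
        lin = 10.0 ** (vals / 20.0)
        back = lambda x: 20.0 * np.log10(x)
    else:
        raise ValueError("domain must be 'power' or 'amplitude'")
    mean_db = float(back(np.mean(lin)))
    if vals.size < 2:
        return mean_db, float("nan")
    sd = np.std(lin, ddof=1)
    sd_db = float(back(sd)) if sd > 0 else float("-inf")
    return mean_db, sd_db
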