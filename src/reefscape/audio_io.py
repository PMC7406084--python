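"""Calibrated audio input/output.

Hydrophone recordings arrive as integer ADC counts inside mono PCM WAV
files.  Everything downstream (band levels, impulse detection) works on
absolute sound pressure in pascals, so the first step of the pipeline is
the linear calibration

    p[Pa] = counts / 2^(B-1) * V_fullscale / (10^((S + G)/20) * 1e6)

where ``B`` is the ADC bit depth, ``S`` the hydrophone sensitivity in
dB re V/uPa (a negative number, e.g. -174.5 for the deployed units) and
``G`` any additional gain in dB.  The 1e6 converts uPa to Pa.

The module also handles the canonical 2-minute file segmentation and a
CSV recording manifest that tracks which files are excluded from
analysis (e.g. files recorded while turtles were being hand-captured
next to the hydrophone).
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_SEGMENT_S = 120.0

MANIFEST_COLUMNS = ["path", "site", "start_time", "duration_s", "excluded", "reason"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Hydrophone + recorder calibration record.

    sensitivity_db_re_v_per_upa : hydrophone sensitivity, dB re V/uPa
        (negative; the deployed units were -174.5 +/- 2).
    gain_db : additional recorder gain in dB (0 when unstated).
    adc_fullscale_v : voltage mapped to full-scale counts.
    bit_depth : ADC resolution, 16 or 24 bit.
    """

    sensitivity_db_re_v_per_upa: float
    gain_db: float = 0.0
    adc_fullscale_v: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.bit_depth not in (16, 24):
            raise ValueError(f"bit_depth must be 16 or 24, got {self.bit_depth}")
        if self.adc_fullscale_v <= 0:
            raise ValueError("adc_fullscale_v must be positive")

    @property
    def fullscale_counts(self) -> int:
        return 2 ** (self.bit_depth - 1)

    @property
    def pa_per_count(self) -> float:
        """Linear calibration constant: pascals per ADC count."""
        v_per_upa = 10.0 ** ((self.sensitivity_db_re_v_per_upa + self.gain_db) / 20.0)
        return self.adc_fullscale_v / (self.fullscale_counts * v_per_upa * 1e6)


@dataclass
class CalibratedSegment:
    """A contiguous stretch of calibrated pressure, in pascals."""

    pressure_pa: np.ndarray
    sample_rate_hz: float
    start_time: pd.Timestamp
    site_id: str
    clipped: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.pressure_pa = np.asarray(self.pressure_pa, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.pressure_pa) / self.sample_rate_hz

    def split(self, window_s: float = CANONICAL_SEGMENT_S) -> list["CalibratedSegment"]:
        """Cut into consecutive non-overlapping windows; remainder dropped."""
        chunks, _ = segment_stream(self.pressure_pa, self.sample_rate_hz, window_s)
        out = []
        for i, chunk in enumerate(chunks):
            start = self.start_time + pd.Timedelta(seconds=i * window_s)
            out.append(
                CalibratedSegment(
                    pressure_pa=chunk,
                    sample_rate_hz=self.sample_rate_hz,
                    start_time=start,
                    site_id=self.site_id,
                    clipped=self.clipped,
                )
            )
        return out


def counts_to_pressure(
    raw_counts: np.ndarray,
    cal: CalibrationSpec,
    sample_rate_hz: float,
    start_time: pd.Timestamp | str = "1970-01-01",
    site_id: str = "",
) -> CalibratedSegment:
    """Convert integer ADC counts to absolute pressure in pascals.

    Clipped input (samples at or beyond 99 % of full scale) is flagged on
    the returned segment but is not fatal; zero-length input is an error.
    """
    raw = np.asarray(raw_counts)
    if raw.size == 0:
        raise ValueError("zero-length input")
    limit = cal.fullscale_counts
    if np.any(np.abs(raw) > limit):
        raise ValueError("raw counts exceed +/- 2^(bit_depth-1)")
    n_clipped = int(np.count_nonzero(np.abs(raw) >= 0.99 * limit))
    if n_clipped:
        logger.warning("segment contains %d clipped samples", n_clipped)
    return CalibratedSegment(
        pressure_pa=raw.astype(float) * cal.pa_per_count,
        sample_rate_hz=sample_rate_hz,
        start_time=pd.Timestamp(start_time),
        site_id=site_id,
        clipped=n_clipped > 0,
        n_clipped=n_clipped,
    )


def pressure_to_counts(pressure_pa: np.ndarray, cal: CalibrationSpec) -> np.ndarray:
    """Inverse of :func:`counts_to_pressure`, rounding to the nearest count."""
    counts = np.rint(np.asarray(pressure_pa, dtype=float) / cal.pa_per_count)
    limit = cal.fullscale_counts
    counts = np.clip(counts, -limit, limit - 1)
    dtype = np.int16 if cal.bit_depth == 16 else np.int32
    return counts.astype(dtype)


def segment_stream(
    samples: np.ndarray, sample_rate_hz: float, window_s: float = CANONICAL_SEGMENT_S
) -> tuple[list[np.ndarray], int]:
    """Cut a sample stream into consecutive non-overlapping windows.

    Returns (segments, n_dropped_samples).  A trailing remainder shorter
    than one window is dropped (zero-padding would bias SPL estimates);
    a stream shorter than one window yields an empty list with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    samples = np.asarray(samples)
    win = int(round(window_s * sample_rate_hz))
    n_full = len(samples) // win
    dropped = len(samples) - n_full * win
    if n_full == 0:
        logger.warning("stream shorter than one %.0f s window; nothing segmented", window_s)
        return [], dropped
    if dropped:
        logger.info("dropped trailing remainder of %d samples", dropped)
    return [samples[i * win : (i + 1) * win] for i in range(n_full)], dropped


# -- WAV --------------------------------------------------------------------

def write_wav(path: str | Path, counts: np.ndarray, sample_rate_hz: int) -> None:
    """Write mono 16-bit PCM WAV (the canonical recorder format)."""
    counts = np.asarray(counts)
    if counts.dtype != np.int16:
        if np.any(np.abs(counts) > 2**15):
            raise ValueError("counts out of int16 range")
        counts = counts.astype(np.int16)
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(sample_rate_hz))
        w.writeframes(counts.tobytes())


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read mono PCM WAV; returns (counts, sample_rate).

    16-bit returns int16 counts; 24-bit is decoded to int32 counts in the
    +/- 2^23 range.
    """
    with wave.open(str(path), "rb") as w:
        if w.getnchannels() != 1:
            raise ValueError("only mono WAV is supported")
        width = w.getsampwidth()
        fs = w.getframerate()
        frames = w.readframes(w.getnframes())
    if width == 2:
        return np.frombuffer(frames, dtype="<i2"), fs
    if width == 3:
        raw = np.frombuffer(frames, dtype=np.uint8).reshape(-1, 3)
        as32 = (
            raw[:, 0].astype(np.int32)
            | (raw[:, 1].astype(np.int32) << 8)
            | (raw[:, 2].astype(np.int32) << 16)
        )
        as32 = np.where(as32 >= 2**23, as32 - 2**24, as32)  # sign extension
        return as32, fs
    raise ValueError(f"unsupported sample width {width} bytes")


def load_calibrated_wav(
    path: str | Path,
    cal: CalibrationSpec,
    start_time: pd.Timestamp | str,
    site_id: str,
) -> CalibratedSegment:
    counts, fs = read_wav(path)
    return counts_to_pressure(counts, cal, fs, start_time=start_time, site_id=site_id)


def parse_wav_filename(path: str | Path) -> tuple[str, pd.Timestamp]:
    """Parse the ``site_YYYYMMDD_HHMMSS.wav`` naming pattern."""
    stem = Path(path).stem
    parts = stem.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(f"file name {stem!r} does not match site_YYYYMMDD_HHMMSS")
    site, date, time = parts
    return site, pd.Timestamp(f"{date}T{time[:2]}:{time[2:4]}:{time[4:6]}")


# -- manifest ---------------------------------------------------------------

def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a recording manifest CSV, validating required columns."""
    df = pd.read_csv(path)
    if df.empty and not set(MANIFEST_COLUMNS) <= set(df.columns):
        return pd.DataFrame(columns=MANIFEST_COLUMNS)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    df = df.copy()
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    df["reason"] = df["reason"].fillna("")
    for site, grp in df.groupby("site"):
        if not grp["start_time"].is_monotonic_increasing or grp["start_time"].duplicated().any():
            raise ValueError(f"start_times not strictly increasing for site {site!r}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.loc[:, MANIFEST_COLUMNS].copy()
    out["start_time"] = pd.to_datetime(out["start_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def analysis_set(manifest: pd.DataFrame) -> pd.DataFrame:
    """Rows entering analysis: everything not flagged excluded."""
    return manifest.loc[~manifest["excluded"]].reset_index(drop=True)
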