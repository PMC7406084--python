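"""Circadian aggregation and covariate alignment.

Per-file band levels and impulse counts are binned by local hour of day
to expose diel structure (dawn/dusk chorus peaks, daytime wind noise),
and joined with the environmental series for the inferential layer.
Hour-of-day comes from the file's start time; hourly wind/tide series
are matched by nearest-hour lookup.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .spl import average_spl

logger = logging.getLogger(__name__)

MIN_COVERAGE_HOURS = 24.0


def circadian_profile(band_series: pd.DataFrame, *, domain: str = "power") -> pd.DataFrame:
    """Hour-of-day profile of one site/band SPL series.

    ``band_series`` needs columns ``start_time`` and ``spl_db``.  Returns
    24 rows (hour, mean_db, sd_db, n_files); hours with no files carry
    ``n_files == 0`` and missing means.  Per-hour averaging happens in
    the linear pressure-squared domain (see :func:`reefscape.spl.average_spl`).
    """
    if band_series.empty:
        raise ValueError("empty band series")
    df = band_series.copy()
    df["hour"] = pd.to_datetime(df["start_time"]).dt.hour
    rows = []
    for hour in range(24):
        vals = df.loc[df["hour"] == hour, "spl_db"]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append(dict(hour=hour, mean_db=np.nan, sd_db=np.nan, n_files=0))
        else:
            mean_db, sd_db = average_spl(vals.to_numpy(), domain=domain)
            rows.append(dict(hour=hour, mean_db=mean_db, sd_db=sd_db, n_files=len(vals)))
    return pd.DataFrame(rows)


def minimum_coverage_filter(
    file_table: pd.DataFrame, min_hours: float = MIN_COVERAGE_HOURS
) -> pd.DataFrame:
    """Flag sites with too little recording for diel/biological analysis.

    ``file_table`` needs columns ``site`` and ``duration_s`` (one row per
    analyzed file).  Sites totalling under ``min_hours`` are excluded
    with a reason.
    """
    hours = file_table.groupby("site")["duration_s"].sum() / 3600.0
    out = hours.rename("hours").reset_index()
    out["included"] = out["hours"] >= min_hours
    out["reason"] = np.where(
        out["included"], "", f"coverage below {min_hours:g} h"
    )
    for row in out.itertuples():
        if not row.included:
            logger.info("site %s excluded: %.1f h < %g h", row.site, row.hours, min_hours)
    return out


def join_covariates(
    band_spl: pd.DataFrame,
    counts: pd.DataFrame,
    env: pd.DataFrame,
) -> pd.DataFrame:
    """Per-file covariate table for the statistical layer.

    Inner join on (site, start_time) of: long-format band SPLs (pivoted
    wide as ``spl_<band>``), per-file fish/shrimp counts, and the
    environmental table (beaufort, tide_m).  Duplicate keys are an
    error; unmatched rows are logged and dropped; missing covariate
    values survive as NaN.
    """
    keys = ["site", "start_time"]
    wide = band_spl.pivot_table(
        index=keys, columns="band_center_hz", values="spl_db", aggfunc="first"
    )
    wide.columns = [f"spl_{c:g}" for c in wide.columns]
    wide = wide.reset_index()
    counts = counts.drop(columns=["hour"], errors="ignore")
    env = env.drop(columns=["hour"], errors="ignore")
    for name, df in (("counts", counts), ("env", env)):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate (site, start_time) keys in {name} table")
    merged = wide.merge(counts, on=keys, how="inner").merge(env, on=keys, how="inner")
    lost = len(wide) - len(merged)
    if lost:
        logger.warning("join_covariates dropped %d unmatched files", lost)
    if merged.empty:
        logger.warning("join_covariates produced an empty table (disjoint keys)")
    merged["hour"] = pd.to_datetime(merged["start_time"]).dt.hour
    return merged
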