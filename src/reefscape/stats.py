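"""Inferential layer linking band levels to geophony and biophony.

Four tools, matching standard soundscape-ecology practice:

* Spearman rank correlation of a band-SPL series against wind, tide or
  event counts (monotone association, no distributional assumptions);
* a Gaussian additive model (GAM, identity link) of band SPL on hour of
  day, wind, fish counts and shrimp counts — penalized cubic regression
  splines for the covariates and a *cyclic* cubic spline for hour so the
  diel effect joins smoothly across midnight.  Fitting is delegated to
  mgcv (R) through ``Rscript`` with GCV smoothness selection;
* Kruskal-Wallis for comparing band levels across sites;
* Wilcoxon-Mann-Whitney (normal approximation with tie correction) for
  two-group comparisons such as turtle size between islands.

No multiple-testing correction is applied — results tables carry an
``n_tests`` note so the user sees how many band x covariate tests ran.
"""

from __future__ import annotations

import json
import math
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

GAM_DEFAULT_K = {"hour": 10, "beaufort": 8, "fish_count": 8, "shrimp_count": 8}


@dataclass(frozen=True)
class CorrelationResult:
    band_center_hz: float
    covariate: str
    rs: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GamResult:
    response: str
    deviance_explained_pct: float
    edf: dict[str, float]
    n: int
    # fitted smooth of hour evaluated on a closed 0..24 grid (periodicity check)
    hour_grid: tuple[float, ...] = ()
    hour_smooth: tuple[float, ...] = ()


@dataclass(frozen=True)
class RankTestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


# -- Spearman ---------------------------------------------------------------

def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x, y, *, band_center_hz: float = float("nan"), covariate: str = "",
    seed: int = 0, n_perm: int = 10000,
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  p-values: exact enumeration for n <= 8,
    seeded Monte-Carlo permutation for n <= 30, t approximation above.
    Missing pairs are dropped; a constant series yields rho = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return CorrelationResult(band_center_hz, covariate, rho, float("nan"), n)
    if n <= 8:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = _spearman_rho(x, y[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    elif n <= 30:
        rng = np.random.default_rng(seed)
        hits = 1  # identity permutation included
        for _ in range(n_perm):
            r = _spearman_rho(x, y[rng.permutation(n)])
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / (n_perm + 1)
    else:
        t = rho * math.sqrt((n - 2) / max(1 - rho**2, 1e-15))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(band_center_hz, covariate, rho, float(min(p, 1.0)), n)


# -- GAM via mgcv -----------------------------------------------------------

_GAM_R_TEMPLATE = r"""
suppressMessages(library(mgcv))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
spec <- jsonlite::fromJSON(args[2])
terms <- c()
for (i in seq_len(nrow(spec$smooths))) {
  s <- spec$smooths[i, ]
  terms <- c(terms, sprintf("s(%s, bs='%s', k=%d)", s$var, s$bs, s$k))
}
f <- as.formula(paste(spec$response, "~", paste(terms, collapse = " + ")))
m <- gam(f, data = d, family = gaussian(), knots = list(hour = c(0, 24)))
sm <- summary(m)
grid <- data.frame(hour = seq(0, 24, length.out = 49))
for (v in spec$smooths$var) {
  if (v != "hour") grid[[v]] <- mean(d[[v]])
}
pred <- predict(m, newdata = grid, type = "terms")
hour_col <- grep("hour", colnames(pred))
out <- list(
  deviance_explained_pct = 100 * sm$dev.expl,
  edf = as.list(setNames(sm$edf, spec$smooths$var)),
  n = nrow(d),
  hour_grid = grid$hour,
  hour_smooth = as.numeric(pred[, hour_col])
)
cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 10))
"""


def fit_gam(
    table: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("hour", "beaufort", "fish_count", "shrimp_count"),
    k: dict[str, int] | None = None,
) -> GamResult:
    """Fit the Gaussian additive model of one band's SPL.

    ``hour`` gets a cyclic cubic regression spline (knot range pinned to
    [0, 24] so the fitted diel effect is periodic); every other predictor
    a penalized cubic regression spline.  Basis size is capped below the
    number of unique covariate values.  Smoothness is chosen by GCV
    (mgcv's default for Gaussian models).  Raises on convergence
    failure or rank deficiency rather than returning silently.
    """
    k = {**GAM_DEFAULT_K, **(k or {})}
    cols = [response, *predictors]
    d = table.loc[:, cols].replace([np.inf, -np.inf], np.nan).dropna()
    if len(d) < 50:
        raise ValueError(f"fit_gam needs >= 50 complete rows, got {len(d)}")
    smooths = []
    for v in predictors:
        uniq = d[v].nunique()
        bs = "cc" if v == "hour" else "cr"
        kk = min(k.get(v, 8), uniq - 1)
        if kk < 3:
            raise ValueError(f"predictor {v!r} has too few unique values ({uniq})")
        smooths.append(dict(var=v, bs=bs, k=int(kk)))
    with tempfile.TemporaryDirectory() as tmp:
        data_csv = Path(tmp) / "gam_data.csv"
        spec_json = Path(tmp) / "gam_spec.json"
        script = Path(tmp) / "fit_gam.R"
        d.to_csv(data_csv, index=False)
        spec_json.write_text(json.dumps({"response": response, "smooths": smooths}))
        script.write_text(_GAM_R_TEMPLATE)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data_csv), str(spec_json)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"mgcv GAM fit failed:\n{proc.stderr[-2000:]}")
        out = json.loads(proc.stdout)
    return GamResult(
        response=response,
        deviance_explained_pct=float(out["deviance_explained_pct"]),
        edf={key: float(v) for key, v in out["edf"].items()},
        n=int(out["n"]),
        hour_grid=tuple(out["hour_grid"]),
        hour_smooth=tuple(out["hour_smooth"]),
    )


# -- rank tests -------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return RankTestResult("kruskal_wallis", 0.0, 1.0, tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return RankTestResult("kruskal_wallis", float(h), float(p), tuple(len(g) for g in groups))


def wilcoxon_mann_whitney(a, b) -> RankTestResult:
    """Two-sided Wilcoxon-Mann-Whitney via the tie-corrected normal Z."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var <= 0:
        return RankTestResult("wilcoxon_mann_whitney", 0.0, 1.0, (n1, n2))
    z = (u1 - mu) / math.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return RankTestResult("wilcoxon_mann_whitney", float(z), float(p), (n1, n2))


# -- batch helpers over the covariate table ---------------------------------

def correlation_table(
    cov: pd.DataFrame,
    bands: tuple[float, ...] = (31.5, 125, 250, 500, 1000, 2000),
    covariates: tuple[str, ...] = ("beaufort", "tide_m", "fish_count", "shrimp_count"),
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman rs for every band x covariate pair, per site."""
    rows = []
    for site, g in cov.groupby("site"):
        for band in bands:
            col = f"spl_{band:g}"
            if col not in g.columns:
                continue
            for name in covariates:
                if name not in g.columns:
                    continue
                res = spearman(
                    g[col], g[name], band_center_hz=band, covariate=name, seed=seed
                )
                rows.append(
                    dict(site=site, band_center_hz=band, covariate=name,
                         rs=res.rs, p_value=res.p_value, n=res.n)
                )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)  # no multiplicity correction applied
    return out
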