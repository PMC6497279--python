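"""How many frames are enough: plateau detection and the CV stopping rule.

Two lines of evidence decide the sufficient annotation effort for a frame
stream of ``N`` usable frames:

1. **LOWESS plateau.** Replicate diversity estimates are smoothed against
   log10 sample size with locally weighted regression (tricube weights,
   local-linear fits).  The plateau size ``n*`` is the smallest sample size
   beyond which the smoothed slope stays below a tolerance (default 0.05
   diversity units per decade) — the point where annotating more frames no
   longer moves the estimate.
2. **Coefficient of variation.** Across replicates at each size, CV = sd/mean
   of the index.  CV falls roughly linearly in log10(n); an ordinary
   least-squares fit of CV on log10(n) is inverted to find ``n_cv``, the
   smallest size whose predicted CV drops below an acceptability threshold
   (default 25%).

The recommended systematic interval is ``floor(N / max(n*, n_cv))`` — the
more conservative (larger) of the two sample sizes wins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "LowessFit",
    "CvModel",
    "SufficiencyReport",
    "lowess_fit",
    "detect_plateau",
    "cv_by_size",
    "fit_cv_model",
    "sufficiency_report",
]


@dataclass(frozen=True)
class LowessFit:
    """A locally weighted regression of diversity on log10 sample size."""

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    span: float
    n_robust_iters: int


@dataclass(frozen=True)
class CvModel:
    """OLS fit of replicate CV on log10 sample size."""

    slope: float
    intercept: float
    r_squared: float
    n_cv: int | None
    cv_threshold: float

    def predict(self, n) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(n, dtype=float))


@dataclass(frozen=True)
class SufficiencyReport:
    """Joint decision from the plateau and CV rules."""

    n_star: int | None
    slope_tol: float
    cv_slope: float
    cv_intercept: float
    cv_r_squared: float
    n_cv: int | None
    cv_threshold: float
    n_total: int
    recommended_interval: int | None
    index: str = "N2"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def lowess_fit(points, span: float = 2 / 3, n_robust_iters: int = 0) -> LowessFit:
    """Locally weighted scatterplot smoothing at every observed x.

    ``points`` is an (x, y) pair of arrays or a sequence of (x, y) tuples.
    Each fitted value comes from a weighted local-linear regression over the
    ``span`` fraction of nearest neighbours with tricube weights; robustness
    iterations (biweight reweighting) are off by default.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == 2 and arr.shape[1] != 2:
        x, y = arr[0], arr[1]
    else:
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if int(math.ceil(span * len(x))) < 2:
        raise ValueError(
            f"span {span} leaves fewer than 2 points per local window for "
            f"{len(x)} points; increase the span"
        )
    fitted = _sm_lowess(
        y, x, frac=span, it=n_robust_iters, return_sorted=False
    )
    return LowessFit(
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        fitted=np.asarray(fitted, dtype=float),
        span=span,
        n_robust_iters=n_robust_iters,
    )


def detect_plateau(fit: LowessFit, slope_tol: float = 0.05) -> int | None:
    """Smallest sample size beyond which the smoothed curve stays flat.

    Scans the piecewise slopes of the smoothed curve (in diversity units per
    decade of sample size, since x is log10 n) and returns
    ``round(10**x_i)`` for the smallest ``x_i`` from which every later slope
    is below ``slope_tol``.  Returns ``None`` when the curve is still rising
    at its end.
    """
    order = np.argsort(fit.x)
    x = fit.x[order]
    f = fit.fitted[order]
    # collapse tied x (replicates at the same size) to their mean fit
    ux, inv = np.unique(x, return_inverse=True)
    uf = np.zeros_like(ux)
    np.add.at(uf, inv, f)
    uf /= np.bincount(inv)
    if len(ux) < 3:
        raise ValueError("need at least 3 distinct x values")
    slopes = np.diff(uf) / np.diff(ux)
    flat = slopes < slope_tol
    if not flat[-1]:
        return None
    # first index from which every subsequent slope is flat
    i = len(flat)
    while i > 0 and flat[i - 1]:
        i -= 1
    return int(round(10.0 ** ux[i]))


def cv_by_size(curve: pd.DataFrame, index: str = "N2") -> pd.DataFrame:
    """Replicate mean, sd and CV of a diversity index at each sample size.

    ``curve`` is the tidy output of :func:`towcam.subsampling.run_design`.
    Rows are grouped by nominal size; ``n`` is the mean realized frame count.
    CV is NaN where the replicate mean is zero or undefined.
    """
    if index not in curve.columns:
        raise KeyError(index)
    counts = curve.groupby("size_nominal")[index].count()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"need >= 2 replicates per size; offending sizes: {bad}")
    g = curve.groupby("size_nominal")
    out = pd.DataFrame(
        {
            "size_nominal": counts.index,
            "n": g["n_frames"].mean().to_numpy(),
            "mean": g[index].mean().to_numpy(),
            "sd": g[index].std(ddof=1).to_numpy(),
        }
    ).reset_index(drop=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv"] = np.where(out["mean"] != 0, out["sd"] / out["mean"], np.nan)
    return out


def fit_cv_model(cv_table: pd.DataFrame, cv_threshold: float = 0.25) -> CvModel:
    """OLS of CV on log10(n) and the size at which predicted CV first meets the threshold.

    Returns the fitted slope, intercept and R^2, plus ``n_cv``: the smallest
    integer sample size with predicted CV <= ``cv_threshold`` (``None`` when
    the fitted line never reaches it).
    """
    tbl = cv_table.dropna(subset=["cv"])
    if len(tbl) < 3:
        raise ValueError("need at least 3 sizes with a defined CV")
    logn = np.log10(tbl["n"].to_numpy(dtype=float))
    if np.ptp(logn) == 0:
        raise ValueError("all sizes identical; CV model is degenerate")
    res = stats.linregress(logn, tbl["cv"].to_numpy(dtype=float))
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2)

    n_min = int(np.ceil(tbl["n"].min()))
    if intercept + slope * math.log10(n_min) <= cv_threshold:
        n_cv: int | None = n_min
    elif slope >= 0:
        n_cv = None
    else:
        n_cv = int(math.ceil(10.0 ** ((cv_threshold - intercept) / slope)))
    return CvModel(
        slope=slope, intercept=intercept, r_squared=r2, n_cv=n_cv, cv_threshold=cv_threshold
    )


def sufficiency_report(
    curve: pd.DataFrame,
    n_total: int,
    index: str = "N2",
    span: float = 2 / 3,
    n_robust_iters: int = 0,
    slope_tol: float = 0.05,
    cv_threshold: float = 0.25,
) -> SufficiencyReport:
    """Full sufficiency decision from a replicate diversity curve.

    Smooths replicate ``index`` values against log10 realized sample size for
    the plateau size ``n*``, fits the CV model for ``n_cv``, and recommends
    the systematic interval ``floor(n_total / max(n*, n_cv))``.
    """
    pts = curve.dropna(subset=[index])
    if pts.empty:
        raise ValueError("curve has no defined diversity values")
    fit = lowess_fit(
        np.column_stack([np.log10(pts["n_frames"].to_numpy(dtype=float)), pts[index].to_numpy(dtype=float)]),
        span=span,
        n_robust_iters=n_robust_iters,
    )
    n_star = detect_plateau(fit, slope_tol=slope_tol)
    cv_model = fit_cv_model(cv_by_size(curve, index=index), cv_threshold=cv_threshold)

    candidates = [n for n in (n_star, cv_model.n_cv) if n is not None]
    if candidates:
        n_req = max(candidates)
        interval: int | None = max(1, n_total // n_req)
    else:
        interval = None
    return SufficiencyReport(
        n_star=n_star,
        slope_tol=slope_tol,
        cv_slope=cv_model.slope,
        cv_intercept=cv_model.intercept,
        cv_r_squared=cv_model.r_squared,
        n_cv=cv_model.n_cv,
        cv_threshold=cv_model.cv_threshold,
        n_total=n_total,
        recommended_interval=interval,
        index=index,
    )
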