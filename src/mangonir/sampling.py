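"""Spectral outlier screening and correction/prediction set partitioning.

The screen is the standard chemometric PCA-based one: mean-centre the
spectra, decompose, and flag samples whose Hotelling T-squared (distance
inside the model plane) or Q residual (distance off the plane) exceeds
its confidence limit.  Partitioning uses the Kennard-Stone max-min
algorithm on mean-centred raw spectra so one split can be reused across
all candidate pretreatments of an indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .datasets import CalibrationSplit, INDICATORS, INDICATOR_UNITS, SpectrumSet


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

@dataclass
class OutlierResult:
    flags: np.ndarray          # True = outlier
    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    n_components: int
    sample_ids: tuple

    @property
    def outlier_ids(self) -> list:
        return [s for s, f in zip(self.sample_ids, self.flags) if f]


def _q_limit(q: np.ndarray, confidence: float) -> float:
    """Moment-matched scaled-chi-square limit for the Q residual."""
    m = q.mean()
    v = q.var(ddof=1)
    if m <= 0 or v <= 0:
        return 0.0
    g = v / (2.0 * m)
    h = 2.0 * m**2 / v
    return g * stats.chi2.ppf(confidence, h)


def detect_outliers(s: SpectrumSet, n_components: int | None = None,
                    confidence: float = 0.99) -> OutlierResult:
    """PCA T-squared / Q-residual outlier screen on mean-centred spectra.

    ``n_components=None`` keeps components explaining >= 95 % of the
    variance, capped at 10.  A sample is flagged when EITHER statistic
    exceeds its limit at the requested confidence.
    """
    n, p = s.absorbance.shape
    x = s.absorbance - s.absorbance.mean(axis=0)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    var = sv**2 / max(n - 1, 1)
    total = var.sum()
    # variance at rounding level of the absorbance scale = identical spectra
    degenerate = (1e-10 * max(1.0, float(np.abs(s.absorbance).max()))) ** 2
    if total <= degenerate:
        # all spectra identical: nothing to flag
        zeros = np.zeros(n)
        return OutlierResult(np.zeros(n, bool), zeros, zeros.copy(), 0.0, 0.0,
                             0, tuple(s.sample_ids))
    if n_components is None:
        cum = np.cumsum(var) / total
        k = int(np.searchsorted(cum, 0.95) + 1)
        k = min(k, 10, n - 1, p)
    else:
        k = int(n_components)
        if k >= min(n, p):
            raise ValueError("n_components must be < min(n_samples, n_wavelengths)")
    k = max(k, 1)

    scores = u[:, :k] * sv[:k]
    lam = np.where(var[:k] > 0, var[:k], np.inf)
    t2 = ((scores**2) / lam).sum(axis=1)
    resid = x - scores @ vt[:k]
    q = (resid**2).sum(axis=1)

    if n > k:
        f = stats.f.ppf(confidence, k, n - k)
        t2_limit = k * (n - 1) / (n - k) * f
    else:  # degenerate; cannot set a limit
        t2_limit = np.inf
    q_limit = _q_limit(q, confidence) if q.max() > 1e-300 else 0.0
    flags = (t2 > t2_limit) | (q > q_limit) if q_limit > 0 else (t2 > t2_limit)
    return OutlierResult(flags, t2, q, float(t2_limit), float(q_limit),
                         k, tuple(s.sample_ids))


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------

def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Greedy max-min Euclidean sample selection (Kennard-Stone).

    Starts from the two mutually farthest samples, then repeatedly adds
    the sample whose minimum distance to the selected set is largest.
    Ties resolve to the lowest row index, making the order fully
    deterministic.  Returns the indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (2 <= n_select <= n):
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")
    d = squareform(pdist(X))
    # first occurrence in row-major order = lexicographically smallest (i, j)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d))  # argmax returns the lowest index on ties
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf
    return np.asarray(selected)


def correction_size(n: int, ratio: float = 0.75) -> int:
    """Correction-set size: round(ratio * n), half away from zero."""
    return int(math.floor(ratio * n + 0.5))


def split_by_ks(s: SpectrumSet, quality: pd.DataFrame, indicator: str,
                ratio: float = 0.75) -> CalibrationSplit:
    """3:1 Kennard-Stone partition of one indicator's samples.

    Samples missing the indicator are dropped first; Kennard-Stone runs
    on the mean-centred raw spectra of the remainder, selecting the
    correction set; everything else is the prediction set.
    """
    if indicator not in quality.columns:
        raise KeyError(f"indicator {indicator!r} not in quality table")
    keep = quality.loc[quality[indicator].notna(), "sample_id"]
    keep = [sid for sid in keep if sid in s.sample_ids]
    n = len(keep)
    if n < 8:
        raise ValueError(f"only {n} samples with {indicator}; split degenerate (< 8)")
    sub = s.select(keep)
    x = sub.absorbance - sub.absorbance.mean(axis=0)
    n_corr = correction_size(n, ratio)
    sel = kennard_stone(x, n_corr)
    corr_ids = tuple(sub.sample_ids[sel])
    in_corr = set(sel)
    pred_ids = tuple(sid for i, sid in enumerate(sub.sample_ids) if i not in in_corr)
    return CalibrationSplit(indicator, corr_ids, pred_ids, ratio)


# ---------------------------------------------------------------------------
# summaries (calibration-table style)
# ---------------------------------------------------------------------------

def summarize(quality: pd.DataFrame, split: CalibrationSplit) -> pd.DataFrame:
    """Per variety x set summary of the split's indicator.

    Columns: n, minimum, maximum, extreme value (max - min), mean, sd
    and coefficient of variation — the usual sample-characteristics
    table accompanying a calibration/prediction partition.
    """
    ind = split.indicator
    rows = []
    for set_name, ids in (("Correction", split.correction_ids),
                          ("Prediction", split.prediction_ids)):
        sub = quality[quality["sample_id"].isin(ids)]
        if sub.empty:
            raise ValueError(f"{set_name} set is empty")
        for variety, grp in sub.groupby("variety", sort=True):
            v = grp[ind].to_numpy(dtype=float)
            mean = v.mean()
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            rows.append({
                "variety": variety,
                "set": set_name,
                "indicator": ind,
                "unit": INDICATOR_UNITS.get(ind, ""),
                "n": int(v.size),
                "minimum": v.min(),
                "maximum": v.max(),
                "extreme_value": v.max() - v.min(),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            })
    return pd.DataFrame(rows)


def extreme_value(minimum: float, maximum: float) -> float:
    """Range of an indicator: max - min (orientation-checked)."""
    lo, hi = sorted((minimum, maximum))
    return hi - lo
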