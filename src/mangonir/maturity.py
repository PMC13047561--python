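"""Comprehensive harvesting-decision index and maturity grading.

The four quality indicators (firmness, pH, SSC, DMC) are standardised,
summarised by correlation-matrix PCA, and combined into a single
composite evaluation index

    F = a*Z_firmness + b*Z_pH + c*Z_SSC + d*Z_DMC

whose coefficients are the explained-variance-weighted combination of
the score coefficients of the retained components (Kaiser rule by
default).  Fruit maturity is graded on the 6.5-9 scale: grade 6.5 at
the commercial-harvest reference, +0.5 for every 8 further days.  Grade
boundaries on F are calibrated as midpoints between per-grade mean F
values, and classification accuracy is scored per grade and overall.

:class:`MaturityIndex` is the model object (quality table in, ``fit()``
out); the module functions are the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import INDICATORS

GRADE_BASE = 6.5
GRADE_STEP = 0.5
GRADE_DAYS = 8
GRADE_MAX = 9.0

_EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

def standardize(quality: pd.DataFrame, stats: pd.DataFrame | None = None):
    """Z-score the four indicators (columns ordered firmness, pH, SSC, DMC).

    Fit mode (``stats=None``) estimates mean/sd (sample sd, n-1) from
    the data; apply mode reuses the provided stats.  Returns (Z, stats)
    where Z is an n x 4 DataFrame and stats has rows mean/sd.
    """
    X = quality[list(INDICATORS)].to_numpy(dtype=float)
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [INDICATORS[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant indicator(s), cannot standardise: {bad}")
        stats = pd.DataFrame([mean, sd], index=["mean", "sd"],
                             columns=list(INDICATORS))
    z = (X - stats.loc["mean"].to_numpy()) / stats.loc["sd"].to_numpy()
    zf = pd.DataFrame(z, columns=list(INDICATORS), index=quality.index)
    return zf, stats


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA with the reporting conventions used here.

    ``loadings[j, k]`` = eigenvector * sqrt(eigenvalue) (variable-
    component correlations); ``score_coef`` = loadings / eigenvalue, so
    Z @ score_coef gives unit-variance component scores.  Component
    signs are fixed so the SSC loading is >= 0 on every component.
    """

    variables: tuple
    eigenvalues: np.ndarray
    loadings: np.ndarray          # variables x components
    explained_pct: np.ndarray
    score_coef: np.ndarray        # variables x components (0 where eigenvalue ~ 0)

    def cumulative_explained(self, n_components: int) -> float:
        """Cumulative explained variance (%) of the first components."""
        return float(self.explained_pct[:n_components].sum())


def pca_correlation(Z: pd.DataFrame) -> PCAResult:
    """Eigendecompose the correlation matrix of standardised indicators."""
    vars_ = tuple(Z.columns)
    X = Z.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("PCA needs >= 2 variables")
    if n <= p:
        raise ValueError("PCA needs more samples than variables")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite values")
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: SSC loading >= 0; fallback first nonzero positive
    ssc_row = vars_.index("ssc") if "ssc" in vars_ else 0
    for k in range(p):
        v = eigvec[:, k]
        pivot = v[ssc_row]
        if pivot == 0:
            nz = np.flatnonzero(v)
            pivot = v[nz[0]] if nz.size else 1.0
        if pivot < 0:
            eigvec[:, k] = -v
    loadings = eigvec * np.sqrt(eigval)
    explained = 100.0 * eigval / eigval.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        score_coef = np.where(eigval > _EIG_TOL, loadings / eigval, 0.0)
    return PCAResult(vars_, eigval, loadings, explained, score_coef)


def composite_coefficients(p: PCAResult, retain: str | int = "kaiser") -> np.ndarray:
    """Composite index coefficients (a, b, c, d).

    Components are retained by rule — "kaiser" (eigenvalue >= 1), an
    integer (first k), or "first2" — and their score-coefficient rows
    are combined weighted by explained variance:

        coef_j = sum_k explained_k * score_coef[j, k] / sum_k explained_k
    """
    if retain == "kaiser":
        keep = np.flatnonzero(p.eigenvalues >= 1.0)
    elif retain == "first2":
        keep = np.arange(min(2, p.eigenvalues.size))
    else:
        keep = np.arange(int(retain))
    if keep.size == 0:
        warnings.warn("no component passed the retention rule; falling back "
                      "to the first component", RuntimeWarning, stacklevel=2)
        keep = np.array([0])
    w = p.explained_pct[keep]
    w = w / w.sum()
    return p.score_coef[:, keep] @ w


def f_index(Z: pd.DataFrame | np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Composite evaluation index F = a*Zx1 + b*Zx2 + c*Zx3 + d*Zx4."""
    Zm = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    coeffs = np.asarray(coeffs, dtype=float)
    if Zm.shape[1] != coeffs.size:
        raise ValueError(f"{Zm.shape[1]} Z columns but {coeffs.size} coefficients")
    return Zm @ coeffs


# ---------------------------------------------------------------------------
# grade scheme
# ---------------------------------------------------------------------------

def true_grade(days_past_commercial) -> np.ndarray:
    """Maturity grade: 6.5 at the commercial standard, +0.5 per 8 days.

    grade(d) = 6.5 + 0.5 * floor(d / 8), clamped to the labelled 6.5-9
    range (values outside 0-40 days clamp with a warning); negative
    days map to NaN, the pre-commercial window.
    """
    d = np.asarray(days_past_commercial, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d > 40):
        warnings.warn("days > 40 clamp to grade 9", RuntimeWarning, stacklevel=2)
    g = GRADE_BASE + GRADE_STEP * np.floor(d / GRADE_DAYS)
    g = np.clip(g, GRADE_BASE, GRADE_MAX)
    g[d < 0] = np.nan  # pre-commercial
    return float(g[0]) if scalar else g


def grade_label(grade: float) -> str:
    if np.isnan(grade):
        return "pre-commercial"
    return f"{grade:g}"


# ---------------------------------------------------------------------------
# thresholds and classification
# ---------------------------------------------------------------------------

def _pava_increasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: weighted isotonic (non-decreasing) fit."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i] for i in range(y.size)]
    i = 0
    while i < len(blocks) - 1:
        a, b = blocks[i], blocks[i + 1]
        ya = y[a[0]]
        yb = y[b[0]]
        if ya > yb:
            wa = w[a].sum()
            wb = w[b].sum()
            merged = (ya * wa + yb * wb) / (wa + wb)
            blocks[i] = a + b
            del blocks[i + 1]
            y[blocks[i]] = merged
            i = max(i - 1, 0)
        else:
            i += 1
    return y


def calibrate_thresholds(F: np.ndarray, grades: np.ndarray):
    """Grade cut points on F: midpoints between per-grade mean F values.

    Returns (thresholds, grade_labels, grade_means) with labels in
    ascending grade order and len(thresholds) = len(labels) - 1.  If the
    per-grade means are not monotone increasing they are isotonically
    adjusted first (with a warning).
    """
    F = np.asarray(F, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if np.any(np.isnan(grades)):
        raise ValueError("calibration contains ungraded (pre-commercial) samples")
    labels = np.unique(grades)
    if labels.size < 2:
        raise ValueError("need >= 2 grades in the calibration data")
    means = np.array([F[grades == g].mean() for g in labels])
    counts = np.array([(grades == g).sum() for g in labels], dtype=float)
    if np.any(np.diff(means) <= 0):
        warnings.warn("per-grade mean F not strictly increasing; applying "
                      "isotonic adjustment", RuntimeWarning, stacklevel=2)
        means = _pava_increasing(means, counts)
    thresholds = 0.5 * (means[:-1] + means[1:])
    return thresholds, labels, means


def classify(F: np.ndarray, thresholds: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Bin F by the calibrated thresholds into grade labels."""
    F = np.asarray(F, dtype=float)
    idx = np.searchsorted(np.asarray(thresholds, float), F, side="right")
    return np.asarray(labels, dtype=float)[idx]


def classify_and_score(F: np.ndarray, true_grades: np.ndarray,
                       thresholds: np.ndarray, labels: np.ndarray):
    """Grade each sample from F and score against the true grades.

    Returns (per-grade accuracy dict %, overall accuracy %, confusion
    matrix DataFrame true x predicted).
    """
    F = np.asarray(F, dtype=float)
    tg = np.asarray(true_grades, dtype=float)
    if F.size == 0:
        raise ValueError("empty prediction set")
    pred = classify(F, thresholds, labels)
    all_labels = np.unique(np.concatenate([tg, np.asarray(labels, float)]))
    conf = pd.DataFrame(0, index=all_labels, columns=all_labels)
    for t, p in zip(tg, pred):
        conf.loc[t, p] += 1
    per_grade = {}
    for g in np.unique(tg):
        mask = tg == g
        per_grade[float(g)] = 100.0 * float((pred[mask] == g).mean())
    overall = 100.0 * float((pred == tg).mean())
    conf.index.name = "true"
    conf.columns.name = "predicted"
    return per_grade, overall, conf


def f_boxplot_stats(F: np.ndarray, grades: np.ndarray) -> pd.DataFrame:
    """Per-grade five-number summary of F with 1.5*IQR outlier fences.

    Quartiles use linear-interpolation quantiles; whiskers are the most
    extreme points inside the fences; points beyond are listed.
    """
    F = np.asarray(F, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if F.size == 0:
        raise ValueError("no samples to summarise")
    rows = []
    for g in np.unique(grades):
        v = np.sort(F[grades == g])
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence = q1 - 1.5 * iqr
        hi_fence = q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = v[(v < lo_fence) | (v > hi_fence)]
        rows.append({
            "grade": float(g), "n": int(v.size),
            "minimum": float(v[0]), "q1": float(q1), "median": float(med),
            "q3": float(q3), "maximum": float(v[-1]),
            "whisker_low": float(inside[0]), "whisker_high": float(inside[-1]),
            "outliers": outliers.tolist(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class MaturityIndex:
    """Composite harvesting-decision model built from a quality table.

    PCA and composite coefficients are fitted on the pooled calibration
    samples; grade thresholds are calibrated per variety by default
    (varieties ripen on different trajectories, so the same F cuts at
    different values per variety).

    Parameters
    ----------
    quality : pandas.DataFrame
        Quality table with variety/day metadata; ``day`` is days past
        the commercial-harvest reference.
    calibration_ids : sequence of str, optional
        Samples used to fit standardisation, PCA and thresholds
        (default: all).
    retain : "kaiser", "first2" or int
        Component-retention rule.
    per_variety_thresholds : bool
        Calibrate grade cut points per variety (default) or pooled.
    """

    def __init__(self, quality: pd.DataFrame, calibration_ids=None,
                 retain: str | int = "kaiser",
                 per_variety_thresholds: bool = True):
        self.quality = quality.reset_index(drop=True)
        self.calibration_ids = (
            list(calibration_ids) if calibration_ids is not None
            else self.quality["sample_id"].tolist()
        )
        self.retain = retain
        self.per_variety_thresholds = per_variety_thresholds

    def fit(self) -> "MaturityIndexResults":
        cal = self.quality[self.quality["sample_id"].isin(self.calibration_ids)]
        if cal.empty:
            raise ValueError("no calibration samples found in the quality table")
        Z, stats = standardize(cal)
        pca = pca_correlation(Z)
        coeffs = composite_coefficients(pca, self.retain)
        F_cal = f_index(Z, coeffs)
        grades = true_grade(cal["day"].to_numpy())
        thresholds = {}
        if self.per_variety_thresholds:
            for variety, grp in cal.groupby("variety", sort=True):
                mask = cal["sample_id"].isin(grp["sample_id"]).to_numpy()
                thresholds[variety] = calibrate_thresholds(F_cal[mask], grades[mask])
        else:
            thresholds[None] = calibrate_thresholds(F_cal, grades)
        return MaturityIndexResults(self, stats, pca, coeffs, thresholds)


class MaturityIndexResults:
    """Fitted maturity model: coefficients, PCA, grade thresholds."""

    def __init__(self, model: MaturityIndex, stats: pd.DataFrame,
                 pca: PCAResult, coefficients: np.ndarray, thresholds: dict):
        self.model = model
        self.standardization = stats
        self.pca = pca
        self.coefficients = coefficients  # (a, b, c, d)
        self.thresholds = thresholds      # variety -> (cuts, labels, means)

    def f_values(self, quality: pd.DataFrame) -> np.ndarray:
        Z, _ = standardize(quality, self.standardization)
        return f_index(Z, self.coefficients)

    def _cuts_for(self, variety):
        if None in self.thresholds:
            return self.thresholds[None]
        if variety not in self.thresholds:
            raise KeyError(f"no calibrated thresholds for variety {variety!r}")
        return self.thresholds[variety]

    def classify(self, quality: pd.DataFrame) -> pd.DataFrame:
        """Per-sample F, predicted grade, and true grade when day known."""
        F = self.f_values(quality)
        out = quality[["sample_id", "variety"]].copy()
        out["F"] = F
        pred = np.empty(len(quality))
        for variety, grp in quality.groupby("variety", sort=False):
            cuts, labels, _ = self._cuts_for(variety)
            mask = (quality["variety"] == variety).to_numpy()
            pred[mask] = classify(F[mask], cuts, labels)
        out["predicted_grade"] = pred
        if "day" in quality.columns:
            out["true_grade"] = true_grade(quality["day"].to_numpy())
        return out

    def score(self, quality: pd.DataFrame) -> dict:
        """Accuracy per variety: per-grade %, overall %, confusion matrix."""
        graded = self.classify(quality)
        results = {}
        for variety, grp in graded.groupby("variety", sort=True):
            cuts, labels, _ = self._cuts_for(variety)
            per_grade, overall, conf = classify_and_score(
                grp["F"].to_numpy(), grp["true_grade"].to_numpy(), cuts, labels)
            results[variety] = {
                "per_grade_accuracy_pct": per_grade,
                "overall_accuracy_pct": overall,
                "confusion": conf,
            }
        return results

    def summary(self) -> str:
        a, b, c, d = self.coefficients
        lines = [
            "Comprehensive harvesting-decision index",
            "=" * 47,
            f"F = {a:+.4f}*Z_firmness {b:+.4f}*Z_pH "
            f"{c:+.4f}*Z_SSC {d:+.4f}*Z_DMC",
            "",
            "PCA of the correlation matrix:",
        ]
        for k, (ev, ex) in enumerate(zip(self.pca.eigenvalues,
                                         self.pca.explained_pct), 1):
            lines.append(f"  PC{k}: eigenvalue {ev:6.3f}  explained {ex:6.2f} %")
        lines.append(f"  PC1+PC2 cumulative: "
                     f"{self.pca.cumulative_explained(2):.2f} %")
        lines.append("")
        for variety, (cuts, labels, _) in sorted(
                self.thresholds.items(), key=lambda kv: str(kv[0])):
            name = variety if variety is not None else "(pooled)"
            cut_s = ", ".join(f"{c:.3f}" for c in cuts)
            lines.append(f"grade thresholds [{name}]: "
                         f"grades {labels.tolist()} cuts [{cut_s}]")
        return "\n".join(lines)
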