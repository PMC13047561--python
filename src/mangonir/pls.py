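"""NIPALS partial least squares calibration and model evaluation.

The calibration model for each quality indicator is PLS1 regression of
the (pretreated) spectra on the indicator, Y = Xb + e, fitted by the
NIPALS algorithm.  Model quality is reported the way NIR calibration
work reports it: correlation coefficient and root-mean-square error on
the correction set (Rc, RMSEC) and on the independent prediction set
(Rp, RMSEP).

:class:`PLSCalibration` is the user-facing model object (construct from
a SpectrumSet + quality table, call ``fit()``); the module-level
functions underneath are the algorithmic pieces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CalibrationSplit, SpectrumSet
from .preprocess import Pretreatment, standard_candidates

_TOL = 1e-12


# ---------------------------------------------------------------------------
# core NIPALS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS1 model in original (unscaled) coordinates.

    ``coef`` is the regression vector b of Y = Xb + e; ``intercept``
    restores the raw scale after centring.  W, P, q hold the latent
    structure (weights, X-loadings, y-loadings per component).
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray           # p x a
    P: np.ndarray           # p x a
    q: np.ndarray           # a
    coef: np.ndarray        # p
    intercept: float
    n_latent: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent-variable scores T = (X - x_mean) W (P'W)^-1."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return Xc @ R


def fit_pls(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_latent`` components.

    Centres X and y; per component sets w prop. to X'y (unit norm),
    t = Xw, p = X't/(t't), q = y't/(t't), then deflates X and y.  Stops
    early (with the achieved component count) if a degenerate component
    appears (||X'y|| or ||t|| below tolerance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if not (1 <= n_latent <= min(n - 1, p)):
        raise ValueError(f"n_latent must be in [1, {min(n - 1, p)}], got {n_latent}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance; calibration undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.abs(Xc).max()), 1.0)

    Ws, Ps, qs = [], [], []
    for _ in range(n_latent):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL * scale:
            break
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < (_TOL * scale) ** 2:
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        Ws.append(w)
        Ps.append(pvec)
        qs.append(qa)
    if not Ws:
        raise ValueError("no informative component: X carries no covariance with y")
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(x_mean, y_mean, W, P, q, coef, intercept, len(qs))


def select_latent(X: np.ndarray, y: np.ndarray, max_latent: int = 15,
                  folds: int = 10, seed: int | None = None) -> int:
    """Pick the latent-variable count by venetian-blind cross-validation.

    Deterministic ordered folds (sample i -> fold i mod ``folds``); the
    chosen count is the smallest whose CV-RMSE is within one standard
    error of the minimum.  ``seed`` is accepted for interface symmetry
    but unused: the scheme is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds < 2:
        raise ValueError("need >= 2 folds")
    folds = min(folds, n)
    cap = min(max_latent, min(n - n // folds - 1, p))
    if cap < 1:
        raise ValueError("not enough samples for cross-validation")

    sq_err = np.full((folds, cap), np.nan)
    counts = np.zeros(folds)
    for f in range(folds):
        test = np.arange(f, n, folds)
        train = np.setdiff1d(np.arange(n), test)
        counts[f] = test.size
        kmax = min(cap, min(train.size - 1, p))
        for k in range(1, kmax + 1):
            model = fit_pls(X[train], y[train], k)
            resid = y[test] - model.predict(X[test])
            sq_err[f, k - 1] = float(resid @ resid) / test.size
        # reuse the deepest fit for counts the fold could not support
        for k in range(kmax + 1, cap + 1):
            sq_err[f, k - 1] = sq_err[f, kmax - 1]

    w = counts / counts.sum()
    rmse = np.sqrt(sq_err.T @ w)                  # pooled CV-RMSE per count
    fold_rmse = np.sqrt(sq_err)                   # folds x cap
    k_min = int(np.argmin(rmse))
    se = fold_rmse[:, k_min].std(ddof=1) / np.sqrt(folds)
    within = np.flatnonzero(rmse <= rmse[k_min] + se)
    return int(within[0]) + 1


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Calibration/prediction diagnostics for one fitted model."""

    indicator: str
    pretreatment: str
    rc: float
    rmsec: float
    rp: float
    rmsep: float
    n_latent: int
    n_correction: int
    n_prediction: int
    degenerate: bool = False   # constant predictions encountered

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "pretreatment": self.pretreatment,
            "Rc": self.rc, "RMSEC": self.rmsec,
            "Rp": self.rp, "RMSEP": self.rmsep,
            "n_latent": self.n_latent,
            "n_correction": self.n_correction,
            "n_prediction": self.n_prediction,
        }


def _r_and_rmse(measured: np.ndarray, predicted: np.ndarray):
    """Pearson r (0 with a warning if undefined) and RMSE (denominator n)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rmse = float(np.sqrt(np.mean((measured - predicted) ** 2)))
    if np.std(predicted) == 0 or np.std(measured) == 0:
        warnings.warn("constant measured or predicted values; correlation "
                      "reported as 0", RuntimeWarning, stacklevel=2)
        return 0.0, rmse, True
    r = float(np.corrcoef(measured, predicted)[0, 1])
    return r, rmse, False


def evaluate(model: PLSModel, Xc, yc, Xp, yp, indicator: str = "",
             pretreatment: str = "") -> ModelReport:
    """Rc/RMSEC on the correction set, Rp/RMSEP on the prediction set."""
    rc, rmsec, d1 = _r_and_rmse(yc, model.predict(Xc))
    rp, rmsep, d2 = _r_and_rmse(yp, model.predict(Xp))
    return ModelReport(indicator, pretreatment, rc, rmsec, rp, rmsep,
                       model.n_latent, len(np.asarray(yc)), len(np.asarray(yp)),
                       degenerate=d1 or d2)


# ---------------------------------------------------------------------------
# model object (construct -> fit -> results)
# ---------------------------------------------------------------------------

class PLSCalibration:
    """PLS calibration of one quality indicator against NIR spectra.

    Parameters
    ----------
    spectra : SpectrumSet
        Raw spectra (pretreatment is applied internally so its fitted
        statistics come from the correction set only).
    quality : pandas.DataFrame
        Quality table containing ``indicator``.
    indicator : str
        One of firmness, pH, ssc, dmc_pct.
    split : CalibrationSplit
        Correction/prediction partition (see :func:`~mangonir.sampling.split_by_ks`).
    pretreatment : Pretreatment or str, optional
        Spectral pretreatment; default untreated.
    """

    def __init__(self, spectra: SpectrumSet, quality: pd.DataFrame,
                 indicator: str, split: CalibrationSplit,
                 pretreatment: Pretreatment | str = "none"):
        if isinstance(pretreatment, str):
            pretreatment = Pretreatment(pretreatment)
        self.spectra = spectra
        self.quality = quality.set_index("sample_id", drop=False)
        self.indicator = indicator
        self.split = split
        self.pretreatment = pretreatment

    def _sets(self):
        corr = self.spectra.select(self.split.correction_ids)
        pred = self.spectra.select(self.split.prediction_ids)
        self.pretreatment.fit(corr)
        Xc = self.pretreatment.apply(corr).absorbance
        Xp = self.pretreatment.apply(pred).absorbance
        yc = self.quality.loc[list(self.split.correction_ids), self.indicator].to_numpy(float)
        yp = self.quality.loc[list(self.split.prediction_ids), self.indicator].to_numpy(float)
        return Xc, yc, Xp, yp

    def fit(self, n_latent: int | None = None, max_latent: int = 15,
            folds: int = 10) -> "PLSCalibrationResults":
        """Fit; ``n_latent=None`` selects the count by cross-validation."""
        Xc, yc, Xp, yp = self._sets()
        if n_latent is None:
            n_latent = select_latent(Xc, yc, max_latent=max_latent, folds=folds)
        model = fit_pls(Xc, yc, n_latent)
        report = evaluate(model, Xc, yc, Xp, yp, self.indicator,
                          self.pretreatment.label)
        return PLSCalibrationResults(self, model, report)


class PLSCalibrationResults:
    """Fitted calibration: latent structure, diagnostics, predictions."""

    def __init__(self, calibration: PLSCalibration, model: PLSModel,
                 report: ModelReport):
        self.calibration = calibration
        self.model = model
        self.report = report

    # diagnostics, statsmodels-style attribute access
    @property
    def rc(self): return self.report.rc
    @property
    def rmsec(self): return self.report.rmsec
    @property
    def rp(self): return self.report.rp
    @property
    def rmsep(self): return self.report.rmsep
    @property
    def n_latent(self): return self.model.n_latent
    @property
    def params(self) -> np.ndarray:
        """Regression vector b on the pretreated spectral scale."""
        return self.model.coef

    def predict(self, spectra: SpectrumSet) -> pd.Series:
        treated = self.calibration.pretreatment.apply(spectra)
        return pd.Series(self.model.predict(treated.absorbance),
                         index=treated.sample_ids, name=self.calibration.indicator)

    def summary(self) -> str:
        r = self.report
        lines = [
            "PLS calibration results",
            "=" * 47,
            f"indicator:        {r.indicator}",
            f"pretreatment:     {r.pretreatment}",
            f"latent variables: {r.n_latent}",
            f"correction set:   n={r.n_correction}  Rc={r.rc:7.4f}  RMSEC={r.rmsec:.4g}",
            f"prediction set:   n={r.n_prediction}  Rp={r.rp:7.4f}  RMSEP={r.rmsep:.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# pretreatment comparison grid
# ---------------------------------------------------------------------------

def select_pretreatment(spectra: SpectrumSet, quality: pd.DataFrame,
                        split: CalibrationSplit, indicator: str,
                        candidates: list | None = None,
                        max_latent: int = 15, folds: int = 10):
    """Fit one model per candidate pretreatment on the SAME split.

    Ranking: maximise Rp; ties within 0.005 break by lower RMSEP, then
    lower RMSEC, then fewer latent variables.  Returns (best report,
    list of all reports in candidate order).
    """
    if candidates is None:
        candidates = standard_candidates()
    if not candidates:
        raise ValueError("empty candidate list")
    reports = []
    for cand in candidates:
        if isinstance(cand, str):
            cand = Pretreatment(cand)
        res = PLSCalibration(spectra, quality, indicator, split, cand).fit(
            max_latent=max_latent, folds=folds)
        reports.append(res.report)
    return rank_reports(reports), reports


def rank_reports(reports: list, rp_tie: float = 0.005) -> "ModelReport":
    """Best report under the composite optimality rule (see above)."""
    if not reports:
        raise ValueError("empty report list")
    best = reports[0]
    for rep in reports[1:]:
        if rep.rp > best.rp + rp_tie:
            best = rep
        elif rep.rp > best.rp - rp_tie:  # tie on Rp
            key_new = (rep.rmsep, rep.rmsec, rep.n_latent)
            key_old = (best.rmsep, best.rmsec, best.n_latent)
            if key_new < key_old:
                best = rep
    return best


def reports_to_frame(reports: list) -> pd.DataFrame:
    """Comparison-grid table (Parameter, Preprocessing method, Rc, ...)."""
    return pd.DataFrame([r.to_dict() for r in reports])
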