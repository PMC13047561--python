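"""CSV/JSON readers and writers for every pipeline artefact.

Spectra travel as wide CSV (header ``sample_id,650,651,...,950``),
quality tables as plain CSV, splits and fitted models as JSON.  All
round-trips are lossless (numeric tolerance 1e-12): floats are written
with full repr precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CalibrationSplit, QUALITY_COLUMNS, SpectrumSet, validate_quality
from .pls import PLSModel

log = logging.getLogger("mangonir")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def write_spectra(s: SpectrumSet, path) -> None:
    frame = s.to_frame()
    # integer-nm headers when the grid is integral
    cols = [f"{c:g}" for c in frame.columns]
    frame.columns = cols
    frame.to_csv(path, float_format=None)


def read_spectra(path) -> SpectrumSet:
    frame = pd.read_csv(path, index_col=0)
    if frame.index.name != "sample_id":
        raise ValueError(
            f"{path}: malformed header; first column must be 'sample_id', "
            f"got {frame.index.name!r}")
    try:
        wl = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength column: {exc}") from None
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = numeric.index[numeric[col].isna()][0]
        raise ValueError(f"{path}: non-numeric/missing cell at row {row!r}, "
                         f"column {col!r}")
    frame = numeric
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample_id {dup!r}")
    return SpectrumSet(wl, frame.to_numpy(dtype=float), frame.index.astype(str))


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def write_quality(q: pd.DataFrame, path) -> None:
    q[list(QUALITY_COLUMNS)].to_csv(path, index=False)


def read_quality(path) -> pd.DataFrame:
    q = pd.read_csv(path)
    missing = [c for c in QUALITY_COLUMNS if c not in q.columns]
    # tolerate a 'dmc' column name for the dry-matter column
    if "dmc_pct" in missing and "dmc" in q.columns:
        q = q.rename(columns={"dmc": "dmc_pct"})
        missing.remove("dmc_pct")
    if missing:
        raise ValueError(f"{path}: quality table missing column(s) {missing}")
    for col in ("firmness", "pH", "ssc", "dmc_pct"):
        if not pd.api.types.is_numeric_dtype(q[col]):
            bad = q.index[pd.to_numeric(q[col], errors="coerce").isna()
                          & q[col].notna()]
            raise ValueError(f"{path}: non-numeric cell(s) in column {col!r} "
                             f"at row(s) {bad.tolist()[:5]}")
    # unit sniffing: DMC given as a mass fraction rather than percent
    dmc = q["dmc_pct"].dropna()
    if len(dmc) and (dmc < 1.0).all():
        warnings.warn(f"{path}: dmc_pct values all < 1; interpreting as mass "
                      "fractions and converting to percent", UserWarning,
                      stacklevel=2)
        log.warning("%s: converted DMC from fraction to percent", path)
        q["dmc_pct"] = q["dmc_pct"] * 100.0
    return validate_quality(q)


# ---------------------------------------------------------------------------
# splits and models
# ---------------------------------------------------------------------------

def write_split(split: CalibrationSplit, path) -> None:
    Path(path).write_text(json.dumps(split.to_dict(), indent=1, sort_keys=True))


def read_split(path) -> CalibrationSplit:
    return CalibrationSplit.from_dict(json.loads(Path(path).read_text()))


def write_model(model: PLSModel, path, meta: dict | None = None) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept,
        "n_latent": model.n_latent,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_model(path) -> tuple:
    d = json.loads(Path(path).read_text())
    model = PLSModel(
        x_mean=np.asarray(d["x_mean"], float),
        y_mean=float(d["y_mean"]),
        W=np.asarray(d["W"], float),
        P=np.asarray(d["P"], float),
        q=np.asarray(d["q"], float),
        coef=np.asarray(d["coef"], float),
        intercept=float(d["intercept"]),
        n_latent=int(d["n_latent"]),
    )
    return model, d.get("meta", {})
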