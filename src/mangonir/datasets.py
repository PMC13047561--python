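"""Core in-memory containers for the mango NIR workflow.

Two data objects travel through every stage: a :class:`SpectrumSet`
(per-fruit visible/NIR absorbance on a shared wavelength grid) and a
:class:`QualityTable` (the four destructive quality indicators with
variety/batch/day metadata).  Both are thin, validated wrappers around
numpy/pandas structures so that downstream code can rely on their
invariants instead of re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INSTRUMENT_RANGE_NM = (650.0, 950.0)

#: canonical indicator order used everywhere (Z-score columns, PCA, index F)
INDICATORS = ("firmness", "pH", "ssc", "dmc_pct")

#: units for reporting
INDICATOR_UNITS = {
    "firmness": "N/mm^2",
    "pH": "",
    "ssc": "deg Brix",
    "dmc_pct": "%",
}

QUALITY_COLUMNS = ("sample_id", "variety", "batch", "day") + INDICATORS


class SpectrumSet:
    """Absorbance spectra for a set of fruit on one wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Strictly ascending wavelengths in nm, within the 650-950 nm
        instrument range.
    absorbance : array-like, shape (n_samples, n_wavelengths)
        Dimensionless absorbance; no missing values allowed.
    sample_ids : sequence of str
        One unique identifier per row.
    """

    def __init__(self, wavelengths, absorbance, sample_ids):
        wl = np.asarray(wavelengths, dtype=float)
        ab = np.asarray(absorbance, dtype=float)
        if ab.ndim == 1:
            ab = ab[None, :]
        ids = pd.Index([str(s) for s in sample_ids], name="sample_id")
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        lo, hi = INSTRUMENT_RANGE_NM
        if wl[0] < lo - 1e-9 or wl[-1] > hi + 1e-9:
            raise ValueError(
                f"wavelengths outside instrument range {lo:g}-{hi:g} nm: "
                f"[{wl[0]:g}, {wl[-1]:g}]"
            )
        if ab.shape != (len(ids), wl.size):
            raise ValueError(
                f"absorbance shape {ab.shape} does not match "
                f"{len(ids)} samples x {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains missing/non-finite values")
        if ids.has_duplicates:
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicated sample_id(s): {dup}")
        self.wavelengths = wl
        self.absorbance = ab
        self.sample_ids = ids

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy_with(self, absorbance: np.ndarray) -> "SpectrumSet":
        """New set with the same grid/ids and replaced absorbance."""
        return SpectrumSet(self.wavelengths, absorbance, self.sample_ids)

    def select(self, sample_ids: Iterable[str]) -> "SpectrumSet":
        """Subset rows by id, in the order given."""
        idx = self.sample_ids.get_indexer([str(s) for s in sample_ids])
        if np.any(idx < 0):
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"sample_id(s) not in SpectrumSet: {missing}")
        return SpectrumSet(
            self.wavelengths, self.absorbance[idx], self.sample_ids[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per sample, one column per wavelength."""
        return pd.DataFrame(
            self.absorbance, index=self.sample_ids, columns=self.wavelengths
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectrumSet":
        wl = np.asarray([float(c) for c in frame.columns])
        return cls(wl, frame.to_numpy(dtype=float), frame.index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SpectrumSet(n={len(self)}, "
            f"grid={self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm, "
            f"{self.n_wavelengths} points)"
        )


def validate_quality(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a quality table in place and return it.

    Required columns: sample_id, variety, batch, day, firmness, pH, ssc,
    dmc_pct.  Firmness must be positive, pH in (0, 14), SSC non-negative
    and DMC in [0, 100] percent (DMC is always stored in percent).
    """
    missing = [c for c in QUALITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"quality table missing column(s): {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id(s): {dup}")
    checks = [
        ("firmness", table["firmness"] <= 0, "firmness must be > 0 N/mm^2"),
        ("pH", (table["pH"] <= 0) | (table["pH"] >= 14), "pH must be in (0, 14)"),
        ("ssc", table["ssc"] < 0, "SSC must be >= 0 deg Brix"),
        (
            "dmc_pct",
            (table["dmc_pct"] < 0) | (table["dmc_pct"] > 100),
            "DMC must be in [0, 100] percent",
        ),
    ]
    for col, bad, msg in checks:
        bad = bad & table[col].notna()
        if bad.any():
            rows = table.index[bad].tolist()[:5]
            raise ValueError(f"{msg} (offending rows: {rows})")
    return table


@dataclass(frozen=True)
class CalibrationSplit:
    """Correction/prediction partition for one indicator (Kennard-Stone)."""

    indicator: str
    correction_ids: tuple
    prediction_ids: tuple
    ratio: float = 0.75

    def __post_init__(self):
        overlap = set(self.correction_ids) & set(self.prediction_ids)
        if overlap:
            raise ValueError(f"correction/prediction sets overlap: {sorted(overlap)[:5]}")

    @property
    def n_correction(self) -> int:
        return len(self.correction_ids)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_ids)

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "ratio": self.ratio,
            "correction_ids": list(self.correction_ids),
            "prediction_ids": list(self.prediction_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSplit":
        return cls(
            indicator=d["indicator"],
            correction_ids=tuple(d["correction_ids"]),
            prediction_ids=tuple(d["prediction_ids"]),
            ratio=float(d.get("ratio", 0.75)),
        )
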