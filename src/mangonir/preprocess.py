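"""Spectral pretreatments.

Six standard chemometric pretreatments plus the identity, exposed both
as plain functions and as a fit/apply :class:`Pretreatment` object so a
transform fitted on the correction set (relevant only for MSC, whose
reference spectrum must come from the correction set) can be re-applied
to prediction samples without leakage.

Conventions: standard deviations are sample (n-1); vector and min-max
normalisation operate per spectrum (row-wise); Savitzky-Golay
derivatives are scaled by the wavelength step so output units are
absorbance * nm^-k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .datasets import SpectrumSet

METHODS = (
    "none", "msc", "snv", "sg_smooth", "sg_derivative",
    "vector_norm", "minmax_norm",
)


def _check_grid(a: SpectrumSet, b_wl: np.ndarray) -> None:
    if a.wavelengths.shape != b_wl.shape or not np.allclose(a.wavelengths, b_wl):
        raise ValueError("wavelength grid mismatch between spectra and fitted reference")


# ---------------------------------------------------------------------------
# multiplicative scatter correction
# ---------------------------------------------------------------------------

def msc_reference(calibration: SpectrumSet) -> np.ndarray:
    """MSC reference = mean spectrum of the calibration (correction) set."""
    if len(calibration) == 0:
        raise ValueError("cannot fit MSC on an empty calibration set")
    ref = calibration.absorbance.mean(axis=0)
    if np.std(ref) == 0:
        raise ValueError("MSC reference spectrum has zero variance")
    return ref


def msc_apply(s: SpectrumSet, reference: np.ndarray) -> SpectrumSet:
    """Regress each spectrum on the reference and remove slope/offset.

    Per sample, OLS fit observed = a + b * reference; corrected =
    (observed - a) / b.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (s.n_wavelengths,):
        raise ValueError(
            f"MSC reference length {ref.size} does not match the "
            f"{s.n_wavelengths}-point wavelength grid")
    rc = ref - ref.mean()
    denom = rc @ rc
    x = s.absorbance
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    a = x.mean(axis=1) - b * ref.mean()
    return s.copy_with((x - a[:, None]) / b[:, None])


# ---------------------------------------------------------------------------
# row-wise normalisations
# ---------------------------------------------------------------------------

def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum centre and scale to unit sd."""
    x = s.absorbance
    if x.shape[1] < 2:
        raise ValueError("SNV needs >= 2 points per spectrum")
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum, SNV undefined for sample(s): "
            f"{s.sample_ids[bad].tolist()}"
        )
    return s.copy_with((x - x.mean(axis=1, keepdims=True)) / sd[:, None])


def vector_norm(s: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum to unit Euclidean norm."""
    x = s.absorbance
    nrm = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(nrm == 0)
    if bad.size:
        raise ValueError(
            f"zero spectrum, vector normalisation undefined for sample(s): "
            f"{s.sample_ids[bad].tolist()}"
        )
    return s.copy_with(x / nrm[:, None])


def minmax_norm(s: SpectrumSet) -> SpectrumSet:
    """Map each spectrum affinely onto [0, 1] (max-min homing)."""
    x = s.absorbance
    lo = x.min(axis=1)
    hi = x.max(axis=1)
    bad = np.flatnonzero(hi == lo)
    if bad.size:
        raise ValueError(
            f"constant spectrum, min-max normalisation undefined for "
            f"sample(s): {s.sample_ids[bad].tolist()}"
        )
    return s.copy_with((x - lo[:, None]) / (hi - lo)[:, None])


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------

def sg_filter(s: SpectrumSet, window: int = 11, polyorder: int = 2,
              deriv: int = 0) -> SpectrumSet:
    """Savitzky-Golay smoothing (deriv=0) or derivative (deriv=k).

    Local polynomial least squares on a sliding window; edges are
    handled by refitting the polynomial on the one-sided window so the
    wavelength grid is preserved.  Derivatives are divided by the grid
    step to the k-th power (units absorbance * nm^-k); requires a
    uniform grid for deriv > 0.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window length must be odd and positive")
    if deriv < 0 or deriv > polyorder:
        raise ValueError("need 0 <= deriv <= polyorder")
    if window <= polyorder:
        raise ValueError("window length must exceed polynomial order")
    if window > s.n_wavelengths:
        raise ValueError("window longer than the wavelength grid")
    steps = np.diff(s.wavelengths)
    delta = float(steps[0])
    if deriv > 0 and not np.allclose(steps, delta):
        raise ValueError("derivative requires a uniform wavelength grid")
    out = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, axis=1, mode="interp",
    )
    return s.copy_with(out)


# ---------------------------------------------------------------------------
# batch means
# ---------------------------------------------------------------------------

def batch_mean_spectra(s: SpectrumSet, groups) -> SpectrumSet:
    """Mean spectrum per group (batch or maturity grade), ascending labels."""
    labels = pd.Series(list(groups), index=s.sample_ids)
    if len(labels) != len(s):
        raise ValueError("one group label required per sample")
    frame = s.to_frame().groupby(labels, sort=True).mean()
    return SpectrumSet(s.wavelengths, frame.to_numpy(), [str(g) for g in frame.index])


# ---------------------------------------------------------------------------
# fit/apply wrapper
# ---------------------------------------------------------------------------

@dataclass
class Pretreatment:
    """A named pretreatment with its parameters and fitted state.

    Only MSC carries fitted state (the correction-set mean spectrum);
    the others are stateless per-sample transforms, but routing them all
    through fit/apply keeps pipeline code uniform.
    """

    method: str = "none"
    window: int = 11
    polyorder: int = 2
    deriv: int = 1
    reference: np.ndarray | None = None
    reference_grid: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown pretreatment {self.method!r}; one of {METHODS}")

    def fit(self, calibration: SpectrumSet) -> "Pretreatment":
        if self.method == "msc":
            self.reference = msc_reference(calibration)
            self.reference_grid = calibration.wavelengths.copy()
        return self

    def apply(self, s: SpectrumSet) -> SpectrumSet:
        if self.method == "none":
            return s
        if self.method == "msc":
            if self.reference is None:
                raise RuntimeError("MSC must be fitted on the correction set first")
            _check_grid(s, self.reference_grid)
            return msc_apply(s, self.reference)
        if self.method == "snv":
            return snv(s)
        if self.method == "vector_norm":
            return vector_norm(s)
        if self.method == "minmax_norm":
            return minmax_norm(s)
        if self.method == "sg_smooth":
            return sg_filter(s, self.window, self.polyorder, deriv=0)
        if self.method == "sg_derivative":
            return sg_filter(s, self.window, self.polyorder, deriv=self.deriv)
        raise AssertionError("unreachable")

    @property
    def label(self) -> str:
        names = {
            "none": "Original spectrum",
            "msc": "Multiplicative scatter correction",
            "snv": "Standard normal variate transform",
            "sg_smooth": "SG convolution smoothing",
            "sg_derivative": "SG convolution derivative",
            "vector_norm": "Vector normalization",
            "minmax_norm": "Maximum-minimum normalization",
        }
        return names[self.method]


def standard_candidates(window: int = 11, polyorder: int = 2,
                        deriv: int = 1) -> list:
    """The untreated spectrum plus the six standard pretreatments."""
    return [
        Pretreatment("none"),
        Pretreatment("msc"),
        Pretreatment("snv"),
        Pretreatment("sg_smooth", window=window, polyorder=polyorder),
        Pretreatment("sg_derivative", window=window, polyorder=polyorder, deriv=deriv),
        Pretreatment("vector_norm"),
        Pretreatment("minmax_norm"),
    ]
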