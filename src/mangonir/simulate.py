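"""Synthetic orchard generator.

Emulates a multi-variety mango harvest-window study: batches of fruit
picked every few days across the commercial-harvest window, each fruit
measured destructively (firmness, pH, soluble solids, dry matter) and
scanned with a portable 650-950 nm spectrometer.

The generator reproduces the statistical structure the downstream
analysis relies on, not the absolute physics of fruit tissue:

* quality indicators move linearly between variety-specific start/end
  values over the window, plus a batch-shared, lag-1-autocorrelated
  "weather" fluctuation and independent per-fruit measurement noise;
* mean absorbance decreases with maturity grade, with an absorption
  trough near 805 nm and a dry-matter-linked rise above 900 nm;
* each observed spectrum is distorted by a multiplicative slope and an
  additive offset (the scatter effects MSC/SNV are designed to remove)
  plus white noise.

Everything is deterministic under a seed: all sub-streams derive from a
single master ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import INDICATORS, SpectrumSet, validate_quality

DEFAULT_SEED = 20260320

#: lag-1 autocorrelation of the batch-level weather fluctuation
WEATHER_RHO = 0.6


@dataclass(frozen=True)
class SamplingDesign:
    """Batch sampling plan across the harvest window.

    Batch k of a variety is picked on day ``day0_offset + k *
    batch_interval_days`` relative to the commercial-harvest reference
    (k = 0-based batch index; the default offset 0 makes the first batch
    the commercial-harvest reference itself).
    """

    varieties: tuple = ("Tainong", "Guifei", "Jinhuang")
    batches_per_variety: tuple = (11, 10, 10)
    fruits_per_batch: int = 25
    batch_interval_days: int = 4
    day0_offset: int = 0

    def __post_init__(self):
        if len(self.varieties) != len(self.batches_per_variety):
            raise ValueError("one batch count required per variety")
        if any(b <= 0 for b in self.batches_per_variety):
            raise ValueError("batch counts must be positive")
        if self.fruits_per_batch <= 0 or self.batch_interval_days <= 0:
            raise ValueError("fruits_per_batch and batch_interval_days must be positive")

    def batch_days(self, variety: str) -> np.ndarray:
        """Sampling days (past first batch) for one variety."""
        n = self.batches_per_variety[self.varieties.index(variety)]
        return np.arange(n) * self.batch_interval_days

    def window_days(self, variety: str) -> int:
        """Span in days from first to last batch of a variety."""
        return int(self.batch_days(variety)[-1])


def design_total(design: SamplingDesign) -> int:
    """Total number of fruit the design produces."""
    return int(sum(design.batches_per_variety)) * design.fruits_per_batch


@dataclass(frozen=True)
class IndicatorTrajectory:
    """Start/end value of one indicator over the window, plus noise terms.

    ``fluctuation`` is the stationary amplitude (same units as the
    indicator) of the batch-shared weather deviation; ``noise_sd`` the
    per-fruit measurement noise standard deviation.
    """

    start: float
    end: float
    fluctuation: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.fluctuation < 0 or self.noise_sd < 0:
            raise ValueError("fluctuation and noise_sd must be >= 0")

    def at(self, day: np.ndarray, window: float) -> np.ndarray:
        """Linear interpolation between endpoints over [0, window]."""
        frac = np.asarray(day, dtype=float) / window if window > 0 else 0.0
        return self.start + (self.end - self.start) * frac


@dataclass(frozen=True)
class VarietyProfile:
    """Per-variety generative parameters.

    Spectral model for a clean fruit spectrum A(lambda):

        A = level - depth * exp(-(lambda - trough)^2 / (2 width^2))
            - grade_sensitivity * (grade - 6.5)
            + dmc_rise_coeff * DMC% * max(0, (lambda - 900) / 50)

    then per-fruit distortion ``slope * A + offset + noise`` with
    slope ~ N(1, slope_spread), offset ~ N(0, offset_spread).
    """

    name: str
    firmness: IndicatorTrajectory
    pH: IndicatorTrajectory
    ssc: IndicatorTrajectory
    dmc_pct: IndicatorTrajectory
    trough_nm: float = 805.0
    trough_width_nm: float = 60.0
    baseline_level: float = 0.80
    trough_depth: float = 0.35
    dmc_rise_coeff: float = 0.004  # absorbance per % DMC at full ramp
    grade_sensitivity: float = 0.04  # absorbance per maturity grade unit
    slope_spread: float = 0.05
    offset_spread: float = 0.02
    noise_sd: float = 0.005  # spectral white noise, absorbance units

    def __post_init__(self):
        for name in ("slope_spread", "offset_spread", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.firmness.end > self.firmness.start:
            raise ValueError("firmness must be non-increasing over the window")
        for ind in ("pH", "ssc", "dmc_pct"):
            t = getattr(self, ind)
            if t.end < t.start:
                raise ValueError(f"{ind} must be non-decreasing over the window")

    def trajectory(self, indicator: str) -> IndicatorTrajectory:
        return getattr(self, indicator)


def _traj(start, end, fluct_frac=0.05, noise_frac=0.02):
    rng_ = abs(end - start)
    return IndicatorTrajectory(start, end, fluct_frac * rng_, noise_frac * rng_)


def default_profiles(fluctuation_frac: float = 0.05,
                     noise_frac: float = 0.02) -> dict:
    """The three-variety study conditions.

    Endpoints are the published 40-day trajectories for 'Tainong',
    'Guifei' and 'Jinhuang'; fluctuation defaults to 5 % and measurement
    noise to 2 % of each indicator's range.
    """

    def p(name, firm, ph, ssc, dmc):
        return VarietyProfile(
            name=name,
            firmness=_traj(*firm, fluctuation_frac, noise_frac),
            pH=_traj(*ph, fluctuation_frac, noise_frac),
            ssc=_traj(*ssc, fluctuation_frac, noise_frac),
            dmc_pct=_traj(*dmc, fluctuation_frac, noise_frac),
        )

    return {
        "Tainong": p("Tainong", (13.0, 9.3), (2.78, 3.15), (4.2, 6.8), (14.0, 19.0)),
        "Guifei": p("Guifei", (11.6, 9.9), (2.83, 3.29), (4.9, 5.3), (12.0, 13.0)),
        "Jinhuang": p("Jinhuang", (11.6, 7.3), (3.34, 3.88), (4.9, 6.6), (12.0, 14.0)),
    }


def default_grid(step_nm: float = 1.0) -> np.ndarray:
    """650-950 nm grid; 1-nm step (301 points) by default."""
    return np.arange(650.0, 950.0 + step_nm / 2, step_nm)


def continuous_grade(day, day0_offset: int = 0) -> np.ndarray:
    """Maturity grade before flooring: 6.5 + 0.5 * days/8."""
    return 6.5 + 0.5 * (np.asarray(day, dtype=float) + day0_offset) / 8.0


def _check_varieties(design: SamplingDesign, profiles: dict) -> None:
    unknown = [v for v in design.varieties if v not in profiles]
    if unknown:
        raise KeyError(f"no VarietyProfile for variety/varieties {unknown}")


def generate_quality(design: SamplingDesign, profiles: dict,
                     seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Generate the per-fruit quality table for a sampling design.

    Each indicator is the linear trend between its endpoints, plus a
    lag-1 autocorrelated deviation shared by all fruit of a batch
    (weather), plus independent per-fruit measurement noise.
    """
    _check_varieties(design, profiles)
    master = np.random.SeedSequence([seed, 1])
    streams = master.spawn(len(design.varieties))
    rows = []
    for variety, ss in zip(design.varieties, streams):
        rng = np.random.default_rng(ss)
        prof = profiles[variety]
        days = design.batch_days(variety)
        window = max(design.window_days(variety), 1)
        n_batches = len(days)
        # batch-level AR(1) weather deviation per indicator, stationary sd = amplitude
        fluct = {}
        for ind in INDICATORS:
            amp = prof.trajectory(ind).fluctuation
            eps = rng.standard_normal(n_batches)
            f = np.empty(n_batches)
            f[0] = eps[0]
            for k in range(1, n_batches):
                f[k] = WEATHER_RHO * f[k - 1] + math.sqrt(1 - WEATHER_RHO**2) * eps[k]
            fluct[ind] = amp * f
        for b, day in enumerate(days):
            for j in range(design.fruits_per_batch):
                row = {
                    "sample_id": f"{variety[:3].upper()}-B{b:02d}-F{j:02d}",
                    "variety": variety,
                    "batch": b,
                    "day": int(day),
                }
                for ind in INDICATORS:
                    t = prof.trajectory(ind)
                    val = (
                        float(t.at(day, window))
                        + fluct[ind][b]
                        + t.noise_sd * rng.standard_normal()
                    )
                    row[ind] = val
                rows.append(row)
    table = pd.DataFrame(rows)
    return validate_quality(table)


def clean_spectrum(profile: VarietyProfile, grid: np.ndarray,
                   grade: float, dmc_pct: float) -> np.ndarray:
    """Noise- and scatter-free spectrum for one fruit state."""
    wl = np.asarray(grid, dtype=float)
    baseline = profile.baseline_level - profile.trough_depth * np.exp(
        -((wl - profile.trough_nm) ** 2) / (2.0 * profile.trough_width_nm**2)
    )
    ramp = np.clip((wl - 900.0) / 50.0, 0.0, None)
    return (
        baseline
        - profile.grade_sensitivity * (grade - 6.5)
        + profile.dmc_rise_coeff * dmc_pct * ramp
    )


def generate_spectra(quality: pd.DataFrame, profiles: dict,
                     grid: np.ndarray | None = None,
                     seed: int = DEFAULT_SEED) -> SpectrumSet:
    """Generate observed spectra for every fruit in a quality table.

    The clean spectrum is a function of the fruit's continuous maturity
    grade and DMC; the observed spectrum adds multiplicative slope,
    additive offset and white noise per fruit.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 650.0 - 1e-9 or grid[-1] > 950.0 + 1e-9:
        raise ValueError("wavelength grid outside the 650-950 nm instrument range")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    unknown = sorted(set(quality["variety"]) - set(profiles))
    if unknown:
        raise KeyError(f"no VarietyProfile for variety/varieties {unknown}")

    master = np.random.SeedSequence([seed, 2])
    rng = np.random.default_rng(master)
    n = len(quality)
    ab = np.empty((n, grid.size))
    grades = continuous_grade(quality["day"].to_numpy())
    for i, (_, row) in enumerate(quality.iterrows()):
        prof = profiles[row["variety"]]
        clean = clean_spectrum(prof, grid, grades[i], row["dmc_pct"])
        slope = 1.0 + prof.slope_spread * rng.standard_normal()
        offset = prof.offset_spread * rng.standard_normal()
        noise = prof.noise_sd * rng.standard_normal(grid.size)
        ab[i] = slope * clean + offset + noise
    return SpectrumSet(grid, ab, quality["sample_id"].tolist())


def generate_dataset(design: SamplingDesign | None = None,
                     profiles: dict | None = None,
                     grid: np.ndarray | None = None,
                     seed: int = DEFAULT_SEED):
    """Convenience wrapper: quality table + matching spectra."""
    if design is None:
        design = SamplingDesign()
    if profiles is None:
        profiles = default_profiles()
    quality = generate_quality(design, profiles, seed=seed)
    spectra = generate_spectra(quality, profiles, grid=grid, seed=seed)
    return spectra, quality


def scale_noise(profiles: dict, fluctuation_frac: float | None = None,
                noise_frac: float | None = None,
                spectral_noise_sd: float | None = None) -> dict:
    """Return profiles with noise terms rescaled relative to each range.

    Used to run the generator under alternative noise regimes (e.g. a
    noiseless separability check) without touching the trajectories.
    """
    out = {}
    for name, prof in profiles.items():
        kw = {}
        for ind in INDICATORS:
            t = prof.trajectory(ind)
            rng_ = abs(t.end - t.start)
            kw[ind] = IndicatorTrajectory(
                t.start,
                t.end,
                t.fluctuation if fluctuation_frac is None else fluctuation_frac * rng_,
                t.noise_sd if noise_frac is None else noise_frac * rng_,
            )
        if spectral_noise_sd is not None:
            kw["noise_sd"] = spectral_noise_sd
            kw["slope_spread"] = 0.0 if spectral_noise_sd == 0 else prof.slope_spread
            kw["offset_spread"] = 0.0 if spectral_noise_sd == 0 else prof.offset_spread
        out[name] = replace(prof, **kw)
    return out
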