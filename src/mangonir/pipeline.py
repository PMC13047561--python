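"""End-to-end pipeline driver.

Chains every stage: simulate (when no input files are given) -> spectral
outlier screen -> per-indicator Kennard-Stone split -> pretreatment x
PLS comparison grid -> best-model selection -> batch-level correlations
-> PCA / composite index F -> maturity grading — and writes one report
bundle per run: summary tables (sample characteristics, model grid,
correlations), serialized models, grading results, and a run log that
records the seed and every resolved default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json

import numpy as np
import pandas as pd
import yaml

from . import fileio, simulate
from .correlations import quality_correlation
from .datasets import INDICATORS
from .maturity import MaturityIndex
from .pls import PLSCalibration, select_pretreatment, reports_to_frame
from .preprocess import standard_candidates
from .sampling import detect_outliers, split_by_ks, summarize


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with runnable defaults.

    An all-default config simulates the three-variety study design and
    runs the complete analysis on it.
    """

    # inputs; None = simulate
    spectra_path: str | None = None
    quality_path: str | None = None
    out_dir: str = "."
    seed: int = simulate.DEFAULT_SEED
    # generator
    fluctuation_frac: float = 0.05
    noise_frac: float = 0.02
    varieties: tuple = ("Tainong", "Guifei", "Jinhuang")
    batches_per_variety: tuple = (11, 10, 10)
    fruits_per_batch: int = 25
    batch_interval_days: int = 4
    # screening / splitting
    outlier_confidence: float = 0.99
    split_ratio: float = 0.75
    # PLS
    max_latent: int = 15
    cv_folds: int = 10
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 1
    # index
    retain_rule: str = "kaiser"
    per_variety_thresholds: bool = True
    by_batch_correlation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        for key in ("varieties", "batches_per_variety"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["varieties"] = list(d["varieties"])
        d["batches_per_variety"] = list(d["batches_per_variety"])
        return d


def _load_or_simulate(config: PipelineConfig, log: list):
    if (config.spectra_path is None) != (config.quality_path is None):
        raise PipelineError("config: provide both spectra_path and "
                            "quality_path, or neither (to simulate)")
    if config.spectra_path is not None:
        for p in (config.spectra_path, config.quality_path):
            if not Path(p).exists():
                raise PipelineError(f"config: input file not found: {p}")
        log.append(f"inputs: {config.spectra_path}, {config.quality_path}")
        return fileio.read_spectra(config.spectra_path), \
            fileio.read_quality(config.quality_path)
    design = simulate.SamplingDesign(
        varieties=tuple(config.varieties),
        batches_per_variety=tuple(config.batches_per_variety),
        fruits_per_batch=config.fruits_per_batch,
        batch_interval_days=config.batch_interval_days,
    )
    profiles = simulate.default_profiles(config.fluctuation_frac,
                                         config.noise_frac)
    log.append(f"simulated design: {design} (total {simulate.design_total(design)})")
    spectra, quality = simulate.generate_dataset(design, profiles,
                                                 seed=config.seed)
    return spectra, quality


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full analysis; returns the bundle as a dict and writes it.

    The bundle directory is ``<out_dir>/run-<seed>``; contents are
    deterministic under a fixed seed (byte-identical on rerun).
    """
    config = config or PipelineConfig()
    log: list = [f"seed: {config.seed}"]
    log.append(f"resolved config: {json.dumps(config.resolved(), sort_keys=True)}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    spectra, quality = stage("load/simulate", _load_or_simulate, config, log)

    bundle: dict = {"config": config.resolved(), "varieties": {}}
    summaries, grids, correlations = [], [], []
    best_rows = []
    index_cal_ids: list = []    # firmness correction sets, all varieties
    index_pred_ids: list = []

    for variety in config.varieties:
        q_v = quality[quality["variety"] == variety].reset_index(drop=True)
        s_v = spectra.select(q_v["sample_id"])

        screen = stage(f"outlier-screen[{variety}]", detect_outliers, s_v,
                       confidence=config.outlier_confidence)
        keep = ~screen.flags
        log.append(f"{variety}: {screen.flags.sum()} spectral outlier(s) "
                   f"removed of {len(q_v)}: {screen.outlier_ids}")
        q_v = q_v[keep].reset_index(drop=True)
        s_v = spectra.select(q_v["sample_id"])

        candidates = standard_candidates(config.sg_window, config.sg_polyorder,
                                         config.sg_deriv)
        v_out = {"n_retained": int(len(q_v)), "indicators": {}}
        for indicator in INDICATORS:
            split = stage(f"split[{variety}/{indicator}]", split_by_ks,
                          s_v, q_v, indicator, config.split_ratio)
            if indicator == "firmness":
                index_cal_ids.extend(split.correction_ids)
                index_pred_ids.extend(split.prediction_ids)
            summaries.append(summarize(q_v, split).assign(variety=variety))
            best, reports = stage(
                f"train[{variety}/{indicator}]", select_pretreatment,
                s_v, q_v, split, indicator, candidates,
                max_latent=config.max_latent, folds=config.cv_folds)
            grid = reports_to_frame(reports).assign(variety=variety)
            grids.append(grid)
            best_rows.append({**best.to_dict(), "variety": variety})
            v_out["indicators"][indicator] = {
                "split": {"n_correction": split.n_correction,
                          "n_prediction": split.n_prediction},
                "best": best.to_dict(),
            }
            log.append(f"{variety}/{indicator}: best pretreatment "
                       f"'{best.pretreatment}' Rp={best.rp:.4f} "
                       f"RMSEP={best.rmsep:.4g} ({best.n_latent} LVs)")

        corr = stage(f"correlate[{variety}]", quality_correlation, q_v,
                     by_batch=config.by_batch_correlation)
        correlations.append(corr.to_long().assign(variety=variety))
        bundle["varieties"][variety] = v_out

    # pooled composite maturity index; thresholds per variety; calibrated
    # on the firmness correction sets, scored on the prediction sets
    retained = quality[quality["sample_id"].isin(index_cal_ids + index_pred_ids)]
    mi = MaturityIndex(retained, calibration_ids=index_cal_ids,
                       retain=config.retain_rule,
                       per_variety_thresholds=config.per_variety_thresholds)
    results = stage("index", mi.fit)
    pred_q = retained[retained["sample_id"].isin(index_pred_ids)]
    grades = stage("grade", results.classify, pred_q)
    scores = stage("score", results.score, pred_q)

    bundle["maturity"] = {
        "coefficients": dict(zip("abcd", map(float, results.coefficients))),
        "explained_pct": results.pca.explained_pct.tolist(),
        "pc12_cumulative_pct": results.pca.cumulative_explained(2),
        "accuracy": {
            v: {
                "overall_pct": s["overall_accuracy_pct"],
                "per_grade_pct": {f"{g:g}": a for g, a
                                  in s["per_grade_accuracy_pct"].items()},
            } for v, s in scores.items()
        },
    }
    for v, s in scores.items():
        log.append(f"{v}: overall grading accuracy "
                   f"{s['overall_accuracy_pct']:.1f} %")

    # ---- write the bundle -------------------------------------------
    out = Path(config.out_dir) / f"run-{config.seed}"
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(summaries, ignore_index=True).to_csv(out / "sample_summary.csv",
                                                   index=False)
    pd.concat(grids, ignore_index=True).to_csv(out / "model_grid.csv",
                                               index=False)
    pd.DataFrame(best_rows).to_csv(out / "best_models.csv", index=False)
    pd.concat(correlations, ignore_index=True).to_csv(
        out / "correlations.csv", index=False)
    grades.to_csv(out / "grades.csv", index=False)
    (out / "maturity_model.json").write_text(json.dumps({
        "coefficients": bundle["maturity"]["coefficients"],
        "standardization": results.standardization.to_dict(),
        "explained_pct": bundle["maturity"]["explained_pct"],
        "thresholds": {
            str(v): {"cuts": c.tolist(), "grades": l.tolist(),
                     "grade_means": m.tolist()}
            for v, (c, l, m) in results.thresholds.items()},
    }, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(bundle, indent=1,
                                                 sort_keys=True, default=str))
    (out / "run.log").write_text("\n".join(log) + "\n")
    bundle["out_dir"] = str(out)
    bundle["results"] = results
    return bundle
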