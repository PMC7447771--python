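"""End-to-end pipeline: simulate -> extract -> agreement -> robustness.

Every run is a pure function of its :class:`RunConfig`: the single seed is
fanned out deterministically per tumor and observer, so identical configs
produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    RobustnessReport,
    dsc_summary,
    icc_results_frame,
    icc_table,
    nzv_filter,
    pairwise_dsc,
    stratified_compare,
    summarize,
)
from .features import ExtractionConfig, extract_all, write_manifest
from .features.manifest import feature_names
from .phantoms import CohortConfig, ObserverSet, make_cohort, save_cohort
from .preprocess import (
    DEFAULT_BIN_WIDTH_CANDIDATES,
    normalize,
    resample_isotropic,
    select_bin_width,
)

logger = logging.getLogger("radrobust")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_config",
           "extract_cohort_features", "analyze_features"]


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    n_easy: int = 30
    n_challenging: int = 10
    n_observers: int = 4
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    bin_width_auto: bool = False
    bin_width_candidates: tuple[float, ...] = DEFAULT_BIN_WIDTH_CANDIDATES
    dsc_good: float = 0.7
    icc_cutoff: float = 0.9
    nzv_threshold: float = 0.95

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["cohort"].items()
            })
        if "extraction" in d and isinstance(d["extraction"], dict):
            d["extraction"] = ExtractionConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["extraction"].items()
            })
        if "bin_width_candidates" in d:
            d["bin_width_candidates"] = tuple(d["bin_width_candidates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(cfg: RunConfig) -> list[str]:
    """Human-readable config violations; empty list when the config is valid."""
    issues = []
    if cfg.n_easy < 1 or cfg.n_challenging < 1:
        issues.append("n_easy and n_challenging must be >= 1")
    if cfg.n_observers < 2:
        issues.append(f"n_observers must be >= 2, got {cfg.n_observers}")
    if not 0.0 <= cfg.dsc_good <= 1.0:
        issues.append(f"dsc_good must be in [0, 1], got {cfg.dsc_good}")
    if not 0.0 <= cfg.icc_cutoff <= 1.0:
        issues.append(f"icc_cutoff must be in [0, 1], got {cfg.icc_cutoff}")
    if not 0.0 < cfg.nzv_threshold <= 1.0:
        issues.append(f"nzv_threshold must be in (0, 1], got {cfg.nzv_threshold}")
    if cfg.extraction.bin_width <= 0:
        issues.append("extraction.bin_width must be positive")
    if cfg.extraction.resample_target_mm <= 0:
        issues.append("extraction.resample_target_mm must be positive")
    if cfg.bin_width_auto and not cfg.bin_width_candidates:
        issues.append("bin_width_auto requires nonempty bin_width_candidates")
    return issues


def _roi_range(oset: ObserverSet, obs: str, ecfg: ExtractionConfig) -> float:
    img = normalize(oset.image, ecfg.normalization_mode)
    mask = oset.observer_masks[obs]
    if ecfg.resample:
        img, (mask,) = resample_isotropic(img, [mask], ecfg.resample_target_mm)
    vals = img.voxels[mask.voxels]
    return float(np.ptp(vals))


def auto_bin_width(cohort: list[ObserverSet], cfg: RunConfig) -> float:
    """Select the bin width that lands the most ROIs in the target bin range."""
    ranges = [
        _roi_range(oset, obs, cfg.extraction)
        for oset in cohort
        for obs in oset.observer_masks
    ]
    ranges = [r for r in ranges if r > 0]
    return select_bin_width(
        ranges, list(cfg.bin_width_candidates), cfg.extraction.disc_spec()
    )


def extract_cohort_features(
    cohort: list[ObserverSet], ecfg: ExtractionConfig
) -> pd.DataFrame:
    """Long-format feature table over every (tumor, observer) segmentation."""
    rows = []
    for oset in cohort:
        for obs, mask in oset.observer_masks.items():
            try:
                fv = extract_all(oset.image, mask, ecfg)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=extract tumor={oset.tumor_id} observer={obs}: {exc}"
                ) from exc
            rows.extend(
                {
                    "tumor_id": oset.tumor_id,
                    "observer_id": obs,
                    "difficulty": oset.difficulty,
                    "feature_name": name,
                    "value": val,
                }
                for name, val in fv.items()
            )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Final report plus the headline quantities of the run."""

    report: RobustnessReport
    headline: dict


def _stratum_robustness(table: pd.DataFrame, difficulty: str, cutoff: float):
    sub = table[table["difficulty"] == difficulty]
    if sub["tumor_id"].nunique() < 2:
        return None
    return summarize(icc_table(sub, cutoff=cutoff))


def analyze_features(
    features: pd.DataFrame,
    pairs: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Agreement + robustness analysis of an extracted feature table."""
    out = Path(out_dir) if out_dir is not None else None

    filtered, removed = nzv_filter(features, threshold=cfg.nzv_threshold)
    if filtered.empty:
        raise RuntimeError("stage=analyze: all features removed by the nzv filter")
    results = icc_table(filtered, cutoff=cfg.icc_cutoff)
    report = summarize(results)
    summary = dsc_summary(pairs)
    try:
        comparison = stratified_compare(pairs)
    except ValueError as exc:  # a stratum too small for the t-test
        logger.warning("stage=analyze stratified comparison skipped: %s", exc)
        by_diff = pairs.groupby(["tumor_id", "difficulty"])["dsc"].mean().reset_index()
        means = by_diff.groupby("difficulty")["dsc"].mean()
        comparison = {
            "mean_dsc_easy": float(means.get("easy", float("nan"))),
            "mean_dsc_challenging": float(means.get("challenging", float("nan"))),
            "mean_difference": float(
                means.get("easy", float("nan")) - means.get("challenging", float("nan"))
            ),
            "n_easy": int((by_diff["difficulty"] == "easy").sum()),
            "n_challenging": int((by_diff["difficulty"] == "challenging").sum()),
            "t_statistic": float("nan"),
            "p_value": float("nan"),
            "note": str(exc),
        }

    strat_rows = []
    for diff in ("easy", "challenging"):
        rep = _stratum_robustness(filtered, diff, cfg.icc_cutoff)
        dvals = pairs.loc[pairs["difficulty"] == diff, "dsc"]
        strat_rows.append(
            {
                "difficulty": diff,
                "n_tumors": int(
                    pairs.loc[pairs["difficulty"] == diff, "tumor_id"].nunique()
                ),
                "mean_dsc": float(dvals.mean()),
                "frac_dsc_good": float((dvals > cfg.dsc_good).mean()),
                "mean_icc": rep.overall_mean_icc if rep else float("nan"),
                "robust_count": rep.robust_count if rep else 0,
                "total_count": rep.total_count if rep else 0,
                "robust_percentage": rep.robust_percentage if rep else float("nan"),
            }
        )
    stratified = pd.DataFrame(strat_rows)

    headline = {
        "mean_dsc": summary["overall_mean"],
        "dsc_range": list(summary["overall_range"]),
        "per_pair_mean_dsc_range": list(summary["per_pair_mean_range"]),
        "frac_pairs_dsc_good": float((pairs["dsc"] > cfg.dsc_good).mean()),
        "mean_icc": report.overall_mean_icc,
        "mean_icc_ci95": list(report.overall_ci95),
        "robust_count": report.robust_count,
        "total_count": report.total_count,
        "robust_percentage": report.robust_percentage,
        "n_features_removed_nzv": len(removed),
        "mean_dsc_easy": comparison["mean_dsc_easy"],
        "mean_dsc_challenging": comparison["mean_dsc_challenging"],
        "welch_t": comparison["t_statistic"],
        "welch_p": comparison["p_value"],
        "robust_percentage_easy": float(stratified.loc[0, "robust_percentage"]),
        "robust_percentage_challenging": float(
            stratified.loc[1, "robust_percentage"]
        ),
    }

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        pairs.to_csv(out / "dsc_pairs.csv", index=False)
        summary["per_pair"].to_csv(out / "dsc_summary.csv", index=False)
        icc_results_frame(results).to_csv(out / "icc_per_feature.csv", index=False)
        report.group_summary.to_csv(out / "group_summary.csv", index=False)
        stratified.to_csv(out / "stratified_summary.csv", index=False)
        pd.DataFrame({"feature_name": removed}).to_csv(
            out / "removed_features.csv", index=False
        )
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
        (out / "summary.json").write_text(json.dumps(headline, indent=2))

    return PipelineResult(report=report, headline=headline)


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    save_volumes: bool = False,
) -> PipelineResult:
    """Execute the full study: simulate, extract, and analyze.

    Writes all report tables plus a run log and a verbatim config copy when
    ``out_dir`` is given; set ``save_volumes`` to also keep the NIfTI cohort.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    timings = {}
    t0 = time.perf_counter()
    logger.info("stage=simulate n_easy=%d n_challenging=%d seed=%d",
                cfg.n_easy, cfg.n_challenging, cfg.seed)
    try:
        cohort = make_cohort(
            cfg.n_easy, cfg.n_challenging, cfg.n_observers, cfg.seed, cfg.cohort
        )
    except Exception as exc:
        raise RuntimeError(f"stage=simulate: {exc}") from exc
    timings["simulate_s"] = time.perf_counter() - t0
    if out is not None and save_volumes:
        save_cohort(cohort, out / "cohort")

    ecfg = cfg.extraction
    if cfg.bin_width_auto:
        ecfg = dataclasses.replace(ecfg, bin_width=auto_bin_width(cohort, cfg))
        logger.info("stage=binwidth selected=%.3g", ecfg.bin_width)

    t1 = time.perf_counter()
    pairs = pairwise_dsc(cohort)
    timings["dsc_s"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    logger.info("stage=extract n_rois=%d wavelet=%s",
                sum(len(o.observer_masks) for o in cohort), ecfg.wavelet)
    features = extract_cohort_features(cohort, ecfg)
    timings["extract_s"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    result = analyze_features(features, pairs, cfg, out_dir=out)
    timings["analyze_s"] = time.perf_counter() - t3
    result.headline["bin_width"] = float(ecfg.bin_width)

    if out is not None:
        features.to_csv(out / "features_long.csv", index=False)
        wide = features.pivot_table(
            index=["tumor_id", "observer_id"],
            columns="feature_name",
            values="value",
            dropna=False,
        )[feature_names(wavelet=ecfg.wavelet)]
        wide.to_csv(out / "features_wide.csv")
        write_manifest(out / "feature_manifest.json", wavelet=ecfg.wavelet)
        (out / "summary.json").write_text(json.dumps(result.headline, indent=2))
        run_log = {
            "package_version": __version__,
            "seed": cfg.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "n_tumors": len(cohort),
            "n_observers": cfg.n_observers,
            "bin_width": float(ecfg.bin_width),
        }
        (out / "run.json").write_text(json.dumps(run_log, indent=2))
    logger.info("pipeline complete: %s", result.report.formatted_percentage())
    return result
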