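"""Inter-observer agreement and feature-robustness statistics.

Implements the study's statistical machinery:

* pairwise volumetric Dice similarity coefficient (DSC) between observer
  segmentations;
* near-zero-variance filtering of the feature table (a feature whose modal
  value covers >= 95% of observations carries no discriminative value);
* ICC(2,1) — the two-way random-effects, absolute-agreement, single-rater
  intraclass correlation — computed from the two-way ANOVA mean squares;
* robustness classification (ICC strictly above a cutoff, default 0.9),
  per-group summaries, and the easy-vs-challenging stratified comparison
  (Welch two-sided t-test on per-tumor mean DSC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features.manifest import parse_feature_name
from .phantoms import ObserverSet
from .volumes import SegmentationMask, check_aligned

__all__ = [
    "dsc",
    "pairwise_dsc",
    "dsc_summary",
    "nzv_filter",
    "icc21",
    "icc21_confidence_interval",
    "icc_table",
    "ICCResult",
    "RobustnessReport",
    "summarize",
    "stratified_compare",
]


def dsc(a: SegmentationMask, b: SegmentationMask) -> float:
    """Volumetric Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    1 means perfect overlap, 0 means disjoint segmentations.
    """
    if not check_aligned(a, b):
        raise ValueError("masks are not geometrically aligned")
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise ValueError("DSC is undefined for two empty masks")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def pairwise_dsc(cohort: list[ObserverSet]) -> pd.DataFrame:
    """DSC for every unordered observer pair of every tumor.

    Columns: tumor_id, observer_a, observer_b, dsc, difficulty.
    """
    rows = []
    for oset in cohort:
        names = list(oset.observer_masks)
        if len(names) < 2:
            raise ValueError(f"{oset.tumor_id}: need >= 2 observers")
        for a, b in combinations(names, 2):
            rows.append(
                {
                    "tumor_id": oset.tumor_id,
                    "observer_a": a,
                    "observer_b": b,
                    "dsc": dsc(oset.observer_masks[a], oset.observer_masks[b]),
                    "difficulty": oset.difficulty,
                }
            )
    return pd.DataFrame(rows)


def dsc_summary(pairs: pd.DataFrame) -> dict:
    """Overall and per-observer-pair mean DSC (the pairwise-comparison view)."""
    per_pair = (
        pairs.groupby(["observer_a", "observer_b"])["dsc"]
        .mean()
        .reset_index()
        .rename(columns={"dsc": "mean_dsc"})
    )
    return {
        "overall_mean": float(pairs["dsc"].mean()),
        "overall_range": (float(pairs["dsc"].min()), float(pairs["dsc"].max())),
        "per_pair": per_pair,
        "per_pair_mean_range": (
            float(per_pair["mean_dsc"].min()),
            float(per_pair["mean_dsc"].max()),
        ),
    }


def _modal_fraction(values: pd.Series) -> float:
    """Fraction of observations taking the modal value; NaN counts as a value."""
    counts = values.value_counts(dropna=False)
    return float(counts.iloc[0] / len(values)) if len(values) else 1.0


def nzv_filter(
    table: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Remove near-zero-variance features from a long-format feature table.

    A feature is removed when its modal value (undefined values counted as
    one category) covers at least ``threshold`` of all tumor-observer
    records.
    """
    if table.empty:
        raise ValueError("feature table is empty")
    removed = []
    for name, grp in table.groupby("feature_name", sort=False):
        if _modal_fraction(grp["value"]) >= threshold:
            removed.append(name)
    kept = table[~table["feature_name"].isin(removed)].reset_index(drop=True)
    return kept, removed


def icc21(values: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA decomposition of an n x k matrix
    (rows = subjects/tumors, columns = raters/observers).

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with MSR, MSC,
    MSE the subject, rater and residual mean squares.  Returns NaN when the
    denominator vanishes (all cells equal: agreement is undefined).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC(2,1) requires >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        return float("nan")
    if np.all(x == x.flat[0]):
        return float("nan")  # no variance anywhere: agreement is undefined
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)  # guard tiny negative round-off
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(denom, 0.0, atol=1e-30):
        return float("nan")
    return float((msr - mse) / denom)


def icc21_confidence_interval(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """F-based confidence interval for a single feature's ICC(2,1)
    (McGraw & Wong). Optional per-feature output; the pipeline's headline
    CI is the across-feature t-interval in :func:`summarize` instead.
    """
    x = np.asarray(values, dtype=np.float64)
    n, k = x.shape
    r = icc21(x)
    if not np.isfinite(r):
        return (float("nan"), float("nan"))
    grand = x.mean()
    ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(
        (((x - grand) ** 2).sum() - ssr - ssc) / ((n - 1) * (k - 1)), 0.0
    )
    a = k * r / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if not np.isfinite(a):
        return (1.0, 1.0)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    mix = k * msc + (k * n - k - n) * mse
    lower = n * (msr - f_l * mse) / (f_l * mix + n * msr)
    upper = n * (f_u * msr - mse) / (mix + n * f_u * msr)
    return (float(lower), float(upper))


@dataclass
class ICCResult:
    """Per-feature robustness record."""

    feature_name: str
    icc: float
    n_subjects: int
    n_raters: int
    robust: bool
    group: str
    filter: str


def icc_table(
    table: pd.DataFrame, cutoff: float = 0.9
) -> list[ICCResult]:
    """Per-feature ICC(2,1) over the tumors x observers grid.

    Tumors with any undefined value for a feature are dropped for that
    feature (subject-wise deletion).  A feature is robust iff its ICC is
    strictly greater than ``cutoff``; undefined ICCs are never robust.
    """
    results = []
    observers = sorted(table["observer_id"].unique())
    for name, grp in table.groupby("feature_name", sort=False):
        wide = grp.pivot_table(
            index="tumor_id", columns="observer_id", values="value", dropna=False
        ).reindex(columns=observers)
        wide = wide.dropna(axis=0, how="any")
        filt, group, _ = parse_feature_name(name)
        n, k = wide.shape
        icc = icc21(wide.to_numpy()) if n >= 2 and k >= 2 else float("nan")
        results.append(
            ICCResult(
                feature_name=name,
                icc=icc,
                n_subjects=n,
                n_raters=k,
                robust=bool(np.isfinite(icc) and icc > cutoff),
                group=group,
                filter=filt,
            )
        )
    return results


def icc_results_frame(results: list[ICCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_name": r.feature_name,
                "icc": r.icc,
                "n_subjects": r.n_subjects,
                "n_raters": r.n_raters,
                "robust": r.robust,
                "group": r.group,
                "filter": r.filter,
            }
            for r in results
        ]
    )


@dataclass
class RobustnessReport:
    """Per-(filter, group) and overall robustness summary."""

    group_summary: pd.DataFrame
    overall_mean_icc: float
    overall_ci95: tuple[float, float]
    robust_count: int
    total_count: int

    @property
    def robust_percentage(self) -> float:
        return 100.0 * self.robust_count / self.total_count

    def formatted_percentage(self) -> str:
        return (
            f"{self.robust_percentage:.1f}% "
            f"({self.robust_count}/{self.total_count})"
        )


def summarize(results: list[ICCResult]) -> RobustnessReport:
    """Aggregate per-feature ICCs into the study's reporting structure.

    The overall 95% CI is the t-based interval of the mean ICC across
    features (the convention behind across-feature summary CIs).
    """
    if not results:
        raise ValueError("no ICC results to summarize")
    df = icc_results_frame(results)
    rows = []
    for (filt, group), grp in df.groupby(["filter", "group"], sort=False):
        vals = grp["icc"].dropna()
        rows.append(
            {
                "filter": filt,
                "group": group,
                "mean_icc": float(vals.mean()) if len(vals) else float("nan"),
                "min_icc": float(vals.min()) if len(vals) else float("nan"),
                "max_icc": float(vals.max()) if len(vals) else float("nan"),
                "robust_count": int(grp["robust"].sum()),
                "total_count": int(len(grp)),
                "robust_percentage": 100.0 * grp["robust"].sum() / len(grp),
            }
        )
    iccs = df["icc"].dropna().to_numpy()
    mean = float(iccs.mean()) if iccs.size else float("nan")
    if iccs.size > 1 and iccs.std(ddof=1) > 0:
        sem = iccs.std(ddof=1) / np.sqrt(iccs.size)
        tcrit = stats.t.ppf(0.975, iccs.size - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        ci = (mean, mean)
    return RobustnessReport(
        group_summary=pd.DataFrame(rows),
        overall_mean_icc=mean,
        overall_ci95=(float(ci[0]), float(ci[1])),
        robust_count=int(df["robust"].sum()),
        total_count=int(len(df)),
    )


def stratified_compare(pairs: pd.DataFrame) -> dict:
    """Easy-vs-challenging comparison of segmentation agreement.

    Computes per-tumor mean DSC, stratifies by difficulty, and applies a
    two-sided Welch (unequal-variance) independent-samples t-test.
    """
    per_tumor = (
        pairs.groupby(["tumor_id", "difficulty"])["dsc"].mean().reset_index()
    )
    easy = per_tumor.loc[per_tumor["difficulty"] == "easy", "dsc"].to_numpy()
    chall = per_tumor.loc[per_tumor["difficulty"] == "challenging", "dsc"].to_numpy()
    if len(easy) < 2 or len(chall) < 2:
        raise ValueError(
            "each stratum needs >= 2 tumors for the t-test "
            f"(easy={len(easy)}, challenging={len(chall)})"
        )
    t, p = stats.ttest_ind(easy, chall, equal_var=False)
    return {
        "mean_dsc_easy": float(easy.mean()),
        "mean_dsc_challenging": float(chall.mean()),
        "mean_difference": float(easy.mean() - chall.mean()),
        "n_easy": int(len(easy)),
        "n_challenging": int(len(chall)),
        "t_statistic": float(t),
        "p_value": float(p),
    }
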