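"""Cohort-level analysis of a long-format two-tracer SUV table.

A cohort table holds one row per (subject, day, tracer) with the ROI SUV
summary statistics and caliper volume.  The analyses here mirror the
study-level questions: how much higher is HER2-tracer uptake in the
high-HER2 cohort, how do tumours stratify around the pooled-mean SUV
threshold, is the FDG treatment response rank-correlated with HER2 uptake,
do voxel-level SUV histograms shift over treatment, and does baseline
glucose uptake predict response.

Convention notes: percent change is (to − from)/from × 100; the high/low
HER2 split uses the pooled per-tumour mean of the HER2-tracer SUV_mean as
threshold with ties going to "high" (≥); correlations across cohorts use
Spearman, within a single cohort Kendall's tau (small n); subjects missing
either variable of a pairwise analysis are excluded with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from petihc import stats as st
from petihc.synthetic import TRACER_FDG, TRACER_HER2

log = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "StratificationResult",
    "read_cohort_table",
    "her2_threshold",
    "stratify",
    "percent_excess",
    "minmax_spread",
    "fdg_response_correlation",
    "baseline_fdg_vs_her2",
    "histogram_shift",
    "glucose_stratified_response",
    "ihc_correlation",
    "analyze_cohort",
]

COLUMNS = ["subject_id", "cohort", "day", "tracer", "suv_mean", "suv_max",
           "suv_sum", "volume_mm3"]


@dataclass
class StratificationResult:
    threshold: float
    assignments: dict[str, str]  # subject_id -> "high" | "low"

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "assignments": self.assignments}


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (unique (subject, day, tracer) rows)."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if df.duplicated(["subject_id", "day", "tracer"]).any():
        raise ValueError("duplicate (subject_id, day, tracer) rows")
    return df


def _her2_series(table: pd.DataFrame) -> pd.Series:
    """Per-subject HER2-tracer SUV_mean (one record per subject)."""
    rows = table[table["tracer"] == TRACER_HER2]
    if rows.empty:
        raise ValueError(f"no {TRACER_HER2} rows in table")
    return rows.set_index("subject_id")["suv_mean"]


def _fdg_day(table: pd.DataFrame, day: int) -> pd.Series:
    rows = table[(table["tracer"] == TRACER_FDG) & (table["day"] == day)]
    return rows.set_index("subject_id")["suv_mean"]


def her2_threshold(table: pd.DataFrame, override: float | None = None) -> float:
    """HER2 stratification threshold: pooled mean of per-tumour HER2 SUV_mean.

    Pooled over all subjects across cohorts; a fixed override (the study
    prints 2.4) can be supplied instead.
    """
    if override is not None:
        return float(override)
    return float(_her2_series(table).mean())


def stratify(table: pd.DataFrame, threshold: float) -> StratificationResult:
    """Split subjects into high (SUV_mean ≥ threshold) vs low HER2."""
    her2 = _her2_series(table)
    return StratificationResult(
        float(threshold),
        {sid: ("high" if v >= threshold else "low") for sid, v in her2.items()},
    )


def percent_excess(mean_a: float, mean_b: float) -> float:
    """How much higher a is than b, in percent of b."""
    if mean_b == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (mean_a - mean_b) / mean_b


def minmax_spread(table: pd.DataFrame, cohort: str) -> float:
    """Percent difference between the min and max tumour HER2 SUV_mean in a cohort."""
    her2 = _her2_series(table[table["cohort"] == cohort])
    lo, hi = float(her2.min()), float(her2.max())
    if lo == 0:
        raise ValueError("minimum SUV_mean is zero")
    return 100.0 * (hi - lo) / lo


def _paired(table: pd.DataFrame, series_b: pd.Series, what: str
            ) -> tuple[np.ndarray, np.ndarray]:
    her2 = _her2_series(table)
    common = her2.index.intersection(series_b.index)
    dropped = len(set(her2.index) | set(series_b.index)) - len(common)
    if dropped:
        log.info("%s: excluded %d subject(s) missing a measurement", what, dropped)
    return her2.loc[common].to_numpy(float), series_b.loc[common].to_numpy(float)


def fdg_response_correlation(table: pd.DataFrame, from_day: int = 3,
                             to_day: int = 6, method: str | None = None,
                             cohort: str | None = None) -> st.CorrelationResult:
    """Correlation of HER2 uptake with the FDG percent change between two days.

    Spearman across cohorts; within a single cohort Kendall's tau is the
    default (small group sizes).
    """
    if cohort is not None:
        table = table[table["cohort"] == cohort]
        method = method or "kendall"
    method = method or "spearman"
    fdg_from, fdg_to = _fdg_day(table, from_day), _fdg_day(table, to_day)
    change = pd.Series(
        [st.percent_change(fdg_from[s], fdg_to[s])
         for s in fdg_from.index.intersection(fdg_to.index)],
        index=fdg_from.index.intersection(fdg_to.index),
    )
    x, y = _paired(table, change, "fdg_response_correlation")
    return st.spearman(x, y) if method == "spearman" else st.kendall_tau(x, y)


def baseline_fdg_vs_her2(table: pd.DataFrame) -> st.CorrelationResult:
    """Spearman of day-0 FDG SUV_mean against HER2-tracer SUV_mean."""
    x, y = _paired(table, _fdg_day(table, 0), "baseline_fdg_vs_her2")
    return st.spearman(x, y)


def histogram_shift(voxels: Mapping[tuple[str, str, int], np.ndarray],
                    subject: str, tracer: str, day_a: int, day_b: int,
                    **ks_kwargs) -> st.KSResult:
    """KS test between the voxel-level SUV samples behind two day histograms."""
    try:
        a = voxels[(subject, tracer, day_a)]
        b = voxels[(subject, tracer, day_b)]
    except KeyError as e:
        raise KeyError(f"no voxel sample for {e.args[0]}") from None
    return st.ks_two_sample(a, b, **ks_kwargs)


def glucose_stratified_response(table: pd.DataFrame,
                                fdg_threshold: float = 0.15) -> dict:
    """Compare day-0→6 FDG change between high and low baseline-glucose tumours.

    Splits on baseline (day-0) FDG SUV_mean at the threshold (ties to high,
    ≥) and compares the day-0→6 percent change by unpaired t.
    """
    day0, day6 = _fdg_day(table, 0), _fdg_day(table, 6)
    common = day0.index.intersection(day6.index)
    change = {s: st.percent_change(day0[s], day6[s]) for s in common}
    hi = [change[s] for s in common if day0[s] >= fdg_threshold]
    lo = [change[s] for s in common if day0[s] < fdg_threshold]
    if not hi or not lo:
        raise ValueError(
            f"all subjects on one side of baseline FDG threshold {fdg_threshold}")
    t, df, p = st.unpaired_t(hi, lo)
    return {"fdg_threshold": fdg_threshold,
            "n_high": len(hi), "n_low": len(lo),
            "mean_change_high": float(np.mean(hi)),
            "mean_change_low": float(np.mean(lo)),
            "t": t, "df": df, "p_value": p}


def ihc_correlation(her2_pct, glut1_pct) -> st.CorrelationResult:
    """Spearman of paired section-level percent-positive values."""
    her2_pct = np.asarray(her2_pct, dtype=float)
    glut1_pct = np.asarray(glut1_pct, dtype=float)
    if her2_pct.shape != glut1_pct.shape:
        raise ValueError("paired stain percentages must have equal length")
    return st.spearman(her2_pct, glut1_pct)


def analyze_cohort(table: pd.DataFrame,
                   voxels: Mapping[tuple[str, str, int], np.ndarray] | None = None,
                   threshold_override: float | None = None,
                   fdg_threshold: float = 0.15) -> dict:
    """Run every figure-level analysis on a cohort table; returns a JSON-able report."""
    her2 = _her2_series(table)
    cohorts = sorted(table["cohort"].unique())
    by_cohort = {c: her2[table[table["tracer"] == TRACER_HER2]
                         .set_index("subject_id")["cohort"] == c]
                 for c in cohorts}
    cohort_stats = {c: {"n": int(v.size), "suv_mean": float(v.mean()),
                        "suv_sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
                    for c, v in by_cohort.items()}

    means = {c: s["suv_mean"] for c, s in cohort_stats.items()}
    ordered = sorted(means, key=means.get, reverse=True)
    excess = {f"{ordered[0]}_vs_{c}": round(percent_excess(means[ordered[0]], means[c]))
              for c in ordered[1:]}

    thr = her2_threshold(table, threshold_override)
    report = {
        "cohort_suv": cohort_stats,
        "percent_excess": excess,
        "minmax_spread": {c: minmax_spread(table, c) for c in cohorts},
        "her2_threshold": thr,
        "stratification": stratify(table, thr).to_dict(),
        "fdg_change_vs_her2": fdg_response_correlation(table).to_dict(),
        "baseline_fdg_vs_her2": baseline_fdg_vs_her2(table).to_dict(),
        "within_cohort_response": {
            c: fdg_response_correlation(table, cohort=c).to_dict() for c in cohorts},
        "glucose_stratified_response": glucose_stratified_response(
            table, fdg_threshold),
        "her2_anova": st.one_way_anova(
            [by_cohort[c].to_numpy(float) for c in cohorts], cohorts).to_dict(),
    }
    if voxels is not None:
        shifts = {}
        for sid in sorted({k[0] for k in voxels if k[1] == TRACER_FDG}):
            for da, db in ((0, 3), (0, 6), (3, 6)):
                if (sid, TRACER_FDG, da) in voxels and (sid, TRACER_FDG, db) in voxels:
                    shifts[f"{sid}:day{da}_vs_day{db}"] = histogram_shift(
                        voxels, sid, TRACER_FDG, da, db).to_dict()
        report["fdg_histogram_shifts"] = shifts
    return report
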