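"""Spline-based detection of rapid N-dose responses in paired time courses.

Expression in an N-treated and a mock-treated (KCl) arm is followed over a
short (0-120 min) course.  Per gene, log2 size-factor-normalized expression
is fit with a natural cubic spline over time in each arm within one linear
model; a gene is differentially expressed when the arm-by-time interaction
is significant (F-test, BH-adjusted) and the gene is adequately expressed.
DE genes are then binned into the timepoints at which their fold change
versus time zero exceeds a threshold, and the per-timepoint DE counts are
correlated with tracer (15N) uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, CountMatrix
from .dose_model import size_factors

__all__ = [
    "TimeCourseResult",
    "natural_spline_basis",
    "fit_spline_de",
    "bin_by_timepoint",
    "de_counts_per_timepoint",
    "correlate_uptake",
]


@dataclass
class TimeCourseResult:
    """Per-gene time-course verdict."""

    gene_id: str
    de_flag: bool
    raw_p: float
    adj_p: float
    total_counts: int
    fold_changes: dict[float, float] = field(default_factory=dict)  # t -> ratio vs t=0
    bins: dict[float, str] = field(default_factory=dict)  # t -> "up"/"down"


def natural_spline_basis(x: np.ndarray, knots: Sequence[float],
                         boundary: tuple[float, float]) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    Columns: x itself plus one truncated-cubic contrast per interior knot,
    linear beyond the boundary knots.  With k interior knots the basis has
    k + 1 columns, so intercept + basis gives k + 2 model df per arm.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = boundary
    all_knots = np.asarray([lo, *knots, hi], dtype=float)
    if np.any(np.diff(all_knots) <= 0):
        raise ValueError(f"knots must be strictly increasing within ({lo}, {hi})")

    def d(k_idx: int) -> np.ndarray:
        num = (np.clip(x - all_knots[k_idx], 0, None) ** 3
               - np.clip(x - hi, 0, None) ** 3)
        return num / (hi - all_knots[k_idx])

    d_last = d(len(all_knots) - 2)
    cols = [x] + [d(k) - d_last for k in range(len(all_knots) - 2)]
    return np.column_stack(cols)


def _spline_columns(times: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    uniq = np.unique(times)
    qs = np.linspace(0, 1, config.spline_knots + 2)[1:-1]  # interior quantiles
    knots = np.quantile(uniq, qs)
    basis = natural_spline_basis(times, knots, (uniq.min(), uniq.max()))
    want = config.spline_df - 1  # df counts the intercept
    if basis.shape[1] != want:
        raise ValueError(
            f"spline config inconsistent: {config.spline_knots} interior knots "
            f"give {basis.shape[1] + 1} df, config requests {config.spline_df}")
    return basis


def fit_spline_de(
    treated: CountMatrix,
    control: CountMatrix,
    times: Sequence[float],
    config: AnalysisConfig | None = None,
) -> list[TimeCourseResult]:
    """Differential expression between arms over time.

    ``times`` gives the sampling time of each column (identical layout in
    both arms).  Both arms are normalized jointly by median-of-ratios size
    factors; the per-gene model on log2(normalized + 1) compares

        intercept + spline(t) + arm   vs   ... + arm x spline(t)

    by an F-test, BH-adjusted across genes.  A gene is DE iff the adjusted
    p is below ``assoc_alpha`` and its combined read count over all columns
    of both arms exceeds ``timecourse_min_total``.
    """
    config = config or AnalysisConfig()
    if treated.gene_ids != control.gene_ids:
        raise ValueError("treated and control arms carry different gene ids")
    times = np.asarray(times, dtype=float)
    if treated.shape[1] != len(times) or control.shape[1] != len(times):
        raise ValueError("times must give one entry per column of each arm")
    if len(np.unique(times)) < 4:
        raise ValueError("need at least 4 distinct timepoints for the spline")

    combined = CountMatrix(pd.concat(
        [treated.counts.add_suffix("_trt"), control.counts.add_suffix("_ctl")],
        axis=1))
    factors = size_factors(combined).to_numpy()
    norm = combined.values() / factors
    y = np.log2(norm + 1.0)  # genes x (2 * n columns)

    t_all = np.concatenate([times, times])
    arm = np.concatenate([np.ones(len(times)), np.zeros(len(times))])
    basis = _spline_columns(t_all, config)
    ones = np.ones(len(t_all))
    X_reduced = np.column_stack([ones, basis, arm])
    X_full = np.column_stack([X_reduced, basis * arm[:, None]])

    raw_p = _f_test_nested(y.T, X_reduced, X_full)
    adj_p = multipletests(raw_p, method="fdr_bh")[1]

    totals = combined.values().sum(axis=1)
    n_trt = len(times)
    results = []
    for g, gene_id in enumerate(treated.gene_ids):
        de = bool(adj_p[g] < config.assoc_alpha
                  and totals[g] > config.timecourse_min_total)
        fold = _fold_changes(norm[g, :n_trt], times)
        results.append(TimeCourseResult(gene_id, de, float(raw_p[g]),
                                        float(adj_p[g]), int(totals[g]), fold))
    return results


def _f_test_nested(Y: np.ndarray, X_reduced: np.ndarray,
                   X_full: np.ndarray) -> np.ndarray:
    """Vectorized nested-model F-test p-values for every response column."""
    n = Y.shape[0]
    rss_r = _rss(Y, X_reduced)
    rss_f = _rss(Y, X_full)
    q = X_full.shape[1] - X_reduced.shape[1]
    dof = n - X_full.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the full spline model")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / q) / (rss_f / dof)
    f = np.where(rss_f <= 0, np.inf, f)
    return stats.f.sf(f, q, dof)


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return (resid ** 2).sum(axis=0)


def _fold_changes(norm_row: np.ndarray, times: np.ndarray) -> dict[float, float]:
    """Treated-arm mean normalized expression at t over the t=0 mean."""
    base = norm_row[times == 0].mean()
    out = {}
    for t in np.unique(times):
        if t == 0:
            continue
        mean_t = norm_row[times == t].mean()
        out[float(t)] = float(mean_t / base) if base > 0 else np.inf
    return out


def bin_by_timepoint(
    results: Sequence[TimeCourseResult],
    config: AnalysisConfig | None = None,
) -> dict[float, dict[str, set[str]]]:
    """Assign DE genes to the timepoints where they are activated/repressed.

    A DE gene is "up" at t when its fold change versus t = 0 strictly
    exceeds ``fc_threshold`` and "down" when it falls strictly below
    ``1 / fc_threshold``; a gene may occupy several timepoints.  Also fills
    each result's ``bins``.
    """
    config = config or AnalysisConfig()
    thr = config.fc_threshold
    out: dict[float, dict[str, set[str]]] = {}
    for res in results:
        if not res.de_flag:
            continue
        for t, fc in res.fold_changes.items():
            if t == 0:
                raise ValueError("fold changes at t=0 are undefined")
            slot = out.setdefault(t, {"up": set(), "down": set()})
            if fc > thr:
                slot["up"].add(res.gene_id)
                res.bins[t] = "up"
            elif fc < 1.0 / thr:
                slot["down"].add(res.gene_id)
                res.bins[t] = "down"
    return out


def de_counts_per_timepoint(
    bins: Mapping[float, Mapping[str, set[str]]],
    times: Sequence[float],
) -> np.ndarray:
    """Number of distinct DE genes binned at each requested timepoint."""
    counts = []
    for t in times:
        slot = bins.get(float(t), {"up": set(), "down": set()})
        counts.append(len(slot["up"] | slot["down"]))
    return np.asarray(counts)


def correlate_uptake(de_counts: Sequence[float],
                     uptake: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of DE counts with tracer uptake."""
    de_counts = np.asarray(de_counts, dtype=float)
    uptake = np.asarray(uptake, dtype=float)
    if de_counts.shape != uptake.shape or de_counts.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 timepoints")
    if np.ptp(de_counts) == 0 or np.ptp(uptake) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(de_counts, uptake)
    return float(r), float(p)
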