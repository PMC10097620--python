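"""Differential-interactor calling.

Two branches, matching the published analysis:

* BH branch — right-tailed two-sample t-test of each bait condition against
  its control, Benjamini–Hochberg adjustment, and a call when the linear
  fold change exceeds ``fold_change`` (default 1.5) and the adjusted P is
  below ``alpha`` (default 0.05).
* Permutation branch — the SAM-style statistic d = diff / (se + s0) with a
  permutation-estimated FDR (default 0.1, s0 = 0.1, 250 randomisations) and
  a volcano cutoff curve; only points with positive t-test difference are
  eligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)


def _welch_parts(a: np.ndarray, b: np.ndarray):
    """Vectorised two-sample statistic pieces along axis 1.

    Returns (diff, se, df) for the Welch (unequal-variance) form. Arrays may
    contain NaN; rows with <2 finite values in either group yield NaN.
    """
    n1 = np.sum(np.isfinite(a), axis=1).astype(float)
    n2 = np.sum(np.isfinite(b), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    bad = (n1 < 2) | (n2 < 2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        q1, q2 = v1 / n1, v2 / n2
        se = np.sqrt(q1 + q2)
        df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
    # zero-variance groups: se 0 -> df undefined; fall back to n1+n2-2
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    diff[bad], se[bad], df[bad] = np.nan, np.nan, np.nan
    return diff, se, df


def _pooled_parts(a: np.ndarray, b: np.ndarray):
    """Classical equal-variance (pooled) two-sample pieces."""
    n1 = np.sum(np.isfinite(a), axis=1).astype(float)
    n2 = np.sum(np.isfinite(b), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    bad = (n1 < 2) | (n2 < 2)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    diff[bad], se[bad], df[bad] = np.nan, np.nan, np.nan
    return diff, se, df


def _right_tail_p(diff: np.ndarray, se: np.ndarray, df: np.ndarray) -> tuple:
    """(t, right-tail p) with degenerate se handled explicitly."""
    t = np.full_like(diff, np.nan)
    p = np.full_like(diff, np.nan)
    ok = np.isfinite(diff) & np.isfinite(se)
    pos_se = ok & (se > 0)
    t[pos_se] = diff[pos_se] / se[pos_se]
    p[pos_se] = stats.t.sf(t[pos_se], df[pos_se])
    zero_se = ok & (se == 0)
    t[zero_se & (diff > 0)] = np.inf
    p[zero_se & (diff > 0)] = 0.0
    t[zero_se & (diff < 0)] = -np.inf
    p[zero_se & (diff < 0)] = 1.0
    t[zero_se & (diff == 0)] = 0.0
    p[zero_se & (diff == 0)] = 0.5
    return t, p


def right_tailed_ttest(
    matrix: IntensityMatrix,
    condition: str,
    control: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Right-tailed two-sample t-test of ``condition`` against ``control``.

    diff = mean(condition) − mean(control); the right-tail probability, so a
    positive diff (enrichment in the bait condition) gives small p. Welch by
    default; ``equal_var=True`` selects the pooled-variance form. Proteins
    with fewer than two values in either group are skipped (NaN row) with a
    logged count.
    """
    a = matrix.values[matrix.condition_columns(condition)].to_numpy()
    b = matrix.values[matrix.condition_columns(control)].to_numpy()
    parts = _pooled_parts if equal_var else _welch_parts
    diff, se, df = parts(a, b)
    t, p = _right_tail_p(diff, se, df)
    n_skip = int(np.isnan(p).sum())
    if n_skip:
        logger.info("right_tailed_ttest(%s vs %s): %d proteins skipped "
                    "(<2 values in a group)", condition, control, n_skip)
    return pd.DataFrame(
        {"diff": diff, "se": se, "df": df, "t_stat": t, "p_value": p},
        index=matrix.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through untouched and excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_differential(
    results: pd.DataFrame, fold_change: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the fold-change and adjusted-P gates to a t-test result table.

    Adds ``q_value``, ``neg_log10_p`` and ``significant_bh`` columns; a
    protein is called when diff > log2(fold_change) and q < alpha.
    """
    out = results.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out["significant_bh"] = (
        (out["diff"] > np.log2(fold_change)) & (out["q_value"] < alpha)
    ).fillna(False)
    return out


def significant_set(results: pd.DataFrame) -> set[str]:
    """Identifiers called significant by the BH branch."""
    return set(results.index[results["significant_bh"].astype(bool)])


def s0_statistic(diff, pooled_spread, s0: float) -> np.ndarray:
    """SAM-style moderated statistic d = diff / (spread + s0).

    ``pooled_spread`` is the standard error of the difference; adding the
    artificial within-group variance term s0 keeps near-zero-variance
    proteins from dominating. Entries with spread + s0 == 0 are undefined
    (NaN).
    """
    diff = np.asarray(diff, dtype=float)
    denom = np.asarray(pooled_spread, dtype=float) + float(s0)
    if float(s0) < 0 or (np.asarray(pooled_spread) < 0).any():
        raise DataError("pooled_spread and s0 must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, np.nan)
    return d


@dataclass
class PermutationFDRResult:
    threshold: float                 # smallest d threshold achieving target FDR
    significant: list[str]           # observed d >= threshold and diff > 0
    fdr_curve: pd.DataFrame          # candidate threshold -> estimated FDR
    cutoff_curve: pd.DataFrame       # (diff, neg_log10_p) locus of d = threshold
    stats: pd.DataFrame              # per-protein diff, se, d, p


def estimate_fdr(d_obs: np.ndarray, d_perm: np.ndarray, candidates: np.ndarray,
                 aggregate: str = "mean") -> np.ndarray:
    """Estimated FDR at each candidate threshold.

    FDR(c) = (average over permutations of #{permuted d >= c}) divided by
    #{observed d >= c}. ``aggregate`` may be "mean" (default) or "median".
    """
    d_obs = np.sort(d_obs[np.isfinite(d_obs)])
    exceed = np.stack([
        row.size - np.searchsorted(row, candidates, side="left")
        for row in (np.sort(r[np.isfinite(r)]) for r in d_perm)
    ])  # n_perm x n_candidates
    agg = np.mean(exceed, axis=0) if aggregate == "mean" else np.median(exceed, axis=0)
    obs = (d_obs.size - np.searchsorted(d_obs, candidates, side="left")).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs > 0, agg / obs, np.inf)
    return fdr


def permutation_fdr(
    matrix: IntensityMatrix,
    condition: str,
    control: str,
    s0: float = 0.1,
    target_fdr: float = 0.1,
    n_randomisations: int = 250,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
    equal_var: bool = False,
    aggregate: str = "mean",
) -> PermutationFDRResult:
    """SAM-style permutation FDR for one condition-vs-control comparison.

    Columns of the two groups are pooled and relabelled into groups of the
    original sizes; the d statistic is recomputed for every relabelling.
    The significance threshold is the smallest observed candidate d at which
    the estimated FDR drops to ``target_fdr`` or below; significant proteins
    have observed d at or above it and a positive t-test difference. With
    ``exhaustive=True`` every distinct relabelling is enumerated instead of
    sampling (identity included), which on a 3-vs-3 comparison gives all
    C(6,3) = 20 relabelings.

    When no threshold achieves the target FDR the significant set is empty
    and the threshold is +inf.
    """
    cond_cols = matrix.condition_columns(condition)
    ctrl_cols = matrix.condition_columns(control)
    pool = matrix.values[cond_cols + ctrl_cols].to_numpy()
    n1, n = len(cond_cols), len(cond_cols) + len(ctrl_cols)
    parts = _pooled_parts if equal_var else _welch_parts

    diff, se, df = parts(pool[:, :n1], pool[:, n1:])
    t, p = _right_tail_p(diff, se, df)
    d_obs = s0_statistic(diff, se, s0)

    if exhaustive:
        labelings = [np.array(c) for c in combinations(range(n), n1)]
    else:
        rng = np.random.default_rng(seed)
        labelings = [rng.permutation(n)[:n1] for _ in range(n_randomisations)]

    d_perm = np.empty((len(labelings), pool.shape[0]))
    all_idx = np.arange(n)
    for b, grp1 in enumerate(labelings):
        grp2 = np.setdiff1d(all_idx, grp1)
        pd_, pse, _ = parts(pool[:, grp1], pool[:, grp2])
        d_perm[b] = s0_statistic(pd_, pse, s0)

    finite_pos = d_obs[np.isfinite(d_obs) & (d_obs > 0)]
    candidates = np.unique(finite_pos)
    if candidates.size == 0:
        fdr = np.array([])
    else:
        fdr = estimate_fdr(d_obs, d_perm, candidates, aggregate=aggregate)

    passing = np.flatnonzero(fdr <= target_fdr)
    if passing.size:
        threshold = float(candidates[passing[0]])
    else:
        threshold = float("inf")

    sig_mask = np.isfinite(d_obs) & (d_obs >= threshold) & (diff > 0)
    significant = list(matrix.values.index[sig_mask])

    stats_df = pd.DataFrame(
        {"diff": diff, "se": se, "df": df, "t_stat": t, "p_value": p,
         "d_stat": d_obs, "significant_perm": sig_mask},
        index=matrix.values.index,
    )
    fdr_df = pd.DataFrame({"threshold": candidates, "est_fdr": fdr})
    cutoff = _cutoff_curve(threshold, s0, df)
    return PermutationFDRResult(threshold, significant, fdr_df, cutoff, stats_df)


def _cutoff_curve(threshold: float, s0: float, df: np.ndarray,
                  n_points: int = 200, max_diff: float = 10.0) -> pd.DataFrame:
    """Locus of the cutoff d = threshold in volcano (diff, −log10 p) space.

    Along the curve the implied standard error is diff/threshold − s0
    (positive only for diff > threshold·s0); p is the right tail of t =
    diff/se at the median residual df of the comparison.
    """
    if not np.isfinite(threshold):
        return pd.DataFrame({"diff": [], "neg_log10_p": []})
    dfm = float(np.nanmedian(df)) if np.isfinite(np.nanmedian(df)) else 4.0
    lo = threshold * s0 * (1 + 1e-9)
    diffs = np.linspace(lo + 1e-6, max_diff, n_points)
    se = diffs / threshold - s0
    tvals = diffs / se
    p = stats.t.sf(tvals, dfm)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame({"diff": diffs, "neg_log10_p": nlp})
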