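"""Missing-value imputation for left-censored LFQ data.

Two schemes are provided, mirroring the two parallel analyses downstream:

* :func:`impute_downshift` — per-column Gaussian draws centred
  ``downshift`` column-sds below the observed column mean with width
  ``width`` column-sds (the Perseus-style MNAR imputation; defaults 0.3 /
  1.8). Feeds the volcano / permutation-FDR branch.
* :func:`impute_lognormal` — per (protein, condition) draws from a
  log-normal whose log-scale location is the mean of the observed
  within-condition replicates; feeds the regression branch.

Observed cells are never touched: imputation fills NaNs only and records
provenance in ``imputed_mask``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import IntensityMatrix

#: Floor applied to any estimated spread so degenerate (constant) columns or
#: conditions still yield non-identical draws.
SD_FLOOR = 0.01


def impute_downshift(
    matrix: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> IntensityMatrix:
    """Impute each column's missing cells from a down-shifted Gaussian.

    For a column with observed mean m and sd s, missing cells are drawn
    independently from Normal(m − downshift·s, (width·s)²). Columns with
    fewer than 2 observed values fall back to the whole-matrix observed
    mean/sd with a warning; zero sds are floored at :data:`SD_FLOOR`.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values.to_numpy()
    obs_all = vals[~np.isnan(vals)]
    if obs_all.size < 2:
        raise DataError("matrix has fewer than 2 observed values in total")
    pooled_mean, pooled_sd = float(obs_all.mean()), float(obs_all.std(ddof=1))

    imputed = out.imputed_mask.to_numpy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size < 2:
            warnings.warn(
                f"column {out.values.columns[j]!r} has {obs.size} observed "
                "values; falling back to pooled matrix mean/sd",
                stacklevel=2,
            )
            m, s = pooled_mean, pooled_sd
        else:
            m, s = float(obs.mean()), float(obs.std(ddof=1))
        s = max(s, SD_FLOOR)
        col[miss] = rng.normal(m - downshift * s, width * s, size=int(miss.sum()))
        imputed[miss, j] = True

    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.imputed_mask = pd.DataFrame(imputed, index=out.values.index,
                                    columns=out.values.columns)
    return out


def _pooled_within_sd(vals: np.ndarray) -> float:
    """Root-mean-square of per-row sds (rows with >=2 observed values)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = (~np.isnan(vals)).sum(axis=1)
        sds = np.nanstd(vals, axis=1, ddof=1)
    sds = sds[(counts >= 2) & np.isfinite(sds)]
    if sds.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(sds**2)))


def impute_lognormal(
    matrix: IntensityMatrix,
    seed: int | np.random.Generator = 0,
    per_protein: bool = True,
) -> IntensityMatrix:
    """Impute from a log-normal fitted to same-condition replicates.

    A log-normal on the raw scale is a Gaussian on the log scale, so draws
    are made (and stored) directly in log2 units. With ``per_protein=True``
    (default) the log-scale location is the mean of the protein's observed
    values within the condition; the spread falls back through
    (1) the protein-within-condition sd when >=3 values are observed,
    (2) the condition-level pooled within-protein sd,
    (3) the whole-matrix pooled within-protein sd.
    With ``per_protein=False`` the location and spread are the condition's
    grand mean and sd over all proteins.

    A (protein, condition) cell with no observed same-condition value falls
    back to the protein's overall observed mean with the whole-matrix pooled
    spread (warned); a protein with no observed value anywhere is an error.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values.to_numpy()
    imputed = out.imputed_mask.to_numpy()

    if np.isnan(vals).all(axis=1).any():
        bad = out.values.index[np.isnan(vals).all(axis=1)].tolist()
        raise DataError(
            f"proteins with no observed value anywhere cannot be imputed: {bad[:5]}"
        )

    global_sd = _pooled_within_sd(vals)
    if not np.isfinite(global_sd):
        global_sd = float(np.nanstd(vals, ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        protein_mean = np.nanmean(vals, axis=1)

    cond_of = out.design.set_index("run_id")["condition_label"]
    col_cond = cond_of.loc[out.values.columns].to_numpy()
    n_fallback_loc = 0

    for label in out.condition_labels():
        cols = np.flatnonzero(col_cond == label)
        block = vals[:, cols]
        miss = np.isnan(block)
        if not miss.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            loc = np.nanmean(block, axis=1)
            own_sd = np.nanstd(block, axis=1, ddof=1)
        n_obs = (~miss).sum(axis=1)
        cond_sd = _pooled_within_sd(block)
        if not np.isfinite(cond_sd):
            cond_sd = global_sd

        if per_protein:
            spread = np.where((n_obs >= 3) & np.isfinite(own_sd), own_sd, cond_sd)
            location = loc
        else:
            obs_block = block[~miss]
            location = np.full(len(block), float(obs_block.mean()))
            spread = np.full(len(block), float(obs_block.std(ddof=1)))

        no_obs = n_obs == 0
        if no_obs.any():
            n_fallback_loc += int(no_obs.sum())
            location = np.where(no_obs, protein_mean, location)
            spread = np.where(no_obs, global_sd, spread)
        spread = np.maximum(spread, SD_FLOOR)

        rows, sub = np.nonzero(miss)
        draws = rng.normal(location[rows], spread[rows])
        block[rows, sub] = draws
        vals[:, cols] = block
        imputed[rows, cols[sub]] = True

    if n_fallback_loc:
        warnings.warn(
            f"{n_fallback_loc} (protein, condition) cells had no observed "
            "same-condition value; fell back to the protein's overall mean",
            stacklevel=2,
        )

    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.imputed_mask = pd.DataFrame(imputed, index=out.values.index,
                                    columns=out.values.columns)
    return out
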