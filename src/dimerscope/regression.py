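"""Per-protein linear model of log-LFQ on the one-hot design factors.

Each protein's (fully imputed) log2 LFQ profile across runs is regressed on
an intercept plus the five binary factors (brafwt, v600e, dimerizer,
sorafenib, vemurafenib). Coefficients are tested against zero with t-tests
(two-sided), adjusted per coefficient across proteins by Benjamini–Hochberg,
and arbitrary contrast vectors c yield estimates c'β with se² = c'Σc. The
sign convention follows the interactome usage: a positive contrast means the
first-named variable increases the protein's log-LFQ more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import FACTORS
from .errors import ConfigurationError, DataError
from .matrix import IntensityMatrix
from .differential import bh_adjust

DESIGN_MATRIX_COLUMNS = ("intercept", *FACTORS)

#: Named contrasts for the study's comparison families: mutant vs wild-type
#: BRAF, sorafenib vs vemurafenib, and the dimerizer (monomer->dimer) effect.
CONTRAST_PRESETS: dict[str, np.ndarray] = {
    "v600e_minus_brafwt": np.array([0.0, -1.0, 1.0, 0.0, 0.0, 0.0]),
    "sorafenib_minus_vemurafenib": np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0]),
    "dimerizer": np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0]),
}


def build_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """One-hot design matrix: intercept column plus the five binary factors.

    Raises :class:`ConfigurationError` naming the offending column when the
    matrix is rank-deficient over the supplied runs (e.g. a factor constant
    across all runs).
    """
    X = pd.DataFrame({"intercept": np.ones(len(design))}, index=design["run_id"])
    for f in FACTORS:
        X[f] = design[f].to_numpy(dtype=float)
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        for f in FACTORS:
            if design[f].nunique() < 2:
                raise ConfigurationError(
                    f"design is rank deficient: factor {f!r} is constant"
                )
        raise ConfigurationError("design matrix is rank deficient")
    return X


@dataclass
class RegressionFit:
    """Per-protein OLS results sharing one design matrix.

    ``beta`` and ``se`` are proteins × coefficients; ``sigma2`` is the
    residual variance (RSS / df_resid) and ``xtx_inv`` the shared (X'X)⁻¹,
    so a protein's coefficient covariance is sigma2 · xtx_inv.
    """

    X: pd.DataFrame
    beta: pd.DataFrame
    se: pd.DataFrame
    sigma2: pd.Series
    xtx_inv: np.ndarray
    df_resid: int
    r2: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.beta.index)

    def cov(self, protein_id: str) -> pd.DataFrame:
        c = float(self.sigma2.loc[protein_id]) * self.xtx_inv
        return pd.DataFrame(c, index=self.columns, columns=self.columns)


def fit_ols(matrix: IntensityMatrix, X: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares per protein.

    The matrix must be fully imputed and its columns aligned with the rows
    of ``X``. Residual variance is RSS/df with df = n_runs − n_columns;
    coefficient covariance is sigma² (X'X)⁻¹.
    """
    matrix.require_complete("fit_ols")
    if list(X.index) != matrix.run_ids:
        if set(X.index) != set(matrix.run_ids):
            raise DataError("design matrix rows do not match matrix runs")
        X = X.loc[matrix.run_ids]
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    df_resid = n - p
    if df_resid <= 0:
        raise DataError(f"non-positive residual df: {n} runs, {p} columns")

    Y = matrix.values.to_numpy(dtype=float).T  # runs x proteins
    beta, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < p:
        raise ConfigurationError("design matrix is rank deficient")
    resid = Y - A @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, np.nan)
        r2 = np.clip(r2, 0.0, 1.0)

    idx = matrix.values.index
    cols = list(X.columns)
    return RegressionFit(
        X=X,
        beta=pd.DataFrame(beta.T, index=idx, columns=cols),
        se=pd.DataFrame(se, index=idx, columns=cols),
        sigma2=pd.Series(sigma2, index=idx),
        xtx_inv=xtx_inv,
        df_resid=df_resid,
        r2=pd.Series(r2, index=idx),
    )


def _t_and_p(estimate: np.ndarray, se: np.ndarray, df: int):
    """Two-sided t-test pieces with explicit zero-se handling."""
    t = np.full_like(estimate, np.nan)
    p = np.full_like(estimate, np.nan)
    degenerate = se == 0
    ok = ~degenerate & np.isfinite(se)
    t[ok] = estimate[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    t[degenerate & (estimate > 0)] = np.inf
    t[degenerate & (estimate < 0)] = -np.inf
    t[degenerate & (estimate == 0)] = 0.0
    p[degenerate] = np.where(estimate[degenerate] == 0, 1.0, 0.0)
    return t, p, degenerate


def coefficient_tests(fit: RegressionFit) -> pd.DataFrame:
    """t-tests of every coefficient against zero, BH-adjusted per coefficient.

    Returns a long table (protein, coefficient, estimate, se, t, p, q,
    degenerate); the q-values are adjusted across proteins within each
    coefficient, not pooled over coefficients.
    """
    frames = []
    for col in fit.columns:
        est = fit.beta[col].to_numpy()
        se = fit.se[col].to_numpy()
        t, p, degen = _t_and_p(est, se, fit.df_resid)
        frames.append(pd.DataFrame({
            "protein": fit.protein_ids,
            "coefficient": col,
            "estimate": est,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "degenerate": degen,
        }))
    return pd.concat(frames, ignore_index=True)


def contrast(fit: RegressionFit, c, name: str | None = None) -> pd.DataFrame:
    """Linear contrast c'β per protein with t-test and BH adjustment.

    ``c`` is a vector over the design columns (or a preset name from
    :data:`CONTRAST_PRESETS`). estimate = c'β, se = sqrt(c' Σ c) with
    Σ = sigma² (X'X)⁻¹; ``sign`` is the sign of the estimate (+1 means the
    positively weighted variable increases log-LFQ more).
    """
    if isinstance(c, str):
        name = name or c
        if c not in CONTRAST_PRESETS:
            raise ConfigurationError(
                f"unknown contrast preset {c!r}; available: "
                f"{sorted(CONTRAST_PRESETS)}"
            )
        c = CONTRAST_PRESETS[c]
    c = np.asarray(c, dtype=float)
    if c.shape != (len(fit.columns),):
        raise ConfigurationError(
            f"contrast length {c.shape} does not match design columns "
            f"({len(fit.columns)})"
        )
    est = fit.beta.to_numpy() @ c
    quad = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2.to_numpy() * quad)
    t, p, degen = _t_and_p(est, se, fit.df_resid)
    return pd.DataFrame(
        {
            "contrast": name or "custom",
            "estimate": est,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "sign": np.sign(est).astype(int),
            "degenerate": degen,
        },
        index=pd.Index(fit.protein_ids, name="protein"),
    )


def predict_log_lfq(fit: RegressionFit, X: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predicted log2 LFQ per protein and run (X·β), proteins × runs."""
    if X is None:
        X = fit.X
    if list(X.columns) != fit.columns:
        raise ConfigurationError("prediction design columns do not match fit")
    pred = X.to_numpy(dtype=float) @ fit.beta.to_numpy().T  # runs x proteins
    return pd.DataFrame(pred.T, index=fit.beta.index, columns=X.index)


def measured_vs_predicted(matrix: IntensityMatrix, fit: RegressionFit) -> pd.DataFrame:
    """Long paired table of measured and predicted log-LFQ for plotting."""
    pred = predict_log_lfq(fit)
    meas = matrix.values
    long = meas.stack().rename("measured").to_frame()
    long["predicted"] = pred.stack()
    long.index.names = ["protein", "run_id"]
    out = long.reset_index()
    cond = matrix.design.set_index("run_id")["condition_label"]
    out["condition_label"] = cond.loc[out["run_id"]].to_numpy()
    return out
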