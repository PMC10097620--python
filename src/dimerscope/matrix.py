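"""Log2 intensity matrix with explicit missingness and imputation provenance.

The container keeps three aligned pieces of state: the values (proteins x
runs, log2 LFQ, NaN where no value exists yet), a boolean mask of cells that
were filled by imputation, and the run-level design table. Observed cells
are never modified by any pipeline stage; imputation only ever fills NaNs
and records having done so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import validate_design
from .errors import DataError


@dataclass
class IntensityMatrix:
    values: pd.DataFrame          # proteins x runs, log2 scale, NaN = missing
    design: pd.DataFrame          # one row per run, aligned to values.columns
    imputed_mask: pd.DataFrame | None = None  # bool, same shape as values

    def __post_init__(self):
        validate_design(self.design)
        run_order = list(self.design["run_id"])
        if list(self.values.columns) != run_order:
            if set(self.values.columns) != set(run_order):
                raise DataError("matrix columns and design run_ids disagree")
            self.values = self.values[run_order]
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            if self.imputed_mask.shape != self.values.shape:
                raise DataError("imputed_mask shape mismatch")
            self.imputed_mask = self.imputed_mask.reindex(
                index=self.values.index, columns=self.values.columns
            ).astype(bool)
        if (self.values.isna() & self.imputed_mask).any().any():
            raise DataError("a cell cannot be both missing and imputed")

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where no observed value exists and no imputation has occurred."""
        return self.values.isna()

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_of(self, run_id: str) -> str:
        row = self.design.loc[self.design["run_id"] == run_id]
        return row["condition_label"].iloc[0]

    def condition_columns(self, label: str) -> list[str]:
        cols = self.design.loc[
            self.design["condition_label"] == label, "run_id"
        ].tolist()
        if not cols:
            raise DataError(f"condition {label!r} not present in design")
        return cols

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.design["condition_label"]:
            if lab not in seen:
                seen.append(lab)
        return seen

    def subset_rows(self, keep: pd.Index | list[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[keep].copy(),
            self.design.copy(),
            self.imputed_mask.loc[keep].copy(),
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.design.copy(), self.imputed_mask.copy()
        )

    def require_complete(self, context: str = "this operation") -> None:
        n_nan = int(self.values.isna().sum().sum())
        if n_nan:
            raise DataError(
                f"{context} requires a fully imputed matrix; {n_nan} cells missing"
            )


def save_matrix(matrix: IntensityMatrix, prefix) -> None:
    """Write a matrix as a TSV trio: values, imputed mask, design."""
    matrix.values.to_csv(f"{prefix}.values.tsv", sep="\t", float_format="%.10g",
                         index_label="protein")
    matrix.imputed_mask.astype(int).to_csv(
        f"{prefix}.imputed.tsv", sep="\t", index_label="protein"
    )
    matrix.design.to_csv(f"{prefix}.design.tsv", sep="\t", index=False)


def load_matrix(prefix) -> IntensityMatrix:
    values = pd.read_csv(f"{prefix}.values.tsv", sep="\t", index_col="protein")
    imputed = pd.read_csv(f"{prefix}.imputed.tsv", sep="\t", index_col="protein")
    design = pd.read_csv(f"{prefix}.design.tsv", sep="\t")
    return IntensityMatrix(values, design, imputed.astype(bool))
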