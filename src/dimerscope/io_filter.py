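"""Reading proteinGroups tables and applying the category and valid-value filters.

The filtering stages mirror the standard Perseus treatment of MaxQuant
output: drop decoy categories (only-identified-by-site, reverse,
contaminant), log2-transform with zeros becoming missing values, keep
proteins with at least ``min_valid`` observed values in at least one
condition, and discard proteins whose missingness exceeds the per-condition
threshold in every condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import validate_design
from .errors import ConfigurationError, DataError, SchemaError
from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "

#: Canonical flag names -> accepted header spellings. "Contaminant" is the
#: MaxQuant 1.3-era header; later versions write "Potential contaminant".
CATEGORY_ALIASES = {
    "only_site": ("Only identified by site", "Only Identified by site"),
    "reverse": ("Reverse",),
    "contaminant": ("Contaminant", "Potential contaminant"),
}


@dataclass
class ProteinGroupsTable:
    """A parsed proteinGroups-dialect table.

    ``data`` keeps the original columns; ``flags`` holds the three decoy
    categories as 0/1 integers under canonical names; ``lfq_columns`` lists
    the per-run intensity columns in file order.
    """

    data: pd.DataFrame
    lfq_columns: list[str]
    flags: pd.DataFrame

    @property
    def run_ids(self) -> list[str]:
        return [c[len(LFQ_PREFIX):] for c in self.lfq_columns]

    def __len__(self) -> int:
        return len(self.data)


def _parse_flags(df: pd.DataFrame) -> pd.DataFrame:
    flags = pd.DataFrame(index=df.index)
    for canonical, spellings in CATEGORY_ALIASES.items():
        col = next((s for s in spellings if s in df.columns), None)
        if col is None:
            logger.warning("category column %s absent; assuming no flagged rows",
                           spellings[0])
            flags[canonical] = 0
        else:
            flags[canonical] = (df[col].fillna("").astype(str).str.strip() == "+").astype(int)
    return flags


def from_dataframe(df: pd.DataFrame) -> ProteinGroupsTable:
    """Wrap an in-memory proteinGroups-dialect DataFrame."""
    if "Protein IDs" not in df.columns:
        raise SchemaError("mandatory column 'Protein IDs' is absent")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise SchemaError(f"no '{LFQ_PREFIX}<run>' columns found")
    df = df.copy()
    for c in lfq_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return ProteinGroupsTable(df, lfq_cols, _parse_flags(df))


def read_proteingroups(path) -> ProteinGroupsTable:
    """Read a tab-separated proteinGroups-dialect file.

    Raises :class:`SchemaError` naming the absent column when the mandatory
    ``Protein IDs`` column or all LFQ columns are missing. Both
    ``Contaminant`` and ``Potential contaminant`` headers are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    for c in lfq_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    for col in ("Only identified by site", "Only Identified by site", "Reverse",
                "Contaminant", "Potential contaminant"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return from_dataframe(df)


def filter_categories(table: ProteinGroupsTable) -> ProteinGroupsTable:
    """Remove rows flagged only-identified-by-site, reverse or contaminant.

    A row flagged in several categories is removed once; surviving rows are
    untouched. Removal counts are logged per category and as a union.
    """
    union = table.flags.any(axis=1)
    for canonical in table.flags.columns:
        logger.info("filter_categories: %d rows flagged %s",
                    int(table.flags[canonical].sum()), canonical)
    logger.info("filter_categories: removing %d of %d rows (union of flags)",
                int(union.sum()), len(table))
    keep = ~union
    return ProteinGroupsTable(
        table.data.loc[keep].copy(),
        table.lfq_columns,
        table.flags.loc[keep].copy(),
    )


def log2_transform(table: ProteinGroupsTable, design: pd.DataFrame) -> IntensityMatrix:
    """Log2-transform LFQ intensities; zeros become missing values.

    The log of an LFQ intensity of zero is not a valid value and is stored
    as NaN. Negative intensities violate the raw-scale precondition.
    """
    validate_design(design)
    raw = table.data[table.lfq_columns].to_numpy(dtype=float)
    if np.nanmin(raw) < 0:
        raise DataError("negative LFQ intensity encountered")
    with np.errstate(divide="ignore"):
        values = np.log2(raw)
    values[~np.isfinite(values)] = np.nan

    ids = table.data["Protein IDs"].astype(str)
    if ids.duplicated().any():
        raise DataError("duplicate Protein IDs; cannot index the matrix")
    run_ids = table.run_ids
    missing_runs = set(run_ids) - set(design["run_id"])
    if missing_runs:
        raise DataError(f"runs absent from design table: {sorted(missing_runs)}")
    design = design.set_index("run_id").loc[run_ids].reset_index()
    values_df = pd.DataFrame(values, index=pd.Index(ids, name="protein"),
                             columns=run_ids)
    return IntensityMatrix(values_df, design)


def _observed_per_condition(matrix: IntensityMatrix) -> pd.DataFrame:
    """Count observed (non-missing) cells per protein per condition."""
    observed = (~matrix.values.isna()).astype(int)
    cond = matrix.design.set_index("run_id")["condition_label"]
    return observed.T.groupby(cond.loc[observed.columns].values).sum().T


def _condition_sizes(matrix: IntensityMatrix) -> pd.Series:
    return matrix.design.groupby("condition_label")["run_id"].count()


def filter_min_valid(matrix: IntensityMatrix, min_valid: int) -> IntensityMatrix:
    """Keep proteins with >= ``min_valid`` observed values in >= 1 condition."""
    sizes = _condition_sizes(matrix)
    if min_valid > sizes.max():
        raise ConfigurationError(
            f"min_valid={min_valid} exceeds the largest condition size {sizes.max()}"
        )
    counts = _observed_per_condition(matrix)
    keep = (counts >= min_valid).any(axis=1)
    logger.info("filter_min_valid: %d of %d proteins retained",
                int(keep.sum()), len(keep))
    return matrix.subset_rows(matrix.values.index[keep.to_numpy()])


def filter_max_missing(
    matrix: IntensityMatrix,
    max_missing_per_condition: int,
    quantifier: str = "every",
) -> IntensityMatrix:
    """Discard proteins whose missing count exceeds the threshold per condition.

    With ``quantifier="every"`` (default) a protein is discarded only when
    every condition has more than ``max_missing_per_condition`` missing
    values among its runs — the most permissive reading of the discard rule.
    ``quantifier="any"`` discards as soon as one condition exceeds it.
    """
    if quantifier not in ("every", "any"):
        raise ConfigurationError("quantifier must be 'every' or 'any'")
    counts = _observed_per_condition(matrix)
    sizes = _condition_sizes(matrix).reindex(counts.columns)
    missing = sizes.to_numpy()[None, :] - counts.to_numpy()
    exceeds = missing > max_missing_per_condition
    discard = exceeds.all(axis=1) if quantifier == "every" else exceeds.any(axis=1)
    logger.info("filter_max_missing(%s, >%d): %d of %d proteins discarded",
                quantifier, max_missing_per_condition, int(discard.sum()),
                len(discard))
    return matrix.subset_rows(matrix.values.index[~discard])


def collapse_technical_replicates(matrix: IntensityMatrix) -> IntensityMatrix:
    """Average technical replicates into one column per biological replicate.

    The collapsed cell is the mean of the observed log2 values; it is
    missing only when every technical replicate is missing. A collapsed cell
    is marked imputed when any contributing cell was imputed. Collapsed
    design rows carry ``tech_rep = 0``.
    """
    design = matrix.design
    key = list(zip(design["condition_label"], design["bio_rep"]))
    groups: dict[tuple, list[str]] = {}
    for run, k in zip(design["run_id"], key):
        groups.setdefault(k, []).append(run)

    new_cols, new_rows = {}, []
    new_imp = {}
    for (label, bio), runs in groups.items():
        first = design.loc[design["run_id"] == runs[0]].iloc[0]
        slug = runs[0].rsplit("_t", 1)[0]
        new_id = slug if slug.endswith(f"_b{bio}") else f"{label}_b{bio}"
        new_cols[new_id] = matrix.values[runs].mean(axis=1, skipna=True)
        new_imp[new_id] = matrix.imputed_mask[runs].any(axis=1) & new_cols[new_id].notna()
        new_rows.append({**{c: first[c] for c in design.columns},
                         "run_id": new_id, "tech_rep": 0})

    values = pd.DataFrame(new_cols)
    values.index = matrix.values.index
    imputed = pd.DataFrame(new_imp)
    imputed.index = matrix.values.index
    new_design = pd.DataFrame(new_rows, columns=list(design.columns))
    return IntensityMatrix(values, new_design, imputed)
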