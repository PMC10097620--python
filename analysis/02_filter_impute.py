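#!/usr/bin/env python
"""Filter the proteinGroups table and impute missing values.

Applies the standard treatment: drop decoy categories, log2-transform with
zero -> missing, keep proteins with >=3 valid values in at least one
condition, discard proteins with >2 missing values in every condition, then
average the technical replicates of each biological replicate. Both
imputation schemes are produced: per-column downshift draws (width 0.3,
shift 1.8) for the volcano branch, and condition-wise log-normal draws for
the differential-call and regression branches.
"""

from pathlib import Path

from dimerscope.design import read_design
from dimerscope.imputation import impute_downshift, impute_lognormal
from dimerscope.io_filter import (collapse_technical_replicates,
                                  filter_categories, filter_max_missing,
                                  filter_min_valid, log2_transform,
                                  read_proteingroups)
from dimerscope.matrix import save_matrix
from dimerscope.params import AnalysisParams

ROOT = Path(__file__).resolve().parents[1] / "results"
PARAMS = AnalysisParams(seed=0)


def main():
    out = ROOT / "matrices"
    out.mkdir(parents=True, exist_ok=True)
    seeds = PARAMS.stage_seeds()

    table = read_proteingroups(ROOT / "data" / "proteingroups.tsv")
    design = read_design(ROOT / "data" / "design.tsv")
    n0 = len(table)
    table = filter_categories(table)
    print(f"category filter: {n0} -> {len(table)} rows")

    m = log2_transform(table, design)
    print(f"missing after log2: {int(m.missing_mask.sum().sum())} cells")
    m = filter_min_valid(m, PARAMS.min_valid)
    m = filter_max_missing(m, PARAMS.max_missing_per_condition)
    print(f"valid-value filters: {len(m.values)} proteins retained")
    m = collapse_technical_replicates(m)
    print(f"collapsed to {len(m.run_ids)} biological-replicate columns")
    save_matrix(m, out / "filtered")

    m_down = impute_downshift(m, PARAMS.width, PARAMS.downshift,
                              seed=seeds["downshift"])
    m_logn = impute_lognormal(m, seed=seeds["lognormal"])
    save_matrix(m_down, out / "downshift")
    save_matrix(m_logn, out / "lognormal")
    print(f"imputed {int(m_logn.imputed_mask.sum().sum())} cells per scheme; "
          f"matrices under {out}")


if __name__ == "__main__":
    main()
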