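#!/usr/bin/env python
"""Call differential interactors per condition against its matched control.

Runs both branches for each of the 12 bait conditions: the BH branch
(right-tailed t-test on the log-normal-imputed matrix, fold change > 1.5,
adjusted P < 0.05) and the permutation branch (d = diff/(se + s0) with
s0 = 0.1, FDR 0.1, 250 randomisations, on the downshift-imputed matrix).
Because the data are simulated, calls are scored against the ground truth:
a call is "true" when the protein carries a nonzero coefficient on any
factor distinguishing the condition from its control.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dimerscope.design import DEFAULT_COMPARISONS, FACTORS
from dimerscope.differential import (call_differential, permutation_fdr,
                                     right_tailed_ttest)
from dimerscope.matrix import load_matrix
from dimerscope.params import AnalysisParams

ROOT = Path(__file__).resolve().parents[1] / "results"
PARAMS = AnalysisParams(seed=0)


def _true_interactors(comparison, truth, design):
    """Proteins whose factor effects differ between condition and control."""
    cond, ctl = comparison
    rows = design.drop_duplicates("condition_label").set_index("condition_label")
    delta = (rows.loc[cond, list(FACTORS)].to_numpy(float)
             - rows.loc[ctl, list(FACTORS)].to_numpy(float))
    beta = truth[[f"beta_{f}" for f in FACTORS]].to_numpy()
    effect = beta @ delta
    return set(truth.loc[effect > 0, "protein_id"])


def main():
    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    seeds = PARAMS.stage_seeds()
    m_logn = load_matrix(ROOT / "matrices" / "lognormal")
    m_down = load_matrix(ROOT / "matrices" / "downshift")
    truth = pd.read_csv(ROOT / "data" / "ground.truth.tsv", sep="\t")

    summary = []
    for cond, ctl in DEFAULT_COMPARISONS:
        res = call_differential(right_tailed_ttest(m_logn, cond, ctl),
                                PARAMS.fold_change, PARAMS.alpha)
        perm = permutation_fdr(m_down, cond, ctl, s0=PARAMS.s0,
                               target_fdr=PARAMS.target_fdr,
                               n_randomisations=PARAMS.n_randomisations,
                               seed=seeds["permutation"])
        slug = cond.replace(" + ", "_").replace("/", "").lower()
        res.to_csv(out / f"bh_{slug}.tsv", sep="\t", float_format="%.10g",
                   index_label="protein")
        perm.stats.to_csv(out / f"volcano_{slug}.tsv", sep="\t",
                          float_format="%.10g", index_label="protein")
        perm.cutoff_curve.to_csv(out / f"cutoff_{slug}.tsv", sep="\t",
                                 float_format="%.10g", index=False)

        called = set(res.index[res["significant_bh"]])
        enriched = _true_interactors((cond, ctl), truth, m_logn.design)
        tp = len(called & enriched)
        summary.append({
            "condition": cond, "control": ctl,
            "bh_calls": len(called), "bh_true": tp,
            "perm_calls": len(perm.significant),
            "perm_true": len(set(perm.significant) & enriched),
            "truly_enriched": len(enriched),
        })
    df = pd.DataFrame(summary)
    df.to_csv(out / "summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nBH branch: {df.bh_calls.sum()} calls, "
          f"{df.bh_true.sum()} true ({df.bh_true.sum() / max(df.bh_calls.sum(), 1):.0%} precision)")
    print(f"permutation branch: {df.perm_calls.sum()} calls, "
          f"{df.perm_true.sum()} true")
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
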