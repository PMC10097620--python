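#!/usr/bin/env python
"""PCA quality control, interactor-overlap matrix, and reference comparison.

Projects the imputed samples onto principal components, flags runs far from
their condition centroid, builds the condition-by-condition interactor
overlap matrix (n/d dialect: numerator = shared interactors, denominator =
the row condition's interactor count) from the BH-branch calls, and
intersects the pooled interactor set with a reference identifier list. The
reference here is synthetic — a list assembled from the simulation's own
ground-truth interactors plus unrelated identifiers — standing in for an
externally curated PPI export.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dimerscope.design import DEFAULT_COMPARISONS
from dimerscope.matrix import load_matrix
from dimerscope.qc import compare_reference, flag_outliers, overlap_matrix, run_pca

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    m = load_matrix(ROOT / "matrices" / "lognormal")

    pca = run_pca(m)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g",
                      index_label="run_id")
    flagged = flag_outliers(pca.scores, m.design, k_sd=4.0)
    (out / "pca_outliers.txt").write_text("\n".join(flagged) + "\n"
                                          if flagged else "")
    evr = pca.explained_variance_ratio
    print(f"PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance; "
          f"{len(flagged)} runs flagged as outliers")

    sets = {}
    for cond, _ in DEFAULT_COMPARISONS:
        slug = cond.replace(" + ", "_").replace("/", "").lower()
        tab = pd.read_csv(ROOT / "differential" / f"bh_{slug}.tsv", sep="\t",
                          index_col="protein")
        sets[cond] = set(tab.index[tab["significant_bh"]])
    mat = overlap_matrix(sets)
    mat.to_strings().to_csv(out / "overlap_matrix.tsv", sep="\t",
                            index_label="condition")
    mat.to_long().to_csv(out / "overlap_long.tsv", sep="\t", index=False)
    diag = {c: mat.entry(c, c)[0] for c in mat.labels}
    print("interactors per condition:", diag)

    # synthetic reference list: half of the true interactors + distractors
    truth = pd.read_csv(ROOT / "data" / "ground.truth.tsv", sep="\t")
    beta_cols = [c for c in truth.columns if c.startswith("beta_")]
    hits = truth.loc[(truth[beta_cols] != 0).any(axis=1), "protein_id"].tolist()
    rng = np.random.default_rng(0)
    reference = sorted(rng.choice(hits, size=len(hits) // 2, replace=False))
    reference += [f"X{i:04d}" for i in range(40)]
    (out / "reference_synthetic.txt").write_text(
        "# synthetic reference interactor list (from simulation ground truth)\n"
        + "\n".join(reference) + "\n")

    union = set().union(*sets.values())
    report = compare_reference(union, reference)
    print(f"reference comparison: {report['n_overlap']} of {report['n_set']} "
          f"called interactors appear among {report['n_reference']} reference ids")
    pd.DataFrame({"shared": report["shared"]}).to_csv(
        out / "reference_overlap.tsv", sep="\t", index=False)
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
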