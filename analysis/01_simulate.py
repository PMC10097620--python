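#!/usr/bin/env python
"""Generate the synthetic AP-MS study.

Emulates the dimerizer study's layout — 16 conditions (4 controls; BRAF wt
and V600E each crossed with {none, sorafenib, vemurafenib} x {+/- A/C}),
3 biological x 2 technical replicates — with 600 prey proteins, ~15% true
interactors (1-3 log2-unit effects), and intensity-dependent left-censoring.
Writes the proteinGroups-dialect table, the run design, and the ground-truth
sidecars under results/data/.
"""

from pathlib import Path

import numpy as np

from dimerscope.design import generate_design, write_design
from dimerscope.synthetic import (default_ground_truth, simulate_lfq,
                                  write_proteingroups, write_ground_truth)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = generate_design(n_bio=3, n_tech=2)
    truth = default_ground_truth(n_proteins=600, frac_interactors=0.15,
                                 seed=SEED)
    dataset = simulate_lfq(design, truth, seed=SEED)

    write_proteingroups(dataset.table, OUT / "proteingroups.tsv")
    write_design(design, OUT / "design.tsv")
    write_ground_truth(truth, OUT / "ground")

    lfq = dataset.table.filter(like="LFQ intensity").to_numpy()
    n_interactors = int((truth.beta != 0).any(axis=1).sum())
    print(f"runs: {len(design)} (16 conditions x 3 bio x 2 tech)")
    print(f"rows: {len(dataset.table)} "
          f"({truth.n_proteins} preys + "
          f"{len(dataset.table) - truth.n_proteins} decoys)")
    print(f"true interactors: {n_interactors}")
    print(f"censored cells (preys): {100 * np.mean(lfq[:truth.n_proteins] == 0):.1f}%")
    print(f"wrote {OUT}/proteingroups.tsv, design.tsv, ground.truth.tsv")


if __name__ == "__main__":
    main()
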