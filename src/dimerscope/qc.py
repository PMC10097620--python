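"""Principal-component QC, outlier flagging, and interactor-set overlap.

The PCA operates on the fully imputed sample × protein matrix and is the
basis for flagging aberrant runs (e.g. a failed pulldown replicate) before
the analyst confirms their removal. Overlap matrices report, for every
ordered pair of conditions, how many of the row condition's interactors are
also found in the column condition, in the n/d dialect where the denominator
is the row's interactor count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataError
from .matrix import IntensityMatrix

#: Rayleigh median factor: for 2-D isotropic Gaussian scatter the median
#: centroid distance is sigma * sqrt(2 ln 2); dividing by it gives a robust
#: sigma estimate from the pooled distances.
_RAYLEIGH_MEDIAN = float(np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PCAResult:
    scores: pd.DataFrame                 # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # proteins x components


def run_pca(matrix: IntensityMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the samples in protein-intensity space (centered, unscaled).

    Deterministic up to component sign. Requires a fully imputed matrix and
    at least two samples.
    """
    matrix.require_complete("run_pca")
    X = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    k = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.run_ids, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=matrix.protein_ids,
                              columns=comp_names),
    )


def flag_outliers(
    scores: pd.DataFrame, design: pd.DataFrame, k_sd: float = 4.0
) -> list[str]:
    """Flag samples far from their condition centroid in the PC1/PC2 plane.

    Each sample's distance to its own condition centroid is compared with a
    robust scale (the pooled median distance divided by the Rayleigh median
    factor); samples beyond ``k_sd`` robust standard deviations are flagged.
    Flagging only — removal is a separate, explicit action by the analyst.
    """
    pcs = scores[["PC1", "PC2"]]
    cond = design.set_index("run_id")["condition_label"].loc[pcs.index]
    centroids = pcs.groupby(cond.values).mean()
    dist = np.sqrt(
        ((pcs.to_numpy() - centroids.loc[cond.values].to_numpy()) ** 2).sum(axis=1)
    )
    robust_sd = float(np.median(dist)) / _RAYLEIGH_MEDIAN
    if robust_sd == 0:
        return []
    flagged = pcs.index[dist > k_sd * robust_sd]
    return list(flagged)


@dataclass
class OverlapMatrix:
    """Condition × condition interactor overlaps with n/d semantics.

    ``numerator[i, j]`` = |S_i ∩ S_j| and the denominator of row i is
    |S_i|, so the diagonal reads |S_i|/|S_i| and numerators are symmetric.
    """

    labels: list[str]
    numerator: pd.DataFrame   # int, labels x labels
    sizes: pd.Series          # |S_i| per label

    def entry(self, row: str, col: str) -> tuple[int, int]:
        return int(self.numerator.loc[row, col]), int(self.sizes.loc[row])

    def to_strings(self) -> pd.DataFrame:
        out = self.numerator.astype(str).copy()
        for row in self.labels:
            d = int(self.sizes.loc[row])
            out.loc[row] = [f"{int(n)}/{d}" for n in self.numerator.loc[row]]
        return out

    def to_long(self) -> pd.DataFrame:
        rows = []
        for r in self.labels:
            for c in self.labels:
                rows.append({
                    "row": r, "column": c,
                    "numerator": int(self.numerator.loc[r, c]),
                    "denominator": int(self.sizes.loc[r]),
                })
        return pd.DataFrame(rows)


def overlap_matrix(interactor_sets: dict[str, set | list]) -> OverlapMatrix:
    """Pairwise overlap counts between per-condition interactor sets.

    Duplicate identifiers within a set are deduplicated with a warning.
    """
    sets: dict[str, set] = {}
    for label, members in interactor_sets.items():
        members = list(members)
        dedup = set(members)
        if len(dedup) < len(members):
            warnings.warn(f"duplicate identifiers in set {label!r}; deduplicated",
                          stacklevel=2)
        sets[label] = dedup
    labels = list(sets)
    num = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for r in labels:
        for c in labels:
            num.loc[r, c] = len(sets[r] & sets[c])
    sizes = pd.Series({lab: len(sets[lab]) for lab in labels})
    return OverlapMatrix(labels, num, sizes)


def compare_reference(interactor_set, reference_list) -> dict:
    """Overlap of an interactor set with an externally supplied reference.

    The reference is a local list of identifiers (for example interactions
    curated for the same cell line in a PPI database export); no network
    access is involved.
    """
    ours = set(interactor_set)
    ref = set(reference_list)
    if not ref:
        warnings.warn("reference list is empty; overlap is trivially empty",
                      stacklevel=2)
    shared = sorted(ours & ref)
    return {
        "n_set": len(ours),
        "n_reference": len(ref),
        "n_overlap": len(shared),
        "shared": shared,
    }


def read_identifier_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]
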