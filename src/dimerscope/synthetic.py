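"""Synthetic AP-MS LFQ data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: each protein's latent log2 LFQ intensity is an additive linear
function of the five one-hot design factors, plus a biological-replicate
random effect shared by the two technical replicates of the same pulldown
and independent technical noise. Cells are then left-censored with a
logistic probability curve in latent intensity — the missing-not-at-random
dropout of low-abundance peptides — and censored cells surface as raw LFQ
intensity 0, exactly as MaxQuant reports them. Decoy rows (contaminants,
reversed-database hits, only-identified-by-site entries) are appended so
the category filter has something to remove.

Output is written in the MaxQuant proteinGroups.txt dialect so the entire
pipeline runs end-to-end without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import FACTORS
from .errors import DataError

_SLOPE_EPS = 1e-8

#: Column order of the emitted proteinGroups dialect (before LFQ columns).
ANNOTATION_COLUMNS = [
    "Protein IDs",
    "Majority protein IDs",
    "Protein names",
    "Gene names",
    "Unique peptides",
    "Sequence coverage [%]",
    "Mol. weight [kDa]",
    "Only identified by site",
    "Reverse",
    "Contaminant",
]


@dataclass
class GroundTruth:
    """True generative parameters of one synthetic study.

    ``beta`` holds, per protein, one log2-intensity coefficient for each of
    the five design factors; a nonzero entry makes the protein a
    condition-specific interactor. ``censor_midpoint`` is the latent log2
    intensity at which the dropout probability is 0.5 and ``censor_slope``
    the logistic scale of the dropout curve (smaller = sharper detection
    limit).
    """

    protein_ids: list[str]
    baseline: np.ndarray              # (n,) log2 units
    beta: np.ndarray                  # (n, len(FACTORS)) log2 units
    sigma_bio: float = 0.3
    sigma_tech: float = 0.15
    censor_midpoint: float = 23.0
    censor_slope: float = 0.8
    n_contaminant: int = 30
    n_reverse: int = 15
    n_onlysite: int = 15

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.protein_ids)
        if self.baseline.shape != (n,):
            raise DataError("baseline must have one entry per protein")
        if self.beta.shape != (n, len(FACTORS)):
            raise DataError(
                f"beta must be (n_proteins, {len(FACTORS)}); got {self.beta.shape}"
            )
        if self.sigma_bio < 0 or self.sigma_tech < 0 or self.censor_slope < 0:
            raise DataError("noise sds and censor_slope must be >= 0")
        if min(self.n_contaminant, self.n_reverse, self.n_onlysite) < 0:
            raise DataError("decoy counts must be >= 0")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def scalars(self) -> dict:
        return {
            "sigma_bio": self.sigma_bio,
            "sigma_tech": self.sigma_tech,
            "censor_midpoint": self.censor_midpoint,
            "censor_slope": self.censor_slope,
            "n_contaminant": self.n_contaminant,
            "n_reverse": self.n_reverse,
            "n_onlysite": self.n_onlysite,
        }


def default_ground_truth(
    n_proteins: int = 600,
    frac_interactors: float = 0.15,
    effect_range: tuple[float, float] = (1.0, 3.0),
    seed: int | np.random.Generator = 0,
    **overrides,
) -> GroundTruth:
    """Build the default study ground truth.

    600 prey proteins with baseline log2 intensities ~ N(26, 2^2) (the bulk
    of an LFQ dynamic range), ~15% of them carrying a nonzero coefficient of
    1-3 log2 units on at least one design factor (mostly enrichments, a
    minority depletions), so that differential calling at 3 biological
    replicates has non-trivial power without being saturated. Replicate
    noise defaults (sigma_bio 0.3, sigma_tech 0.15 log2 units, i.e. ~11-23%
    CV) reflect tight technical re-injections nested in looser biological
    pulldown replicates.
    """
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    baseline = rng.normal(26.0, 2.0, n_proteins)
    beta = np.zeros((n_proteins, len(FACTORS)))
    n_hits = int(round(frac_interactors * n_proteins))
    hit_idx = rng.choice(n_proteins, size=n_hits, replace=False)
    lo, hi = effect_range
    for i in hit_idx:
        k = rng.integers(1, 3)  # 1 or 2 affected factors per interactor
        factors = rng.choice(len(FACTORS), size=k, replace=False)
        for j in factors:
            sign = 1.0 if rng.random() < 0.8 else -1.0
            beta[i, j] = sign * rng.uniform(lo, hi)
    return GroundTruth(ids, baseline, beta, **overrides)


@dataclass
class SimulatedDataset:
    """A simulated study: the proteinGroups-dialect table plus ground truth
    bookkeeping (latent intensities and the censoring mask, preys only)."""

    table: pd.DataFrame           # proteinGroups dialect incl. decoy rows
    design: pd.DataFrame
    truth: GroundTruth
    latent: pd.DataFrame          # proteins x runs, log2, pre-censoring
    censor_mask: pd.DataFrame     # bool, True where the cell was censored


def simulate_lfq(
    design: pd.DataFrame, truth: GroundTruth, seed: int | np.random.Generator
) -> SimulatedDataset:
    """Simulate raw LFQ intensities for every run in ``design``.

    latent = baseline + X·beta + bio effect (shared across technical
    replicates of the same biological replicate) + technical noise;
    P(censored) = expit((censor_midpoint − latent) / max(censor_slope, 1e-8));
    censored cells are recorded as raw intensity 0. Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(seed)
    X = design[list(FACTORS)].to_numpy(dtype=float)      # runs x 5
    if X.shape[1] != truth.beta.shape[1]:
        raise DataError("design factor dimension does not match truth.beta")
    n, r = truth.n_proteins, len(design)

    latent = truth.baseline[:, None] + truth.beta @ X.T  # n x runs

    # biological replicate effect, nested: one draw per (condition, bio rep)
    bio_key = design["condition_label"].astype(str) + "//" + design["bio_rep"].astype(str)
    group_ids, group_idx = np.unique(bio_key.to_numpy(), return_inverse=True)
    bio_eff = rng.normal(0.0, truth.sigma_bio, size=(n, len(group_ids)))
    latent = latent + bio_eff[:, group_idx]
    latent = latent + rng.normal(0.0, truth.sigma_tech, size=(n, r))

    p_censor = expit(
        (truth.censor_midpoint - latent) / max(truth.censor_slope, _SLOPE_EPS)
    )
    censored = rng.random(size=latent.shape) < p_censor
    raw = np.exp2(latent)
    raw[censored] = 0.0

    run_ids = list(design["run_id"])
    latent_df = pd.DataFrame(latent, index=truth.protein_ids, columns=run_ids)
    censor_df = pd.DataFrame(censored, index=truth.protein_ids, columns=run_ids)

    # decoy rows: same baseline intensity distribution, category flag set
    decoys = [
        ("CON__C", truth.n_contaminant, "Contaminant"),
        ("REV__R", truth.n_reverse, "Reverse"),
        ("SITE__S", truth.n_onlysite, "Only identified by site"),
    ]
    decoy_ids, decoy_flags = [], {}
    decoy_raw = []
    base_mu, base_sd = float(np.mean(truth.baseline)), float(np.std(truth.baseline))
    for prefix, count, column in decoys:
        for k in range(count):
            pid = f"{prefix}{k:03d}"
            decoy_ids.append(pid)
            decoy_flags[pid] = column
            lat = rng.normal(base_mu, max(base_sd, 1e-8), size=r)
            p = expit((truth.censor_midpoint - lat) / max(truth.censor_slope, _SLOPE_EPS))
            vals = np.exp2(lat)
            vals[rng.random(size=r) < p] = 0.0
            decoy_raw.append(vals)

    all_ids = list(truth.protein_ids) + decoy_ids
    all_raw = np.vstack([raw] + [np.asarray(decoy_raw)]) if decoy_raw else raw

    table = pd.DataFrame({"Protein IDs": all_ids})
    table["Majority protein IDs"] = all_ids
    table["Protein names"] = [f"Protein {pid}" for pid in all_ids]
    table["Gene names"] = [f"GENE{pid}" for pid in all_ids]
    table["Unique peptides"] = rng.integers(1, 40, size=len(all_ids))
    table["Sequence coverage [%]"] = np.round(rng.uniform(1, 80, size=len(all_ids)), 1)
    table["Mol. weight [kDa]"] = np.round(rng.uniform(10, 300, size=len(all_ids)), 2)
    for col in ("Only identified by site", "Reverse", "Contaminant"):
        table[col] = ["+" if decoy_flags.get(pid) == col else "" for pid in all_ids]
    lfq = pd.DataFrame(all_raw, columns=[f"LFQ intensity {r}" for r in run_ids])
    table = pd.concat([table, lfq], axis=1)

    return SimulatedDataset(table, design.copy(), truth, latent_df, censor_df)


def write_proteingroups(table: pd.DataFrame, path) -> None:
    """Write a proteinGroups-dialect table (tab-separated, UTF-8).

    Category flags are "+" for flagged rows and the empty string otherwise;
    LFQ columns are named ``LFQ intensity <run_id>``.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"table is missing proteinGroups columns: {missing}")
    table.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 encoding="utf-8")


def write_ground_truth(truth: GroundTruth, prefix) -> None:
    """Sidecar files for test harnesses: per-protein table + scalar JSON."""
    per_protein = pd.DataFrame(
        {"protein_id": truth.protein_ids, "baseline": truth.baseline}
    )
    for j, name in enumerate(FACTORS):
        per_protein[f"beta_{name}"] = truth.beta[:, j]
    per_protein.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False,
                       float_format="%.10g")
    with open(f"{prefix}.truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth.scalars(), fh, indent=2, sort_keys=True)
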