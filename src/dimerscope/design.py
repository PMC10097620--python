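"""Experimental layout of the dimerizer AP-MS study.

The study measures the RAF1 interactome under 16 conditions: four controls
(empty vector; the bare FRB+FKBP dimerization-domain pair, alone and with
each RAF inhibitor) and twelve bait conditions crossing the co-transfected
BRAF construct (wild type or V600E, each with RAF1) with drug treatment
(none, sorafenib, vemurafenib) and the A/C heterodimerizer (absent/present).
All four control conditions received the A/C drug. Every condition was run
as 3 biological replicates with 2 technical replicates each (96 MS runs).

Each run is described by five binary one-hot factors used downstream by the
regression model: ``brafwt``, ``v600e``, ``dimerizer``, ``sorafenib``,
``vemurafenib``.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from .errors import DataError

#: One-hot design factors, in canonical order.
FACTORS = ("brafwt", "v600e", "dimerizer", "sorafenib", "vemurafenib")


class Condition(NamedTuple):
    label: str
    slug: str
    brafwt: int
    v600e: int
    dimerizer: int
    sorafenib: int
    vemurafenib: int


#: The 16 study conditions. Labels for the bait conditions follow the
#: condition naming used in the interactor-overlap table ("BRAF + S + A/C"
#: etc.); controls are the empty vector and the FRB+FKBP domain pair.
CONDITIONS: tuple[Condition, ...] = (
    Condition("EV + A/C", "ev_ac", 0, 0, 1, 0, 0),
    Condition("FRB+FKBP + A/C", "frbfkbp_ac", 0, 0, 1, 0, 0),
    Condition("FRB+FKBP + S + A/C", "frbfkbp_s_ac", 0, 0, 1, 1, 0),
    Condition("FRB+FKBP + V + A/C", "frbfkbp_v_ac", 0, 0, 1, 0, 1),
    Condition("BRAF", "braf", 1, 0, 0, 0, 0),
    Condition("BRAF + A/C", "braf_ac", 1, 0, 1, 0, 0),
    Condition("BRAF + S", "braf_s", 1, 0, 0, 1, 0),
    Condition("BRAF + S + A/C", "braf_s_ac", 1, 0, 1, 1, 0),
    Condition("BRAF + V", "braf_v", 1, 0, 0, 0, 1),
    Condition("BRAF + V + A/C", "braf_v_ac", 1, 0, 1, 0, 1),
    Condition("V600E", "v600e", 0, 1, 0, 0, 0),
    Condition("V600E + A/C", "v600e_ac", 0, 1, 1, 0, 0),
    Condition("V600E + S", "v600e_s", 0, 1, 0, 1, 0),
    Condition("V600E + S + A/C", "v600e_s_ac", 0, 1, 1, 1, 0),
    Condition("V600E + V", "v600e_v", 0, 1, 0, 0, 1),
    Condition("V600E + V + A/C", "v600e_v_ac", 0, 1, 1, 0, 1),
)

CONTROL_LABELS = tuple(c.label for c in CONDITIONS[:4])

#: Default condition-vs-control pairing for differential tests: each bait
#: condition is compared with the FRB+FKBP control carrying the same drug.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = tuple(
    (c.label, {0: "FRB+FKBP + A/C",
               1: "FRB+FKBP + S + A/C"}[c.sorafenib]
     if not c.vemurafenib else "FRB+FKBP + V + A/C")
    for c in CONDITIONS[4:]
)

DESIGN_COLUMNS = ["run_id", "condition_label", *FACTORS, "bio_rep", "tech_rep"]


def generate_design(n_bio: int = 3, n_tech: int = 2) -> pd.DataFrame:
    """Enumerate one MS run per (condition, biological rep, technical rep).

    Parameters
    ----------
    n_bio, n_tech : int
        Number of biological and technical replicates per condition.

    Returns
    -------
    pandas.DataFrame
        One row per run with columns :data:`DESIGN_COLUMNS`. The study's
        own layout is ``generate_design(3, 2)`` → 96 runs.
    """
    if n_bio < 1 or n_tech < 1:
        raise DataError("n_bio and n_tech must both be >= 1")
    rows = []
    for cond in CONDITIONS:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append(
                    {
                        "run_id": f"{cond.slug}_b{b}_t{t}",
                        "condition_label": cond.label,
                        "brafwt": cond.brafwt,
                        "v600e": cond.v600e,
                        "dimerizer": cond.dimerizer,
                        "sorafenib": cond.sorafenib,
                        "vemurafenib": cond.vemurafenib,
                        "bio_rep": b,
                        "tech_rep": t,
                    }
                )
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check the SampleDesign invariants, raising :class:`DataError` on failure."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DataError(f"design table missing columns: {missing}")
    if ((design["brafwt"] == 1) & (design["v600e"] == 1)).any():
        raise DataError("brafwt and v600e must never both be 1")
    if ((design["sorafenib"] == 1) & (design["vemurafenib"] == 1)).any():
        raise DataError("sorafenib and vemurafenib must never both be 1")
    triple = design[["condition_label", "bio_rep", "tech_rep"]]
    if triple.duplicated().any():
        raise DataError("(condition_label, bio_rep, tech_rep) triples must be unique")
    if design["run_id"].duplicated().any():
        raise DataError("run_id values must be unique")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    validate_design(design)
    return design


def condition_runs(design: pd.DataFrame, label: str) -> list[str]:
    """Run ids belonging to one condition, in design order."""
    runs = design.loc[design["condition_label"] == label, "run_id"].tolist()
    if not runs:
        raise DataError(f"condition {label!r} not present in design")
    return runs
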