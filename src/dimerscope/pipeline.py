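"""End-to-end pipeline: acquire → filter → impute → test → regress → QC.

A single :class:`PipelineConfig` (constructable from a YAML file) drives the
whole analysis; every stage writes its tabular output under the configured
output directory and the run ends with a manifest recording parameters,
derived stage seeds, and per-stage row counts. Identical config + seed gives
byte-identical result tables.

Stage layout mirrors the published workflow: the downshift-imputed matrix
feeds the volcano / permutation-FDR branch, the log-normal-imputed matrix
feeds the BH differential calls and the regression, and PCA-based QC flags
(but does not remove) outlier runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (DEFAULT_COMPARISONS, generate_design, read_design,
                     write_design)
from .differential import (call_differential, permutation_fdr,
                           right_tailed_ttest, significant_set)
from .errors import PipelineError
from .imputation import impute_downshift, impute_lognormal
from .io_filter import (collapse_technical_replicates, filter_categories,
                        filter_max_missing, filter_min_valid, log2_transform,
                        read_proteingroups)
from .matrix import IntensityMatrix, save_matrix
from .params import AnalysisParams
from .qc import compare_reference, flag_outliers, overlap_matrix, run_pca, \
    read_identifier_list
from .regression import (CONTRAST_PRESETS, build_design_matrix,
                         coefficient_tests, contrast, fit_ols,
                         measured_vs_predicted)
from .synthetic import (default_ground_truth, simulate_lfq, write_proteingroups,
                        write_ground_truth)
from .io_filter import from_dataframe

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class SimulationConfig:
    n_proteins: int = 600
    frac_interactors: float = 0.15
    n_bio: int = 3
    n_tech: int = 2
    truth_overrides: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis once, reproducibly.

    Exactly one of (``proteingroups`` + ``design``) or ``simulate`` must be
    set. ``comparisons`` defaults to each bait condition against its
    drug-matched FRB+FKBP control; ``contrasts`` defaults to the three
    preset comparison families.
    """

    outdir: Path
    proteingroups: Path | None = None
    design: Path | None = None
    simulate: SimulationConfig | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    collapse_technical: bool = True
    differential_method: str = "bh"       # "bh" or "perm" (overlap-set source)
    lognormal_per_protein: bool = True
    comparisons: list[tuple[str, str]] | None = None
    contrasts: list[str] = field(default_factory=lambda: list(CONTRAST_PRESETS))
    reference_list: Path | None = None
    max_missing_quantifier: str = "every"

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        has_files = self.proteingroups is not None and self.design is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise PipelineError(
                "config", "input_choice",
                "exactly one of (proteingroups+design) or simulate must be set",
            )
        if self.differential_method not in ("bh", "perm"):
            raise PipelineError("config", "method",
                                "differential_method must be 'bh' or 'perm'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "params" in raw:
            raw["params"] = AnalysisParams(**raw["params"])
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "comparisons" in raw and raw["comparisons"] is not None:
            raw["comparisons"] = [tuple(pair) for pair in raw["comparisons"]]
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    differential: dict[str, pd.DataFrame]
    permutation: dict
    fit: object
    contrasts: dict[str, pd.DataFrame]
    overlap: object
    outliers: list[str]


def _write(df: pd.DataFrame, path: Path, index: bool = True,
           index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index,
              index_label=index_label)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Raises :class:`PipelineError` carrying the stage name and a machine
    readable code on failure; configuration problems (unknown conditions or
    contrasts) are detected before any computation starts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    seeds = params.stage_seeds()
    manifest: dict = {
        "package_version": __version__,
        "params": params.to_dict(),
        "stage_seeds": seeds,
        "collapse_technical": config.collapse_technical,
        "differential_method": config.differential_method,
        "counts": {},
    }

    # ---- acquire ---------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        design = generate_design(sim.n_bio, sim.n_tech)
        truth = default_ground_truth(
            sim.n_proteins, sim.frac_interactors,
            seed=seeds["simulate"], **sim.truth_overrides,
        )
        dataset = simulate_lfq(design, truth, seed=seeds["simulate"])
        write_proteingroups(dataset.table, out / "proteingroups.tsv")
        write_design(design, out / "design.tsv")
        write_ground_truth(truth, out / "ground")
        table = from_dataframe(dataset.table)
    else:
        try:
            table = read_proteingroups(config.proteingroups)
            design = read_design(config.design)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError("acquire", "read_failed", str(exc)) from exc

    # fail fast on unknown conditions/contrasts before heavy computation
    labels = set(design["condition_label"])
    comparisons = config.comparisons or [
        (c, ctl) for c, ctl in DEFAULT_COMPARISONS if c in labels and ctl in labels
    ]
    for cond, ctl in comparisons:
        for lab in (cond, ctl):
            if lab not in labels:
                raise PipelineError("config", "unknown_condition",
                                    f"condition {lab!r} not in the design")
    for name in config.contrasts:
        if name not in CONTRAST_PRESETS:
            raise PipelineError("config", "unknown_contrast",
                                f"contrast {name!r} has no preset")

    manifest["counts"]["rows_input"] = len(table)

    # ---- filter ----------------------------------------------------------
    table = filter_categories(table)
    manifest["counts"]["rows_after_category_filter"] = len(table)
    matrix = log2_transform(table, design)
    matrix = filter_min_valid(matrix, params.min_valid)
    manifest["counts"]["proteins_after_min_valid"] = len(matrix.values)
    matrix = filter_max_missing(matrix, params.max_missing_per_condition,
                                quantifier=config.max_missing_quantifier)
    manifest["counts"]["proteins_after_max_missing"] = len(matrix.values)
    if config.collapse_technical:
        matrix = collapse_technical_replicates(matrix)
    save_matrix(matrix, out / "matrix_filtered")

    # ---- impute ----------------------------------------------------------
    m_down = impute_downshift(matrix, params.width, params.downshift,
                              seed=seeds["downshift"])
    m_logn = impute_lognormal(matrix, seed=seeds["lognormal"],
                              per_protein=config.lognormal_per_protein)
    manifest["counts"]["cells_imputed"] = int(m_logn.imputed_mask.sum().sum())
    save_matrix(m_down, out / "matrix_downshift")
    save_matrix(m_logn, out / "matrix_lognormal")

    # ---- QC --------------------------------------------------------------
    pca = run_pca(m_logn)
    _write(pca.scores, out / "pca_scores.tsv", index_label="run_id")
    pd.DataFrame({"component": pca.scores.columns,
                  "explained_variance_ratio": pca.explained_variance_ratio}
                 ).to_csv(out / "pca_variance.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
    outliers = flag_outliers(pca.scores, m_logn.design)
    (out / "pca_outliers.txt").write_text("\n".join(outliers) + "\n"
                                          if outliers else "")
    manifest["counts"]["pca_outliers_flagged"] = len(outliers)

    # ---- differential ----------------------------------------------------
    differential: dict[str, pd.DataFrame] = {}
    permutation: dict = {}
    interactor_sets: dict[str, set] = {}
    for cond, ctl in comparisons:
        res = call_differential(
            right_tailed_ttest(m_logn, cond, ctl),
            params.fold_change, params.alpha,
        )
        differential[cond] = res
        _write(res, out / f"differential_bh_{_slug(cond)}.tsv",
               index_label="protein")
        perm = permutation_fdr(
            m_down, cond, ctl, s0=params.s0, target_fdr=params.target_fdr,
            n_randomisations=params.n_randomisations,
            seed=seeds["permutation"],
        )
        permutation[cond] = perm
        _write(perm.stats, out / f"volcano_{_slug(cond)}.tsv",
               index_label="protein")
        _write(perm.cutoff_curve, out / f"cutoff_curve_{_slug(cond)}.tsv",
               index=False)
        if config.differential_method == "bh":
            interactor_sets[cond] = significant_set(res)
        else:
            interactor_sets[cond] = set(perm.significant)
    manifest["counts"]["significant_per_comparison"] = {
        c: len(s) for c, s in interactor_sets.items()
    }

    # ---- regression ------------------------------------------------------
    X = build_design_matrix(m_logn.design)
    fit = fit_ols(m_logn, X)
    _write(fit.beta, out / "regression_coefficients.tsv", index_label="protein")
    _write(coefficient_tests(fit), out / "regression_coefficient_tests.tsv",
           index=False)
    contrast_tables: dict[str, pd.DataFrame] = {}
    for name in config.contrasts:
        tab = contrast(fit, name)
        contrast_tables[name] = tab
        _write(tab, out / f"contrast_{name}.tsv", index_label="protein")
    _write(measured_vs_predicted(m_logn, fit),
           out / "measured_vs_predicted.tsv", index=False)

    # ---- overlap ---------------------------------------------------------
    overlap = overlap_matrix(interactor_sets) if interactor_sets else None
    if overlap is not None:
        _write(overlap.to_strings(), out / "overlap_matrix.tsv",
               index_label="condition")
        _write(overlap.to_long(), out / "overlap_long.tsv", index=False)
    if config.reference_list is not None:
        ref = read_identifier_list(config.reference_list)
        union = set().union(*interactor_sets.values()) if interactor_sets else set()
        report = compare_reference(union, ref)
        (out / "reference_overlap.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest["counts"]["reference_overlap"] = report["n_overlap"]

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", out)
    return PipelineResult(out, manifest, differential, permutation, fit,
                          contrast_tables, overlap, outliers)


def _slug(label: str) -> str:
    return (label.replace(" + ", "_").replace("+", "").replace("/", "")
            .replace(" ", "_").lower())
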