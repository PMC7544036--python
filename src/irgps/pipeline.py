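"""End-to-end workflows: fit, score, compare-cells, simulate.

Each workflow is a plain function over in-memory objects (what the tests
and analysis scripts call) plus a ``cmd_*`` wrapper that reads the input
files named in a :class:`RunConfig`, writes tidy outputs into the output
directory and records a machine-readable run record (config hash, seed,
stage counts, versions) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _version
from .compare import abundance_summary, compare_groups, filter_quality
from .io import (
    collapse_duplicates,
    filter_genes,
    read_clinical,
    read_expression,
    read_feature_table,
    read_geneset,
    restrict_to_geneset,
    write_expression,
)
from .pairs import assign_groups, filter_constant_pairs, risk_score, score_pairs
from .roc import optimal_cutoff, timed_roc
from .screen import screen_candidates
from .select import select_signature
from .signature import Signature, read_signature, write_signature
from .simulate import SimulationConfig, simulate_cohort
from .survival import cox_fit, logrank_test, rmst, score_by_mutation, subgroup_analysis

logger = logging.getLogger("irgps")

__all__ = [
    "RunConfig",
    "FitResult",
    "ScoreResult",
    "fit_workflow",
    "score_workflow",
    "compare_cells_workflow",
    "cmd_fit",
    "cmd_score",
    "cmd_compare_cells",
    "cmd_simulate",
]

#: clinical covariates considered for the Cox tables, in reporting order
DEFAULT_COVARIATES = ("age", "gender", "stage", "t_stage", "n_stage", "clark_level")
MUTATION_FLAGS = ("braf_mut", "nras_mut")


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Defaults are the study constants: gene filters mean > 0 and MAD > 0.5,
    pair-identity bound 90%, survival screen at p < 1e-4, 1000 lasso
    cycles at consensus 0.5, ROC horizon 36 months, FDR 0.05.
    """

    expression: str | None = None
    clinical: str | None = None
    genes: str | None = None
    signature: str | None = None
    cell_fractions: str | None = None
    groups: str | None = None
    min_mean: float = 0.0
    min_mad: float = 0.5
    max_identity_fraction: float = 0.90
    screen_alpha: float = 1e-4
    screen_mode: str = "and"
    n_cycles: int = 1000
    selection_fraction: float = 0.5
    roc_horizon: float = 36.0
    fdr: float = 0.05
    quality_p: float = 0.05
    cutoff: float | None = None
    risk_as_group: bool = False
    seed: int = 0
    out: str = "irgps_out"
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.max_identity_fraction <= 1:
            raise ValueError("max_identity_fraction must lie in (0, 1]")
        if not 0 < self.screen_alpha <= 1:
            raise ValueError("screen_alpha must lie in (0, 1]")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must lie in (0, 1]")
        if self.roc_horizon <= 0:
            raise ValueError("roc_horizon must be positive")


@dataclass
class FitResult:
    signature: Signature
    cutoff: float
    scores: pd.Series
    groups: pd.Series
    candidates: pd.DataFrame
    stage_counts: dict[str, int]


@dataclass
class ScoreResult:
    scores: pd.Series
    groups: pd.Series
    logrank: Any
    cox_table: pd.DataFrame
    rmst: dict | None
    subgroups: dict
    mutation_score_tests: dict


def _stage(counts: dict, name: str, value: int) -> None:
    counts[name] = int(value)
    logger.info("stage %-22s -> %d", name, value)


def fit_workflow(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    geneset: set[str] | None = None,
    config: RunConfig | None = None,
) -> FitResult:
    """Full signature construction on one cohort.

    Gene filters -> pair scoring -> near-constant pair removal -> Cox +
    log-rank candidate screen -> consensus-lasso selection -> risk scores
    -> time-dependent-ROC cutoff. Stage counts trace the funnel
    (genes kept, pairs built, pairs after filter, candidates, final pairs).
    """
    config = config or RunConfig()
    config.validate()
    counts: dict[str, int] = {}
    matrix = collapse_duplicates(expression)
    _stage(counts, "genes_input", matrix.shape[0])
    if geneset is not None:
        matrix = restrict_to_geneset(matrix, geneset)
        _stage(counts, "genes_in_geneset", matrix.shape[0])
    matrix = filter_genes(matrix, min_mean=config.min_mean, min_mad=config.min_mad)
    _stage(counts, "genes_filtered", matrix.shape[0])
    common = [s for s in matrix.columns if s in clinical.index]
    if len(common) < matrix.shape[1]:
        logger.info("dropping %d samples without clinical data", matrix.shape[1] - len(common))
        matrix = matrix[common]
    surv = clinical.loc[matrix.columns]

    psm = score_pairs(matrix, "all")
    _stage(counts, "pairs_built", psm.shape[0])
    psm = filter_constant_pairs(psm, config.max_identity_fraction)
    _stage(counts, "pairs_variable", psm.shape[0])
    candidates = screen_candidates(psm, surv, alpha=config.screen_alpha, mode=config.screen_mode)
    _stage(counts, "pairs_candidate", candidates.shape[0])
    if candidates.shape[0] == 0:
        raise ValueError(
            f"screening: no pair survives alpha={config.screen_alpha}; nothing to select from"
        )
    signature = select_signature(
        psm.loc[candidates.index],
        surv,
        n_cycles=config.n_cycles,
        selection_fraction=config.selection_fraction,
        seed=config.seed,
    )
    _stage(counts, "pairs_signature", len(signature))

    scores = risk_score(psm, signature)
    roc = timed_roc(scores, surv, horizon=config.roc_horizon)
    cutoff, _, _ = optimal_cutoff(roc)
    signature.cutoff = cutoff
    groups = assign_groups(scores, cutoff)
    return FitResult(
        signature=signature,
        cutoff=cutoff,
        scores=scores,
        groups=groups,
        candidates=candidates,
        stage_counts=counts,
    )


def _cox_table(
    surv: pd.DataFrame, scores: pd.Series, risk_as_group: bool, cutoff: float
) -> pd.DataFrame:
    """Tidy univariate + multivariate Cox table over the available covariates.

    The risk factor enters as the continuous score by default, or as the
    binary high/low indicator with ``risk_as_group``. Ordinal clinical
    covariates enter as numeric scores.
    """
    if risk_as_group:
        risk = (assign_groups(scores, cutoff) == "high").astype(float).rename("risk_group")
    else:
        risk = scores.rename("risk_score")
    available = [c for c in DEFAULT_COVARIATES if c in surv.columns and surv[c].nunique() > 1]
    rows = []
    for name in [*available, risk.name]:
        cov = risk if name == risk.name else None
        try:
            res = cox_fit(surv, covariates=cov, which=name)
        except (ValueError, KeyError) as exc:
            logger.warning("univariate Cox for %s failed: %s", name, exc)
            continue
        row = res.summary.loc[name]
        rows.append({"variable": name, "analysis": "univariate", **row.to_dict(),
                     "n": res.n, "n_events": res.n_events})
    try:
        multi = cox_fit(surv, covariates=risk.to_frame(), which=[*available, risk.name])
        for name, row in multi.summary.iterrows():
            rows.append({"variable": name, "analysis": "multivariate", **row.to_dict(),
                         "n": multi.n, "n_events": multi.n_events})
    except (ValueError, KeyError) as exc:
        logger.warning("multivariate Cox failed: %s", exc)
    return pd.DataFrame(rows)


def score_workflow(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: Signature,
    config: RunConfig | None = None,
) -> ScoreResult:
    """Apply a signature to a cohort and evaluate the stratification.

    Computes risk scores, assigns groups at the signature (or override)
    cutoff, then runs the log-rank test, restricted-mean survival,
    univariate and multivariate Cox tables, mutation-stratified subgroup
    analyses and mutation-group score comparisons where flags exist.
    A degenerate stratification (single group) reports NA with a warning
    instead of failing.
    """
    config = config or RunConfig()
    matrix = collapse_duplicates(expression)
    missing = sorted(signature.genes - set(matrix.index))
    if missing:
        raise KeyError(f"signature genes missing from the expression matrix: {missing}")
    common = [s for s in matrix.columns if s in clinical.index]
    matrix = matrix[common]
    surv = clinical.loc[common]
    scores = risk_score(matrix, signature)
    cutoff = config.cutoff if config.cutoff is not None else signature.cutoff
    if cutoff is None:
        raise ValueError("no cutoff: the signature carries none and the config sets none")
    groups = assign_groups(scores, cutoff)

    if groups.nunique() < 2:
        logger.warning("all samples fall in the %s-risk group; survival comparisons are NA", groups.iloc[0])
        lr, rm = None, None
    else:
        lr = logrank_test(surv, groups)
        rm = rmst(surv, groups, tau=min(config.roc_horizon, surv["os_time"].max()))
    cox_table = _cox_table(surv, scores, config.risk_as_group, cutoff)
    subgroups = {}
    mutation_tests = {}
    for flag in MUTATION_FLAGS:
        if flag in surv.columns and surv[flag].notna().any() and surv[flag].nunique() > 1:
            subgroups[flag] = subgroup_analysis(surv, scores, cutoff, flag)
            mutation_tests[flag] = score_by_mutation(scores, surv[flag])
    return ScoreResult(
        scores=scores,
        groups=groups,
        logrank=lr,
        cox_table=cox_table,
        rmst=rm,
        subgroups=subgroups,
        mutation_score_tests=mutation_tests,
    )


def compare_cells_workflow(
    table: pd.DataFrame,
    groups: pd.Series,
    config: RunConfig | None = None,
) -> dict:
    """Quality-filter a cell-fraction table and compare it between groups."""
    config = config or RunConfig()
    n_input = table.shape[0]
    if "p_value" in table.columns:
        table = filter_quality(table, config.quality_p)
        logger.info("quality filter: %d -> %d samples", n_input, table.shape[0])
    result = compare_groups(table, groups, fdr_alpha=config.fdr)
    abundant = abundance_summary(table, groups, min_fraction=0.05)
    return {"n_samples": table.shape[0], "comparison": result, "abundant_features": abundant}


# ---------------------------------------------------------------- cmd wrappers


def _run_record(config: RunConfig, stage_counts: dict, outputs: list[str]) -> dict:
    payload = asdict(config)
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    return {
        "config": payload,
        "config_sha256": digest,
        "seed": config.seed,
        "stage_counts": stage_counts,
        "outputs": outputs,
        "versions": {"irgps": _version, "numpy": np.__version__, "pandas": pd.__version__},
    }


def _write_record(record: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "run_record.json"), "w") as handle:
        json.dump(record, handle, indent=2, default=str)


def _load_groups(config: RunConfig, table_index: pd.Index) -> pd.Series:
    if config.groups:
        frame = pd.read_csv(config.groups, sep="\t", index_col=0)
        return frame.iloc[:, 0].astype(str)
    if config.signature:
        signature = read_signature(config.signature)
        expression = read_expression(config.expression)
        scores = risk_score(collapse_duplicates(expression), signature)
        cutoff = config.cutoff if config.cutoff is not None else signature.cutoff
        return assign_groups(scores, cutoff)
    raise ValueError("compare-cells needs either a groups file or a signature (+expression)")


def cmd_fit(config: RunConfig) -> FitResult:
    """fit: expression + clinical (+ gene list) -> signature JSON + cutoff."""
    for required in ("expression", "clinical"):
        if getattr(config, required) is None:
            raise ValueError(f"fit requires --{required}")
    os.makedirs(config.out, exist_ok=True)
    expression = read_expression(config.expression)
    clinical = read_clinical(config.clinical)
    geneset = read_geneset(config.genes) if config.genes else None
    result = fit_workflow(expression, clinical, geneset, config)
    sig_path = os.path.join(config.out, "signature.json")
    write_signature(result.signature, sig_path)
    result.scores.to_frame().join(result.groups).to_csv(os.path.join(config.out, "risk_scores.tsv"), sep="\t")
    result.candidates.to_csv(os.path.join(config.out, "candidates.tsv"), sep="\t")
    record = _run_record(config, result.stage_counts, ["signature.json", "risk_scores.tsv", "candidates.tsv"])
    record["cutoff"] = result.cutoff
    _write_record(record, config.out)
    return result


def cmd_score(config: RunConfig) -> ScoreResult:
    """score: expression + clinical + signature -> stratified survival report."""
    for required in ("expression", "clinical", "signature"):
        if getattr(config, required) is None:
            raise ValueError(f"score requires --{required}")
    os.makedirs(config.out, exist_ok=True)
    expression = read_expression(config.expression)
    clinical = read_clinical(config.clinical)
    signature = read_signature(config.signature)
    result = score_workflow(expression, clinical, signature, config)
    result.scores.to_frame().join(result.groups).to_csv(os.path.join(config.out, "risk_scores.tsv"), sep="\t")
    result.cox_table.to_csv(os.path.join(config.out, "cox_table.tsv"), sep="\t", index=False)
    summary = {
        "n": int(len(result.scores)),
        "n_high": int((result.groups == "high").sum()),
        "n_low": int((result.groups == "low").sum()),
        "logrank_p": None if result.logrank is None else result.logrank.p,
        "logrank_statistic": None if result.logrank is None else result.logrank.statistic,
        "rmst": result.rmst,
        "mutation_score_tests": result.mutation_score_tests,
    }
    with open(os.path.join(config.out, "survival_summary.json"), "w") as handle:
        json.dump(summary, handle, indent=2, default=str)
    record = _run_record(config, {"n_samples": len(result.scores)}, ["risk_scores.tsv", "cox_table.tsv", "survival_summary.json"])
    _write_record(record, config.out)
    return result


def cmd_compare_cells(config: RunConfig) -> dict:
    """compare-cells: fraction table + groups -> Wilcoxon/BH report."""
    if config.cell_fractions is None:
        raise ValueError("compare-cells requires --cell-fractions")
    os.makedirs(config.out, exist_ok=True)
    table = read_feature_table(config.cell_fractions)
    groups = _load_groups(config, table.index)
    result = compare_cells_workflow(table, groups, config)
    result["comparison"].to_csv(os.path.join(config.out, "cell_comparison.tsv"), sep="\t")
    with open(os.path.join(config.out, "abundant_features.json"), "w") as handle:
        json.dump(result["abundant_features"], handle, indent=2)
    record = _run_record(config, {"n_samples": result["n_samples"]}, ["cell_comparison.tsv", "abundant_features.json"])
    _write_record(record, config.out)
    return result


def cmd_simulate(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """simulate: write a synthetic cohort in the dialects the readers accept."""
    os.makedirs(config.out, exist_ok=True)
    sim_config = SimulationConfig(seed=config.seed, **config.sim)
    expression, clinical, truth = simulate_cohort(sim_config)
    write_expression(expression, os.path.join(config.out, "expression.tsv"))
    clinical.to_csv(os.path.join(config.out, "clinical.tsv"), sep="\t")
    truth_json = {k: (v.tolist() if isinstance(v, (np.ndarray, pd.Series)) else v) for k, v in truth.items()}
    with open(os.path.join(config.out, "truth.json"), "w") as handle:
        json.dump(truth_json, handle, indent=2, default=str)
    record = _run_record(config, {"n_samples": sim_config.n_samples, "n_genes": sim_config.n_genes},
                         ["expression.tsv", "clinical.tsv", "truth.json"])
    _write_record(record, config.out)
    return expression, clinical, truth
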