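"""End-to-end analysis: score a cohort, pick a cutoff, test for predictiveness.

``run_pipeline`` composes the library stages on one cohort and produces an
:class:`AnalysisReport` (validated with pydantic, serialized as deterministic
JSON) plus the curve tables a figure-making step would plot. Every stage logs
rows in / rows out, and exclusions (undefined scores, indeterminate benefit
labels) are enumerated in the report rather than silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from . import __version__
from .config import RunConfig
from .cutoff import compare_auc_paired, roc_curve
from .errors import BtmbkitError, ValidationError
from .io import (clinical_to_frame, read_clinical, read_plasma, read_variants,
                 write_results)
from .scoring import classify_dcb, score_cohort
from .stats import chi_square_test, fisher_exact_2x2
from .survival import interaction_analysis, km_estimate, rcs_cox_curve

log = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "PipelineResult", "run_pipeline", "generate_report"]


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class ReportMeta(BaseModel):
    model_config = ConfigDict(extra="forbid")
    config_hash: str
    seed: int
    package_version: str
    n_patients: int
    score_variable: str
    exclusions: dict[str, int]


class CutoffBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: float
    source: Literal["fixed", "derived"]
    derivation_arm: str
    derivation_n: int
    auc_adjusted: float | None
    auc_btmb: float | None
    auc_comparison_p: float | None
    youden_j: float | None
    optimism_note: str


class ContrastBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    table: list[list[int]]  # rows: high, low; cols: yes, no
    rate_high: float | None
    rate_low: float | None
    test: dict


class StratumHR(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int
    n_events: int


class EndpointSurvival(BaseModel):
    model_config = ConfigDict(extra="forbid")
    interaction_p: float
    interaction_coef: float
    cox_terms: dict
    treatment_hr_marker_high: StratumHR
    treatment_hr_marker_low: StratumHR
    km_medians: dict[str, float | None]
    km_n: dict[str, int]


class RCSBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nonlinearity_p: float
    reference_value: float
    knots: list[float]
    n: int
    n_events: int


class SubgroupBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    filter: str
    n: int
    interaction_p_os: float | None
    interaction_p_pfs: float | None
    note: str


class AnalysisReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    meta: ReportMeta
    biomarker_summary: dict
    cutoff: CutoffBlock
    association: dict[str, dict[str, ContrastBlock]]
    survival: dict[str, EndpointSurvival]
    rcs: dict[str, dict[str, RCSBlock]]
    subgroups: dict[str, SubgroupBlock]


@dataclass
class PipelineResult:
    report: AnalysisReport
    biomarker_table: pd.DataFrame
    curves: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _config_hash(cfg: RunConfig) -> str:
    # out_dir does not affect any computed number, so it is not part of the
    # identity; identical analyses hash identically wherever they are written
    payload = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _contrast(high_yes: int, high_no: int, low_yes: int, low_no: int) -> ContrastBlock:
    """2x2 benefit contrast; chi-square unless any expected cell < 5 (then Fisher)."""
    table = np.array([[high_yes, high_no], [low_yes, low_no]])
    n_high, n_low = high_yes + high_no, low_yes + low_no
    total = table.sum()
    use_fisher = True
    if total > 0 and table.sum(axis=0).all() and table.sum(axis=1).all():
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        use_fisher = bool((expected < 5).any())
    test = (fisher_exact_2x2(table) if use_fisher else chi_square_test(table))
    return ContrastBlock(
        table=table.tolist(),
        rate_high=high_yes / n_high if n_high else None,
        rate_low=low_yes / n_low if n_low else None,
        test=test.to_dict(),
    )


def _stratum(fit) -> StratumHR:
    t = fit.term("treatment")
    return StratumHR(hr=t["hr"], ci_lower=t["ci_lower"], ci_upper=t["ci_upper"],
                     p=t["p"], n=fit.n, n_events=fit.n_events)


def _km_cells(df: pd.DataFrame, endpoint: str, curves: dict, prefix: str):
    medians: dict[str, float | None] = {}
    ns: dict[str, int] = {}
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    for arm in ("ICI", "comparator"):
        for grp, gval in (("high", 1), ("low", 0)):
            cell = df[(df["arm"] == arm) & (df["marker"] == gval)]
            key = f"{arm}_{grp}"
            ns[key] = len(cell)
            if len(cell) == 0:
                medians[key] = None
                continue
            curve = km_estimate(cell[tcol], cell[ecol])
            medians[key] = None if np.isnan(curve.median) else float(curve.median)
            curves[f"{prefix}_{endpoint}_{key}"] = curve.to_frame()
    return medians, ns


def run_pipeline(run_config: RunConfig) -> PipelineResult:
    """Execute scoring, cutoff selection, association, survival and RCS stages."""
    cfg = run_config
    policy = cfg.policy()

    clinical = read_clinical(cfg.clinical)
    variants = read_variants(cfg.variants, cfg.variants_format)
    plasma = read_plasma(cfg.plasma)
    log.info("inputs: %d clinical, %d variant calls, %d plasma samples",
             len(clinical), len(variants), len(plasma))

    profiles = score_cohort(clinical, variants, plasma, policy, cfg.panel_size_mb)
    clin_df = clinical_to_frame(clinical)
    for col in ("os_months", "pfs_months", "sum_longest_diameters_mm"):
        clin_df[col] = pd.to_numeric(clin_df[col], errors="coerce")
    for col in ("os_event", "pfs_event"):
        clin_df[col] = clin_df[col].astype(int)
    df = clin_df.merge(profiles, on="patient_id", validate="one_to_one")

    score_col = "adjusted_btmb" if cfg.score_variable == "adjusted_btmb" else "btmb"
    df["score"] = df[score_col]
    df["dcb"] = [classify_dcb(r.pfs_months, bool(r.pfs_event), policy)
                 for r in df.itertuples()]
    df["responder"] = df["best_response"].isin(["CR", "PR"]).astype(int)

    defined = df["score"].notna()
    exclusions = {
        "undefined_score": int((~defined).sum()),
        "indeterminate_dcb": int((df["dcb"] == "indeterminate").sum()),
    }
    log.info("scoring: %d/%d patients with defined %s", defined.sum(), len(df), score_col)

    # ----- cutoff -----
    labelable = defined & df["dcb"].isin(["DCB", "NDB"])
    roc_mask = labelable.copy()
    if cfg.cutoff_arm == "ici":
        roc_mask &= df["arm"] == "ICI"
    if cfg.split_sample_fraction is not None:
        rng = np.random.default_rng(cfg.seed)
        idx = np.flatnonzero(roc_mask.to_numpy())
        perm = rng.permutation(idx)
        n_derive = max(1, int(round(cfg.split_sample_fraction * idx.size)))
        derive_idx = set(perm[:n_derive].tolist())
        roc_mask = pd.Series([i in derive_idx for i in range(len(df))], index=df.index)

    roc_df = df[roc_mask]
    labels = (roc_df["dcb"] == "DCB").astype(int).to_numpy()
    auc_adj = auc_raw = auc_p = youden_j = None
    if cfg.cutoff == "derive":
        roc_adj = roc_curve(roc_df["score"].to_numpy(), labels)
        cutoff_value, youden_j = roc_adj.optimal_cutoff, roc_adj.youden_j
        source = "derived"
        auc_adj = roc_adj.auc
        both_defined = roc_df["btmb"].notna()
        if both_defined.all() and roc_df["adjusted_btmb"].notna().all():
            a, b, p = compare_auc_paired(roc_df["adjusted_btmb"], roc_df["btmb"], labels)
            auc_adj, auc_raw, auc_p = a, b, p
        curves_roc = pd.DataFrame({
            "threshold": roc_adj.thresholds,
            "sensitivity": roc_adj.sensitivity,
            "specificity": roc_adj.specificity,
            "youden_j": roc_adj.sensitivity + roc_adj.specificity - 1.0,
        })
    else:
        cutoff_value = float(cfg.cutoff)
        source = "fixed"
        curves_roc = None
    log.info("cutoff: %s %.4g (arm=%s, n=%d)", source, cutoff_value,
             cfg.cutoff_arm, int(roc_mask.sum()))

    cutoff_block = CutoffBlock(
        value=float(cutoff_value), source=source, derivation_arm=cfg.cutoff_arm,
        derivation_n=int(roc_mask.sum()),
        auc_adjusted=auc_adj, auc_btmb=auc_raw, auc_comparison_p=auc_p,
        youden_j=youden_j,
        optimism_note=("cutoff derived and evaluated on the same cohort; "
                       "estimates are optimistic" if source == "derived"
                       and cfg.split_sample_fraction is None else ""),
    )

    # ----- grouping -----
    adf = df[defined].copy()
    adf["marker"] = (adf["score"] >= cutoff_value).astype(int)
    if adf["marker"].nunique() < 2:
        missing = "high" if adf["marker"].iloc[0] == 0 else "low"
        raise ValidationError(
            f"degenerate cutoff {cutoff_value}: marker-{missing} stratum is empty")

    # ----- association (per arm) -----
    association: dict[str, dict[str, ContrastBlock]] = {}
    for arm in ("ICI", "comparator"):
        sub = adf[adf["arm"] == arm]
        blocks = {}
        dcb_sub = sub[sub["dcb"].isin(["DCB", "NDB"])]
        hi, lo = dcb_sub[dcb_sub["marker"] == 1], dcb_sub[dcb_sub["marker"] == 0]
        blocks["dcb"] = _contrast(int((hi["dcb"] == "DCB").sum()),
                                  int((hi["dcb"] == "NDB").sum()),
                                  int((lo["dcb"] == "DCB").sum()),
                                  int((lo["dcb"] == "NDB").sum()))
        hi, lo = sub[sub["marker"] == 1], sub[sub["marker"] == 0]
        blocks["orr"] = _contrast(int(hi["responder"].sum()),
                                  int((1 - hi["responder"]).sum()),
                                  int(lo["responder"].sum()),
                                  int((1 - lo["responder"]).sum()))
        association[arm] = blocks

    # ----- survival + interaction -----
    curves: dict[str, pd.DataFrame] = {}
    if curves_roc is not None:
        curves["roc_adjusted"] = curves_roc
    survival_blocks: dict[str, EndpointSurvival] = {}
    for endpoint in cfg.endpoints:
        fit, inter_p, strat = interaction_analysis(
            adf, adf["marker"].to_numpy(), endpoint, cfg.ties_method)
        medians, ns = _km_cells(adf, endpoint, curves, "km")
        survival_blocks[endpoint] = EndpointSurvival(
            interaction_p=float(inter_p),
            interaction_coef=fit.term("treatment_x_marker")["coef"],
            cox_terms=fit.to_dict()["terms"],
            treatment_hr_marker_high=_stratum(strat["high"]),
            treatment_hr_marker_low=_stratum(strat["low"]),
            km_medians=medians,
            km_n=ns,
        )
        log.info("survival %s: interaction p=%.4g (n=%d)", endpoint, inter_p, len(adf))

    # ----- RCS (ICI arm, both score variables) -----
    rcs_blocks: dict[str, dict[str, RCSBlock]] = {}
    ici = df[(df["arm"] == "ICI")]
    for endpoint in cfg.endpoints:
        per_var = {}
        for var in ("btmb", "adjusted_btmb"):
            sub = ici[ici[var].notna()]
            try:
                rcs = rcs_cox_curve(sub[var].to_numpy(),
                                    sub[f"{endpoint}_months"].to_numpy(),
                                    sub[f"{endpoint}_event"].to_numpy(),
                                    k_knots=cfg.rcs_knots,
                                    knot_percentiles=cfg.rcs_knot_percentiles,
                                    ties_method=cfg.ties_method)
            except ValidationError as exc:
                log.warning("rcs %s/%s skipped: %s", endpoint, var, exc)
                continue
            per_var[var] = RCSBlock(
                nonlinearity_p=rcs.nonlinearity_p,
                reference_value=rcs.reference_value,
                knots=[float(k) for k in rcs.knots],
                n=rcs.cox.n, n_events=rcs.cox.n_events,
            )
            curves[f"rcs_{endpoint}_{var}"] = rcs.curve
        rcs_blocks[endpoint] = per_var

    # ----- subgroups -----
    subgroup_blocks: dict[str, SubgroupBlock] = {}
    for name, expr in (cfg.subgroups or {}).items():
        sub = adf.query(expr)
        p_by_ep: dict[str, float | None] = {"os": None, "pfs": None}
        note = ""
        try:
            for endpoint in cfg.endpoints:
                _, p_by_ep[endpoint], _ = interaction_analysis(
                    sub, sub["marker"].to_numpy(), endpoint, cfg.ties_method)
        except BtmbkitError as exc:
            note = f"interaction unavailable: {exc}"
        p_os, p_pfs = p_by_ep["os"], p_by_ep["pfs"]
        subgroup_blocks[name] = SubgroupBlock(
            filter=expr, n=len(sub),
            interaction_p_os=p_os, interaction_p_pfs=p_pfs, note=note)
        log.info("subgroup %s: n=%d", name, len(sub))

    summary = {
        "n_scored": int(defined.sum()),
        "n_undefined": int((~defined).sum()),
        "undefined_reasons": df.loc[~defined, "undefined_reason"]
                               .value_counts().to_dict(),
        "btmb_median": float(df["btmb"].median()),
        "adjusted_btmb_median": float(df.loc[defined, "adjusted_btmb"].median()),
        "mean_af_median": float(df["mean_af"].median()),
        "marker_high_n": int((adf["marker"] == 1).sum()),
        "marker_low_n": int((adf["marker"] == 0).sum()),
    }

    report = AnalysisReport(
        meta=ReportMeta(
            config_hash=_config_hash(cfg), seed=cfg.seed,
            package_version=__version__, n_patients=len(df),
            score_variable=score_col, exclusions=exclusions),
        biomarker_summary=summary,
        cutoff=cutoff_block,
        association=association,
        survival=survival_blocks,
        rcs=rcs_blocks,
        subgroups=subgroup_blocks,
    )
    return PipelineResult(report=report, biomarker_table=profiles, curves=curves)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _summary_text(report: AnalysisReport) -> str:
    lines = [
        "ctDNA-adjusted bTMB analysis",
        f"patients: {report.meta.n_patients} "
        f"(scored {report.biomarker_summary['n_scored']}, "
        f"undefined {report.biomarker_summary['n_undefined']})",
        f"cutoff: {report.cutoff.value:.4g} muts/Mb x ng ({report.cutoff.source}, "
        f"arm={report.cutoff.derivation_arm})",
    ]
    if report.cutoff.auc_adjusted is not None:
        lines.append(
            f"AUC (DCB): adjusted {report.cutoff.auc_adjusted:.3f}"
            + (f" vs raw bTMB {report.cutoff.auc_btmb:.3f} "
               f"(DeLong p={report.cutoff.auc_comparison_p:.3g})"
               if report.cutoff.auc_btmb is not None else ""))
    for ep, blk in report.survival.items():
        hi, lo = blk.treatment_hr_marker_high, blk.treatment_hr_marker_low
        lines.append(
            f"{ep.upper()}: interaction p={blk.interaction_p:.3g}; "
            f"treatment HR high {hi.hr:.2f} [{hi.ci_lower:.2f}-{hi.ci_upper:.2f}], "
            f"low {lo.hr:.2f} [{lo.ci_lower:.2f}-{lo.ci_upper:.2f}]")
    return "\n".join(lines) + "\n"


def generate_report(result: PipelineResult | AnalysisReport | dict, out_dir) -> dict:
    """Write report JSON, its schema, a text summary, curve TSVs and a manifest.

    A dict is validated against the report schema first; a schema-violating
    report is refused. Timestamps go to the run log only, keeping the JSON
    byte-deterministic for identical inputs.
    """
    curves: dict[str, pd.DataFrame] = {}
    biomarker = None
    if isinstance(result, PipelineResult):
        report, curves, biomarker = result.report, result.curves, result.biomarker_table
    elif isinstance(result, AnalysisReport):
        report = result
    else:
        try:
            report = AnalysisReport.model_validate(result)
        except PydanticValidationError as exc:
            raise ValidationError(f"report violates schema: {exc}") from exc

    artifacts: dict = {
        "report": json.loads(report.model_dump_json()),
        "report_schema": AnalysisReport.model_json_schema(),
        "summary": _summary_text(report),
    }
    if biomarker is not None:
        artifacts["biomarker_table"] = biomarker
    for name, frame in curves.items():
        artifacts[name] = frame
    manifest = write_results(artifacts, out_dir)
    run_log = Path(out_dir) / "run.log"
    with run_log.open("a") as fh:
        fh.write(f"{datetime.now(timezone.utc).isoformat()} wrote "
                 f"{len(manifest)} artifacts (config {report.meta.config_hash})\n")
    return manifest
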