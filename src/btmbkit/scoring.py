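"""Per-patient biomarker computation: bTMB, mean AF, ctDNA mass, adjusted score.

The scoring chain follows the tumor-fraction idea: total plasma cell-free DNA
is mostly leukocyte-derived, so the tumor-derived (ctDNA) input mass cannot be
weighed directly. It is instead estimated as

    ctDNA input mass (ng) = cfDNA input mass (ng) x mean somatic allele fraction

and the ctDNA-adjusted bTMB is

    adjusted bTMB = bTMB / ctDNA input mass        [muts / (Mb * ng)]

which removes the tumor-burden dependence that raw bTMB inherits through
variant detectability. Patients with zero mean AF (no detected somatic
variants) or missing plasma have an undefined adjusted score; the default
downstream policy excludes them, an epsilon-floor alternative exists for
sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import ClinicalRecord, PlasmaSample, VariantCall

log = logging.getLogger(__name__)

__all__ = [
    "EligibilityPolicy",
    "BiomarkerProfile",
    "filter_eligible_variants",
    "compute_btmb",
    "compute_mean_af",
    "estimate_ctdna_mass",
    "adjust_btmb",
    "classify_dcb",
    "score_cohort",
]

DCB_THRESHOLD_MONTHS = 6.0


@dataclass(frozen=True)
class EligibilityPolicy:
    """Which variant calls count toward bTMB and toward the mean AF.

    The counting rules behind published bTMB scores are assay-specific; every
    choice is an explicit knob here. Defaults: somatic SNVs+indels at allele
    fraction >= 0.5%, germline-flagged calls excluded, driver mutations
    included; the mean AF uses all somatic calls (not just the bTMB-eligible
    subset).
    """

    af_floor: float = 0.005
    include_indels: bool = True
    exclude_germline: bool = True
    exclude_drivers_from_btmb: bool = False
    mean_af_variant_set: str = "all_somatic"  # or "btmb_eligible"
    zero_mass_policy: str = "exclude"  # or "epsilon_floor"
    epsilon_floor_ng: float = 1e-3
    dcb_indeterminate: str = "exclude"  # or "ndb"

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_floor < 1.0):
            raise ConfigurationError(f"af_floor out of [0,1): {self.af_floor}")
        if self.mean_af_variant_set not in ("all_somatic", "btmb_eligible"):
            raise ConfigurationError(
                f"unknown mean_af_variant_set: {self.mean_af_variant_set!r}")
        if self.zero_mass_policy not in ("exclude", "epsilon_floor"):
            raise ConfigurationError(
                f"unknown zero_mass_policy: {self.zero_mass_policy!r}")
        if self.dcb_indeterminate not in ("exclude", "ndb"):
            raise ConfigurationError(
                f"unknown dcb_indeterminate policy: {self.dcb_indeterminate!r}")


@dataclass(frozen=True)
class BiomarkerProfile:
    """Per-patient biomarker quantities with their derivation invariants.

    ``adjusted_btmb`` is NaN when undefined; ``undefined_reason`` says why
    (``zero_mean_af``, ``no_variants``, ``missing_plasma``, else ``none``).
    """

    patient_id: str
    n_eligible_mutations: int
    btmb: float
    mean_af: float
    cfdna_input_mass_ng: float
    ctdna_input_mass_ng: float
    adjusted_btmb: float
    undefined_reason: str = "none"


def filter_eligible_variants(calls: list[VariantCall],
                             policy: EligibilityPolicy
                             ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split one patient's calls into the bTMB-counted set and the mean-AF set."""
    pids = {c.patient_id for c in calls}
    if len(pids) > 1:
        raise ValidationError(f"calls span multiple patients: {sorted(pids)}")

    somatic = [c for c in calls if not (policy.exclude_germline and c.germline_flag)]
    btmb_set = []
    for c in somatic:
        if c.allele_fraction < policy.af_floor:
            continue
        if not policy.include_indels and c.variant_class in ("insertion", "deletion"):
            continue
        if policy.exclude_drivers_from_btmb and c.driver_flag:
            continue
        btmb_set.append(c)
    mean_af_set = somatic if policy.mean_af_variant_set == "all_somatic" else list(btmb_set)
    return btmb_set, mean_af_set


def compute_btmb(btmb_set: list[VariantCall], panel_size_mb: float) -> float:
    """Mutations per megabase of panel territory."""
    if not panel_size_mb > 0:
        raise ConfigurationError(f"panel_size_mb must be positive: {panel_size_mb}")
    return len(btmb_set) / panel_size_mb


def compute_mean_af(mean_af_set: list[VariantCall]) -> float:
    """Arithmetic mean allele fraction; 0.0 for an empty set."""
    if not mean_af_set:
        return 0.0
    return sum(c.allele_fraction for c in mean_af_set) / len(mean_af_set)


def estimate_ctdna_mass(cfdna_input_mass_ng: float, mean_af: float) -> float:
    """ctDNA input mass (ng) = cfDNA input mass x mean allele fraction."""
    if cfdna_input_mass_ng < 0:
        raise ValidationError(f"negative cfDNA mass: {cfdna_input_mass_ng}")
    if not (0.0 <= mean_af <= 1.0):
        raise ValidationError(f"mean AF out of [0,1]: {mean_af}")
    return cfdna_input_mass_ng * mean_af


def adjust_btmb(btmb: float, ctdna_input_mass_ng: float,
                policy: EligibilityPolicy | None = None) -> float:
    """bTMB divided by ctDNA input mass; NaN when the mass is zero.

    Under ``zero_mass_policy="epsilon_floor"`` a zero mass is replaced by the
    configured floor instead, for sensitivity analysis.
    """
    policy = policy or EligibilityPolicy()
    if btmb < 0 or ctdna_input_mass_ng < 0:
        raise ValidationError("btmb and ctDNA mass must be nonnegative")
    if ctdna_input_mass_ng > 0:
        return btmb / ctdna_input_mass_ng
    if policy.zero_mass_policy == "epsilon_floor":
        return btmb / policy.epsilon_floor_ng
    return math.nan


def classify_dcb(pfs_months: float, pfs_event: bool,
                 policy: EligibilityPolicy | None = None) -> str:
    """Durable clinical benefit label from PFS.

    DCB: progression-free for 6 months or more (event or censored after).
    NDB: progression or death within 6 months.
    Censored before 6 months is indeterminate under the default policy
    (excluded from ROC labeling); the ``ndb`` policy counts it as NDB.
    """
    policy = policy or EligibilityPolicy()
    if pfs_months < 0:
        raise ValidationError(f"negative PFS time: {pfs_months}")
    if pfs_months >= DCB_THRESHOLD_MONTHS:
        return "DCB"
    if pfs_event:
        return "NDB"
    return "NDB" if policy.dcb_indeterminate == "ndb" else "indeterminate"


def score_cohort(clinical: list[ClinicalRecord],
                 variants: list[VariantCall],
                 plasma: list[PlasmaSample],
                 policy: EligibilityPolicy | None = None,
                 panel_size_mb: float = 1.0) -> pd.DataFrame:
    """Compose the per-patient biomarker table for a whole cohort.

    One row per clinical record. Patients without plasma or without variant
    rows carry the corresponding ``undefined_reason``. Variant or plasma rows
    whose patient_id has no clinical record are a reconciliation error.
    """
    policy = policy or EligibilityPolicy()
    clin_ids = [r.patient_id for r in clinical]
    if len(set(clin_ids)) != len(clin_ids):
        raise ValidationError("duplicate patient_id in clinical records")
    clin_set = set(clin_ids)
    orphans = sorted({v.patient_id for v in variants} - clin_set)
    orphans += sorted({p.patient_id for p in plasma} - clin_set)
    if orphans:
        raise ValidationError(f"rows without clinical record: {orphans}")

    by_patient: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_patient.setdefault(v.patient_id, []).append(v)
    plasma_by_id = {p.patient_id: p.cfdna_input_mass_ng for p in plasma}

    rows = []
    n_no_plasma = n_no_variants = n_zero_af = 0
    for rec in clinical:
        calls = by_patient.get(rec.patient_id, [])
        btmb_set, mean_af_set = filter_eligible_variants(calls, policy)
        btmb = compute_btmb(btmb_set, panel_size_mb)
        mean_af = compute_mean_af(mean_af_set)
        cfdna = plasma_by_id.get(rec.patient_id, math.nan)

        reason = "none"
        if rec.patient_id not in plasma_by_id:
            reason = "missing_plasma"
            n_no_plasma += 1
            ctdna = math.nan
            adjusted = math.nan
        else:
            ctdna = estimate_ctdna_mass(cfdna, mean_af)
            adjusted = adjust_btmb(btmb, ctdna, policy)
            if math.isnan(adjusted):
                if not mean_af_set:
                    reason = "no_variants"
                    n_no_variants += 1
                else:
                    reason = "zero_mean_af"
                    n_zero_af += 1
        rows.append({
            "patient_id": rec.patient_id,
            "n_eligible_mutations": len(btmb_set),
            "btmb": btmb,
            "mean_af": mean_af,
            "cfdna_input_mass_ng": cfdna,
            "ctdna_input_mass_ng": ctdna,
            "adjusted_btmb": adjusted,
            "undefined_reason": reason,
        })
    excluded = n_no_plasma + n_no_variants + n_zero_af
    if excluded:
        log.info("score_cohort: %d/%d patients with undefined adjusted score "
                 "(missing plasma %d, no variants %d, zero mean AF %d)",
                 excluded, len(clinical), n_no_plasma, n_no_variants, n_zero_af)
    return pd.DataFrame(rows)
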