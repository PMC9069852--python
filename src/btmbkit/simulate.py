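"""Synthetic randomized two-arm cohorts with burden-driven ctDNA shedding.

The generative model encodes the confounding structure the adjusted score is
meant to break. Each patient carries a true tumor burden B (lognormal sum of
longest diameters, mm) and a true panel mutation count M (negative binomial).
ctDNA shedding is proportional to burden: the patient's mean plasma allele
fraction is a = min(af_cap, s * B * eps) with multiplicative lognormal noise
eps. Each of the M mutations is detected independently with probability
min(1, kappa * a), so the detected count — and with it raw bTMB — rises with
burden even though M does not. In the sub-saturation regime the expected
adjusted score is M * kappa / (panel * cfDNA mass): burden cancels, which is
exactly the decorrelation the adjustment claims.

Survival follows exponential hazards with a treatment x biomarker interaction
on the log-hazard scale, burden entering as standardized log-burden, and
uniform administrative censoring. Best response comes from a logistic model in
treatment x marker; responders are forced to a PFS of at least 2 months so
response and durable-benefit labels cannot contradict each other.

All randomness descends from one seed via per-patient substreams (spawn keyed
by patient index), so growing the cohort never reshuffles earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .io import ClinicalRecord, PlasmaSample, VariantCall

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "truth_summary"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic cohort."""

    n_patients: int = 400
    seed: int = 0
    panel_size_mb: float = 1.0
    # tumor burden: lognormal sum-of-longest-diameters (mm)
    burden_logmean: float = 4.0
    burden_logsd: float = 0.5
    # true panel mutation count: negative binomial
    mutload_mean: float = 10.0
    mutload_dispersion: float = 5.0
    # plasma cfDNA input mass (ng): lognormal
    cfdna_logmean: float = 3.2
    cfdna_logsd: float = 0.4
    # shedding: mean AF = min(af_cap, shedding_slope * burden * noise)
    shedding_slope: float = 2e-4
    shedding_noise_sd: float = 0.25
    af_cap: float = 0.30
    # per-mutation detection probability = min(1, detection_slope * mean AF)
    detection_slope: float = 30.0
    # lognormal scatter of individual variant AFs around the patient mean
    af_scatter_sd: float = 0.3
    arm_prob: float = 0.5
    # latent marker-high definition on the adjusted score, muts/(Mb*ng)
    true_cutoff: float = 8.0
    # survival model
    baseline_median_os: float = 12.0
    baseline_median_pfs: float = 4.0
    beta_treat: float = math.log(0.85)
    beta_marker: float = 0.0
    beta_interaction_os: float = math.log(0.5)
    beta_interaction_pfs: float = math.log(0.45)
    beta_burden: float = math.log(1.3)  # per SD of log-burden
    censor_lo: float = 12.0
    censor_hi: float = 36.0
    # response model: logit P(CR/PR) = base + interaction * treat * marker
    orr_logit_base: float = -1.5
    orr_logit_interaction: float = 1.2
    # original-bTMB-high flag cutoff (muts/Mb); None = cohort median
    btmb_high_cutoff: float | None = None

    def __post_init__(self) -> None:
        def bad(field_name, msg):
            raise ConfigurationError(f"{field_name}: {msg}")

        for name in ("panel_size_mb", "mutload_mean", "mutload_dispersion",
                     "shedding_slope", "detection_slope", "baseline_median_os",
                     "baseline_median_pfs", "true_cutoff"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                bad(name, f"must be finite and positive, got {v}")
        for name in ("burden_logsd", "cfdna_logsd", "shedding_noise_sd",
                     "af_scatter_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                bad(name, f"must be finite and nonnegative, got {v}")
        for name in ("burden_logmean", "cfdna_logmean", "beta_treat",
                     "beta_marker", "beta_interaction_os",
                     "beta_interaction_pfs", "beta_burden",
                     "orr_logit_base", "orr_logit_interaction"):
            if not np.isfinite(getattr(self, name)):
                bad(name, "must be finite")
        if not (0.0 <= self.arm_prob <= 1.0):
            bad("arm_prob", f"must be in [0,1], got {self.arm_prob}")
        if not (0.0 < self.af_cap <= 1.0):
            bad("af_cap", f"must be in (0,1], got {self.af_cap}")
        if self.n_patients < 0:
            bad("n_patients", "must be nonnegative")
        if not (self.censor_lo < self.censor_hi):
            bad("censor_lo", f"censor_lo ({self.censor_lo}) must be below "
                             f"censor_hi ({self.censor_hi})")
        if self.censor_lo < 0:
            bad("censor_lo", "must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    """One simulated cohort: the three input tables plus the generative truth."""

    clinical: list[ClinicalRecord]
    variants: list[VariantCall]
    plasma: list[PlasmaSample]
    truth: pd.DataFrame
    config: SimulationConfig


TRUTH_COLUMNS = [
    "patient_id", "arm_ici", "burden_mm", "true_mutation_count",
    "mean_shed_af", "n_detected", "adjusted_btmb_realized", "latent_high",
    "log_burden_z",
]


def _simulate_patient(rng: np.random.Generator, cfg: SimulationConfig, pid: str):
    """Draw one patient's latent state, plasma sample and variant calls.

    Draw order is fixed; anything conditional draws from the tail of the
    stream so earlier quantities are stable across config changes that only
    touch later ones.
    """
    burden = rng.lognormal(cfg.burden_logmean, cfg.burden_logsd)
    k = cfg.mutload_dispersion
    mutload = int(rng.negative_binomial(k, k / (k + cfg.mutload_mean)))
    cfdna = rng.lognormal(cfg.cfdna_logmean, cfg.cfdna_logsd)
    eps = rng.lognormal(-cfg.shedding_noise_sd ** 2 / 2.0, cfg.shedding_noise_sd)
    mean_af = min(cfg.af_cap, cfg.shedding_slope * burden * eps)
    p_det = min(1.0, cfg.detection_slope * mean_af)
    n_det = int(rng.binomial(mutload, p_det)) if mutload > 0 else 0

    sv = cfg.af_scatter_sd
    afs = np.clip(mean_af * rng.lognormal(-sv * sv / 2.0, sv, size=n_det), 0.0, 1.0)

    treat = int(rng.random() < cfg.arm_prob)
    u_os, u_prog, u_cens, u_resp, u_cr = rng.random(5)
    u_pdl1 = rng.random()
    n_mets = 1 + int(rng.poisson(burden / 40.0))
    stk11 = bool(rng.random() < 0.15)

    calls = []
    for j in range(n_det):
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(10_000, 100_000_000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        u_class = rng.random()
        vclass = "SNV" if u_class < 0.9 else ("insertion" if u_class < 0.95 else "deletion")
        if vclass == "insertion":
            alt = alt + "".join(rng.choice(_BASES, size=2))
        elif vclass == "deletion":
            ref, alt = ref + "".join(rng.choice(_BASES, size=2)), ref
        calls.append(VariantCall(
            patient_id=pid, chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
            allele_fraction=float(afs[j]), depth=int(rng.integers(500, 5000)),
            variant_class=vclass, driver_flag=bool(rng.random() < 0.05),
            germline_flag=False))
    # occasional germline contaminants near AF 0.5, flagged for exclusion
    for _ in range(int(rng.poisson(0.3))):
        calls.append(VariantCall(
            patient_id=pid, chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(10_000, 100_000_000)),
            ref="G", alt="A",
            allele_fraction=float(np.clip(rng.normal(0.5, 0.03), 0.0, 1.0)),
            depth=int(rng.integers(500, 5000)),
            variant_class="SNV", driver_flag=False, germline_flag=True))

    return {
        "burden": burden, "mutload": mutload, "cfdna": cfdna,
        "mean_af": mean_af, "n_det": n_det, "afs": afs, "treat": treat,
        "u_os": u_os, "u_prog": u_prog, "u_cens": u_cens, "u_resp": u_resp,
        "u_cr": u_cr, "u_pdl1": u_pdl1, "n_mets": n_mets, "stk11": stk11,
        "calls": calls,
    }


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort under ``config``; byte-identical for equal seeds."""
    cfg = config
    n = cfg.n_patients
    if n == 0:
        return SimulatedCohort([], [], [], pd.DataFrame(columns=TRUTH_COLUMNS), cfg)

    children = np.random.SeedSequence(cfg.seed).spawn(n)
    pids = [f"P{i + 1:05d}" for i in range(n)]
    draws = [_simulate_patient(np.random.default_rng(children[i]), cfg, pids[i])
             for i in range(n)]

    log_burden = np.log([d["burden"] for d in draws])
    sd = log_burden.std()
    z = (log_burden - log_burden.mean()) / (sd if sd > 0 else 1.0)

    # realized biomarker quantities, as downstream scoring will recompute them
    btmb = np.array([d["n_det"] / cfg.panel_size_mb for d in draws])
    emp_af = np.array([d["afs"].mean() if d["n_det"] > 0 else 0.0 for d in draws])
    ctdna = np.array([d["cfdna"] for d in draws]) * emp_af
    with np.errstate(divide="ignore", invalid="ignore"):
        adjusted = np.where(ctdna > 0, btmb / ctdna, np.nan)
    latent = np.where(np.isnan(adjusted), 0, (adjusted >= cfg.true_cutoff)).astype(int)

    h0_os = math.log(2.0) / cfg.baseline_median_os
    h0_pfs = math.log(2.0) / cfg.baseline_median_pfs

    clinical: list[ClinicalRecord] = []
    variants: list[VariantCall] = []
    plasma: list[PlasmaSample] = []
    truth_rows = []
    btmb_flag_cut = (cfg.btmb_high_cutoff if cfg.btmb_high_cutoff is not None
                     else float(np.median(btmb)))

    for i, d in enumerate(draws):
        t, x = d["treat"], int(latent[i])
        lp_os = (cfg.beta_treat * t + cfg.beta_marker * x
                 + cfg.beta_interaction_os * t * x + cfg.beta_burden * z[i])
        lp_pfs = (cfg.beta_treat * t + cfg.beta_marker * x
                  + cfg.beta_interaction_pfs * t * x + cfg.beta_burden * z[i])
        t_os = -math.log(d["u_os"]) / (h0_os * math.exp(lp_os))
        t_prog = -math.log(d["u_prog"]) / (h0_pfs * math.exp(lp_pfs))
        t_pfs = min(t_prog, t_os)
        cens = cfg.censor_lo + d["u_cens"] * (cfg.censor_hi - cfg.censor_lo)

        os_months = min(t_os, cens)
        os_event = t_os <= cens
        pfs_months = min(t_pfs, cens)
        pfs_event = t_pfs <= cens

        p_resp = 1.0 / (1.0 + math.exp(-(cfg.orr_logit_base
                                         + cfg.orr_logit_interaction * t * x)))
        responder = d["u_resp"] < p_resp
        if responder:
            pfs_months = max(pfs_months, 2.0)
            best = "CR" if d["u_cr"] < 0.15 else "PR"
        else:
            best = "PD" if (pfs_event and pfs_months < 6.0) else "SD"

        pdl1 = ("negative" if d["u_pdl1"] < 0.45
                else "positive" if d["u_pdl1"] < 0.95 else "unknown")

        clinical.append(ClinicalRecord(
            patient_id=pids[i],
            arm="ICI" if t else "comparator",
            os_months=os_months, os_event=bool(os_event),
            pfs_months=pfs_months, pfs_event=bool(pfs_event),
            best_response=best, pdl1_status=pdl1,
            sum_longest_diameters_mm=d["burden"],
            n_metastatic_sites=d["n_mets"],
            stk11_keap1_mut=d["stk11"],
            original_btmb_high=bool(btmb[i] >= btmb_flag_cut),
        ))
        variants.extend(d["calls"])
        plasma.append(PlasmaSample(pids[i], d["cfdna"]))
        truth_rows.append({
            "patient_id": pids[i], "arm_ici": t, "burden_mm": d["burden"],
            "true_mutation_count": d["mutload"], "mean_shed_af": d["mean_af"],
            "n_detected": d["n_det"],
            "adjusted_btmb_realized": float(adjusted[i]),
            "latent_high": x, "log_burden_z": z[i],
        })

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedCohort(clinical, variants, plasma, truth, cfg)


def truth_summary(truth: pd.DataFrame) -> dict:
    """Bookkeeping summary of a truth table (per-arm counts, prevalence, means)."""
    if truth is None or len(truth) == 0:
        raise EmptyInputError("truth table is empty")
    by_arm = truth.groupby("arm_ici")["patient_id"].count()
    return {
        "n_patients": int(len(truth)),
        "n_ici": int(by_arm.get(1, 0)),
        "n_comparator": int(by_arm.get(0, 0)),
        "prevalence_latent_high": float(truth["latent_high"].mean()),
        "mean_burden_mm": float(truth["burden_mm"].mean()),
        "mean_true_mutation_count": float(truth["true_mutation_count"].mean()),
    }
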