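"""Reading and validation of cohort tables, and result-artifact writing.

All tabular I/O is tab-separated UTF-8 with a header row. Missing values are
written as empty strings and accepted as either empty or ``NA`` on read.
Enum-like fields are matched case-insensitively on read and written in
canonical case. Variant tables come either as MAF-like TSV or as VCF 4.x
(via cyvcf2), with multi-allelic records split one call per alternate allele.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "VariantCall",
    "PlasmaSample",
    "read_clinical",
    "read_variants",
    "read_plasma",
    "clinical_to_frame",
    "variants_to_frame",
    "plasma_to_frame",
    "write_table",
    "write_results",
]

ARMS = ("ICI", "comparator")
RESPONSES = ("CR", "PR", "SD", "PD", "NE")
PDL1 = ("negative", "positive", "unknown")
VARIANT_CLASSES = ("SNV", "insertion", "deletion", "other")

CLINICAL_COLUMNS = [
    "patient_id", "arm", "os_months", "os_event", "pfs_months", "pfs_event",
    "best_response", "pdl1_status", "sum_longest_diameters_mm",
    "n_metastatic_sites", "stk11_keap1_mut", "original_btmb_high",
]
VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "allele_fraction", "depth",
    "variant_class", "driver_flag", "germline_flag",
]
PLASMA_COLUMNS = ["patient_id", "cfdna_input_mass_ng"]


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    arm: str
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    best_response: str
    pdl1_status: str = "unknown"
    sum_longest_diameters_mm: float | None = None
    n_metastatic_sites: int | None = None
    stk11_keap1_mut: bool | None = None
    original_btmb_high: bool | None = None


@dataclass(frozen=True)
class VariantCall:
    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_fraction: float
    depth: int
    variant_class: str = "SNV"
    driver_flag: bool = False
    germline_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_fraction <= 1.0):
            raise ValidationError(
                f"allele_fraction out of [0,1] for {self.patient_id} "
                f"{self.chrom}:{self.pos}: {self.allele_fraction}")
        if self.depth < 0:
            raise ValidationError(f"negative depth at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position must be 1-based: {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")


@dataclass(frozen=True)
class PlasmaSample:
    patient_id: str
    cfdna_input_mass_ng: float

    def __post_init__(self) -> None:
        if not (self.cfdna_input_mass_ng > 0):
            raise ValidationError(
                f"cfDNA input mass must be positive for {self.patient_id}: "
                f"{self.cfdna_input_mass_ng}")


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.replace("NA", "")


def _enum(value: str, allowed: tuple[str, ...], column: str, row: int) -> str:
    canon = {a.lower(): a for a in allowed}
    key = value.strip().lower()
    if key not in canon:
        raise ValidationError(
            f"row {row}: unparseable {column} value {value!r} "
            f"(allowed: {', '.join(allowed)})")
    return canon[key]


def _boolish(value: str, column: str, row: int) -> bool:
    key = value.strip().lower()
    if key in ("1", "true", "yes", "t"):
        return True
    if key in ("0", "false", "no", "f"):
        return False
    raise ValidationError(f"row {row}: unparseable boolean in {column}: {value!r}")


def _opt(value: str, conv, column: str, row: int):
    if value.strip() == "":
        return None
    return conv(value, column, row)


def _floatval(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"row {row}: bad number in {column}: {value!r}") from exc


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_clinical(path) -> list[ClinicalRecord]:
    """Read and validate a clinical TSV into :class:`ClinicalRecord` rows.

    ``pfs_months > os_months`` with both events observed is accepted with a
    warning (registry data violate the ordering); duplicate patient ids and
    missing mandatory columns are hard errors.
    """
    df = _read_tsv(path)
    mandatory = CLINICAL_COLUMNS[:8]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing mandatory columns: {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate patient_id: {sorted(set(dup))}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        pid = r["patient_id"].strip()
        if not pid:
            raise ValidationError(f"row {i}: empty patient_id")
        rec = ClinicalRecord(
            patient_id=pid,
            arm=_enum(r["arm"], ARMS, "arm", i),
            os_months=_floatval(r["os_months"], "os_months", i),
            os_event=_boolish(r["os_event"], "os_event", i),
            pfs_months=_floatval(r["pfs_months"], "pfs_months", i),
            pfs_event=_boolish(r["pfs_event"], "pfs_event", i),
            best_response=_enum(r["best_response"], RESPONSES, "best_response", i),
            pdl1_status=_enum(r["pdl1_status"], PDL1, "pdl1_status", i),
            sum_longest_diameters_mm=_opt(r.get("sum_longest_diameters_mm", ""),
                                          _floatval, "sum_longest_diameters_mm", i),
            n_metastatic_sites=(None if r.get("n_metastatic_sites", "").strip() == ""
                                else int(float(r["n_metastatic_sites"]))),
            stk11_keap1_mut=_opt(r.get("stk11_keap1_mut", ""), _boolish,
                                 "stk11_keap1_mut", i),
            original_btmb_high=_opt(r.get("original_btmb_high", ""), _boolish,
                                    "original_btmb_high", i),
        )
        if rec.os_months < 0 or rec.pfs_months < 0:
            raise ValidationError(f"row {i}: negative survival time")
        if rec.os_event and rec.pfs_event and rec.pfs_months > rec.os_months:
            log.warning("row %d (%s): pfs_months %.3g exceeds os_months %.3g; "
                        "record kept", i, pid, rec.pfs_months, rec.os_months)
        records.append(rec)
    return records


def _variant_class_of(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "other"


def read_variants(path, format: str = "maf_tsv") -> list[VariantCall]:
    """Read somatic variant calls from a MAF-like TSV or a VCF 4.x file.

    VCF allele fractions come from the per-sample FORMAT ``AF`` field when
    present, else from allelic depths as AD_alt / (AD_ref + AD_alt); a VCF
    with neither is a format error. Multi-allelic records are split one call
    per alternate allele; every sample carrying the allele contributes a call
    with its own AF (patient id = sample name).
    """
    if format == "maf_tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise ValidationError(f"unknown variant format: {format!r}")


def _read_variants_tsv(path) -> list[VariantCall]:
    df = _read_tsv(path)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        calls.append(VariantCall(
            patient_id=r["patient_id"].strip(),
            chrom=r["chrom"].strip(),
            pos=int(float(r["pos"])),
            ref=r["ref"].strip(),
            alt=r["alt"].strip(),
            allele_fraction=_floatval(r["allele_fraction"], "allele_fraction", i),
            depth=int(float(r["depth"])),
            variant_class=_enum(r["variant_class"], VARIANT_CLASSES,
                                "variant_class", i),
            driver_flag=_boolish(r["driver_flag"], "driver_flag", i),
            germline_flag=_boolish(r["germline_flag"], "germline_flag", i),
        ))
    return calls


def _read_variants_vcf(path) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError("VCF has no sample columns; cannot assign patients")
    calls = []
    for rec in vcf:
        fmt_af = None
        try:
            fmt_af = rec.format("AF")
        except KeyError:
            fmt_af = None
        ad = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if fmt_af is None and ad is None:
            raise ValidationError(
                f"VCF record {rec.CHROM}:{rec.POS} has no AF source "
                "(needs FORMAT AF or AD)")
        depths = rec.format("DP") if "DP" in (rec.FORMAT or []) else None
        driver = bool(rec.INFO.get("DRIVER", 0))
        germline = bool(rec.INFO.get("GERMLINE", 0))
        for ai, alt in enumerate(rec.ALT):
            for si, sample in enumerate(samples):
                if fmt_af is not None:
                    af = float(np.atleast_1d(fmt_af[si])[min(ai, np.atleast_1d(fmt_af[si]).size - 1)])
                    depth = int(depths[si][0]) if depths is not None else 0
                else:
                    row = np.asarray(ad[si], dtype=float)
                    ref_d = row[0]
                    alt_d = row[1 + ai]
                    total = ref_d + alt_d
                    af = float(alt_d / total) if total > 0 else 0.0
                    depth = int(total)
                if math.isnan(af) or af <= 0:
                    continue  # sample does not carry this allele
                calls.append(VariantCall(
                    patient_id=sample,
                    chrom=rec.CHROM,
                    pos=int(rec.POS),
                    ref=rec.REF,
                    alt=alt,
                    allele_fraction=af,
                    depth=depth,
                    variant_class=_variant_class_of(rec.REF, alt),
                    driver_flag=driver,
                    germline_flag=germline,
                ))
    return calls


def read_plasma(path) -> list[PlasmaSample]:
    """Read the per-patient plasma cfDNA input-mass table."""
    df = _read_tsv(path)
    missing = [c for c in PLASMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plasma table missing columns: {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        samples.append(PlasmaSample(
            patient_id=r["patient_id"].strip(),
            cfdna_input_mass_ng=_floatval(r["cfdna_input_mass_ng"],
                                          "cfdna_input_mass_ng", i),
        ))
    ids = [s.patient_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient_id in plasma table")
    return samples


# ---------------------------------------------------------------------------
# frames and writing
# ---------------------------------------------------------------------------

def _records_to_frame(records, columns) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {}
        for f in dc_fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, bool):
                v = int(v)
            row[f.name] = "" if v is None else v
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    return df


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return _records_to_frame(records, CLINICAL_COLUMNS)


def variants_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return _records_to_frame(calls, VARIANT_COLUMNS)


def plasma_to_frame(samples: list[PlasmaSample]) -> pd.DataFrame:
    return _records_to_frame(samples, PLASMA_COLUMNS)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a TSV with full float precision (round-trips to 1e-12 and better)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")
    return path


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(artifacts: dict, out_dir) -> dict:
    """Write a dict of artifacts and return a checksummed file manifest.

    DataFrame values become TSVs, dict/list values JSON, strings plain text;
    keys are file stems. The manifest itself is written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"not a writable directory: {out}")
    manifest = {}
    for name, value in artifacts.items():
        if isinstance(value, pd.DataFrame):
            path = write_table(value, out / f"{name}.tsv")
        elif isinstance(value, (dict, list)):
            path = out / f"{name}.json"
            path.write_text(json.dumps(value, indent=2, sort_keys=True) + "\n")
        elif isinstance(value, str):
            path = out / f"{name}.txt"
            path.write_text(value)
        else:
            raise ValidationError(f"cannot serialize artifact {name!r} of type {type(value)}")
        manifest[path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
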