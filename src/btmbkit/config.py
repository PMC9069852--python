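"""Structured run configuration for the end-to-end analysis.

YAML (or an equivalent mapping) with a fixed key set; unknown keys are
rejected so typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .scoring import EligibilityPolicy

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything `analyze` needs: input paths, scoring policy, analysis knobs."""

    clinical: str
    variants: str
    plasma: str
    out_dir: str = "results"
    variants_format: str = "maf_tsv"  # or "vcf"
    panel_size_mb: float = 1.0
    seed: int = 0

    # scoring policy knobs (mirror EligibilityPolicy)
    af_floor: float = 0.005
    include_indels: bool = True
    exclude_germline: bool = True
    exclude_drivers_from_btmb: bool = False
    mean_af_variant_set: str = "all_somatic"
    zero_mass_policy: str = "exclude"
    epsilon_floor_ng: float = 1e-3
    dcb_indeterminate: str = "exclude"

    # cutoff: a number, or "derive" (Youden on DCB)
    cutoff: float | str = "derive"
    cutoff_arm: str = "ici"  # derive on ICI arm only, or "all"
    split_sample_fraction: float | None = None  # derive on a split, evaluate on the rest

    # continuous variable carried through every stage; "btmb" disables the
    # ctDNA adjustment for side-by-side comparison
    score_variable: str = "adjusted_btmb"

    # survival endpoints to analyze
    endpoints: tuple[str, ...] = ("os", "pfs")

    ties_method: str = "efron"
    rcs_knots: int = 4
    rcs_knot_percentiles: tuple[float, ...] | None = None

    # name -> pandas query over clinical columns
    subgroups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variants_format not in ("maf_tsv", "vcf"):
            raise ConfigurationError(f"variants_format: unknown value {self.variants_format!r}")
        if not self.panel_size_mb > 0:
            raise ConfigurationError(f"panel_size_mb must be positive: {self.panel_size_mb}")
        if self.cutoff_arm not in ("ici", "all"):
            raise ConfigurationError(f"cutoff_arm: unknown value {self.cutoff_arm!r}")
        if self.score_variable not in ("adjusted_btmb", "btmb"):
            raise ConfigurationError(f"score_variable: unknown value {self.score_variable!r}")
        if not self.endpoints or any(ep not in ("os", "pfs") for ep in self.endpoints):
            raise ConfigurationError(f"endpoints must be among ('os', 'pfs'): {self.endpoints}")
        if self.ties_method not in ("efron", "breslow"):
            raise ConfigurationError(f"ties_method: unknown value {self.ties_method!r}")
        if isinstance(self.cutoff, str) and self.cutoff != "derive":
            raise ConfigurationError(
                f"cutoff must be a number or 'derive', got {self.cutoff!r}")
        if self.split_sample_fraction is not None and not (0.0 < self.split_sample_fraction < 1.0):
            raise ConfigurationError("split_sample_fraction must be in (0,1)")
        if self.rcs_knots < 3:
            raise ConfigurationError("rcs_knots must be >= 3")
        # delegate policy-field validation
        self.policy()

    def policy(self) -> EligibilityPolicy:
        return EligibilityPolicy(
            af_floor=self.af_floor,
            include_indels=self.include_indels,
            exclude_germline=self.exclude_germline,
            exclude_drivers_from_btmb=self.exclude_drivers_from_btmb,
            mean_af_variant_set=self.mean_af_variant_set,
            zero_mass_policy=self.zero_mass_policy,
            epsilon_floor_ng=self.epsilon_floor_ng,
            dcb_indeterminate=self.dcb_indeterminate,
        )


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown run-config keys: {unknown}")
    if "subgroups" in raw and raw["subgroups"] is not None and not isinstance(raw["subgroups"], dict):
        raise ConfigurationError("subgroups must be a mapping of name -> filter expression")
    if "rcs_knot_percentiles" in raw and raw["rcs_knot_percentiles"] is not None:
        raw["rcs_knot_percentiles"] = tuple(raw["rcs_knot_percentiles"])
    if "endpoints" in raw:
        eps = raw["endpoints"]
        raw["endpoints"] = tuple([eps] if isinstance(eps, str) else eps)
    missing = [k for k in ("clinical", "variants", "plasma") if k not in raw]
    if missing:
        raise ConfigurationError(f"run config missing required keys: {missing}")
    return RunConfig(**raw)
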