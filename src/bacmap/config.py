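"""Pipeline configuration with published defaults, plus YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


@dataclass
class PipelineConfig:
    """Every stage parameter of the integrated assembly/anchoring pipeline.

    Defaults are the published operating point: preliminary agarose assembly
    at 1e-10/tol 8, HICF at 1e-50/tol 3, integrated reassembly at 1e-12/tol 7,
    marker relaxation by 2/3/4 denary intervals, end-merge descent to 1e-6.
    """

    # -- preliminary agarose assembly
    prelim_cutoff: float = 1e-10
    prelim_tolerance: int = 8
    # -- HICF-only assembly
    hicf_cutoff: float = 1e-50
    hicf_tolerance: int = 3
    hicf_gel_length: int = 10_000
    # -- integrated assembly
    integrated_cutoff: float = 1e-12
    integrated_tolerance: int = 7
    gel_length: int = 5000
    # -- evidence handling
    assembly_max_hits: int = 50         # probes with more hits never relax joins
    anchoring_max_hits: int = 29        # probes with >= 30 hits never anchor
    bac_max_probes: int = 7             # BACs with >= 8 probes are excluded
    # -- QC
    qc_enabled: bool = True
    outlier_low_pct: float = 5.0
    outlier_high_pct: float = 5.0
    crosswell_similarity: float = 0.90
    crosswell_cross_plate: bool = False
    # -- HICF targeting
    terminal_fraction: float = 0.5      # largest half of prelim contigs
    per_end: int = 2
    # -- finalization
    end_merge_floor: float = 1e-6
    burial_fraction: float = 0.80
    # -- synteny / anchoring
    window_at: int = 200_000
    window_vv: int = 1_000_000
    density_bin: int = 200_000
    avg_band_bp_lw: int = 4096          # Lander-Waterman band size
    avg_band_bp_cb: int = 4097          # CB-unit physical coverage band size
    organelle_min_evidence: int = 2
    # -- provenance
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prelim_cutoff", "hicf_cutoff", "integrated_cutoff",
                     "end_merge_floor"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.burial_fraction <= 1):
            raise ConfigError("burial_fraction must be in (0, 1]")
        if not (0 < self.terminal_fraction <= 1):
            raise ConfigError("terminal_fraction must be in (0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
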