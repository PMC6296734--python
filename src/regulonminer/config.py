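"""Pipeline configuration: every tunable threshold with its default.

Defaults encode the screening conditions of the mining procedure: a 2-fold
enrichment floor at p < 1e-10, +/-100 bp fragment extension, hexamer subsites
TGTTAC (F) / GTAACA (R) chained at 20-25 bp centre-to-centre spacing with at
most 2 mismatches overall, a GG-N10-GC sigma-54 element with exact anchors,
and the classic IHF consensus WATCAANNNNTTR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_io import ConfigError


@dataclass
class PipelineConfig:
    """All tunables for mining, scanning and annotation.

    Unknown keys in a YAML file are rejected rather than ignored so that a
    typo cannot silently fall back to a default.
    """

    # peak filtration
    min_enrichment: float = 2.0          # fold over background, inclusive
    max_p: float = 1e-10                 # strict upper bound
    extension: int = 100                 # bp added on each side of a peak

    # sigma-54 orientation screen
    sigma54_anchor_mm: int = 0           # mismatches allowed on GG/GC anchors
    max_promoter_to_atg: int = 500       # bp from sigma-54 centre to the ATG

    # subsite / composite scanning
    motif_f: str = "TGTTAC"
    motif_r: str = "GTAACA"
    per_site_mm: int = 2                 # per-subsite mismatch cap
    mismatch_budget: int = 2             # global cap over a composite
    min_sites: int = 2
    spacing_min: float = 20.0            # centre-to-centre, inclusive
    spacing_max: float = 25.0
    phase_period: float = 10.5           # bp per helical turn
    phase_tol: float = 4.0               # bp deviation from the nearest turn

    # IHF
    ihf_consensus: str = "WATCAANNNNTTR"
    ihf_max_mm: int = 0

    # promoter architecture
    upstream_window: int = 500           # bp extracted upstream of the ATG
    sigma_to_uas_min: float = 30.0       # sigma-54 centre to nearest subsite centre
    sigma_to_uas_max: float = 250.0

    def validate(self) -> "PipelineConfig":
        if self.min_enrichment <= 0 or self.max_p <= 0:
            raise ConfigError("thresholds must be positive")
        if self.extension < 0:
            raise ConfigError("extension must be >= 0")
        if not (0 <= self.per_site_mm <= 6 and 0 <= self.mismatch_budget):
            raise ConfigError("mismatch caps out of range")
        if self.spacing_min > self.spacing_max:
            raise ConfigError("spacing_min > spacing_max")
        if self.sigma54_anchor_mm not in (0, 1, 2):
            raise ConfigError("sigma54_anchor_mm must be 0, 1 or 2")
        for motif in (self.motif_f, self.motif_r):
            if len(motif) != 6 or set(motif) - set("ACGT"):
                raise ConfigError(f"subsite motif {motif!r} must be a 6-mer over ACGT")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
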