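"""Pipeline configuration: thresholds for every stage, serializable to YAML."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .filtering import FilterConfig


@dataclass
class PipelineConfig:
    """All knobs of the analysis pipeline in one round-trippable object."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    enrichment_alpha: float = 0.05
    enrichment_method: str = "binomial"  # binomial | fisher
    n_ref: int = 2504
    cooccurrence_alpha: float = 0.05
    cooccurrence_method: str = "chi2"  # chi2 | fisher
    min_pair_count: int = 0
    category_alpha: float = 0.05
    null_M: int = 999
    null_mode: str = "uniform"  # uniform | degree_matched
    null_statistic: str = "connected_seed_count"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("enrichment_alpha", "cooccurrence_alpha", "category_alpha"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.null_M < 1:
            raise ValueError("null_M must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = asdict(self)
        out["filters"]["coding_keep"] = sorted(self.filters.coding_keep)
        out["filters"]["germline_vaf_bands"] = [
            list(band) for band in self.filters.germline_vaf_bands
        ]
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        fraw = dict(raw.pop("filters", {}))
        if "coding_keep" in fraw:
            fraw["coding_keep"] = frozenset(fraw["coding_keep"])
        if "germline_vaf_bands" in fraw:
            fraw["germline_vaf_bands"] = tuple(
                tuple(band) for band in fraw["germline_vaf_bands"]
            )
        known = {f.name for f in fields(cls)} - {"filters"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(filters=FilterConfig(**fraw), **raw)

    def digest(self) -> str:
        """Short stable hash of the canonical serialized config."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
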