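"""Pipeline configuration: thresholds, paths, conditions, reproducibility."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """The configuration file or an override is invalid."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default.

    Threshold defaults are the canonical calling/analysis values:
    200-nt cluster gap, <=5 genomic loci per read, >=90 % predominance,
    <=2 predominant 5' sites, <=4 star-arm mismatches, 500-CPM expression
    cutoff, q <= 0.05 with >= 2-fold change for differential calls.
    """

    # paths (all optional; the simulate stage fills them in)
    genome: str | None = None
    alignments: dict[str, str] = field(default_factory=dict)  # library -> TSV
    transcriptome: str | None = None
    exclusion_bed: str | None = None
    gene_counts: str | None = None

    # library -> condition
    conditions: dict[str, str] = field(default_factory=dict)

    # thresholds
    max_gap: int = 200
    flank: int = 20
    predominance_min: float = 0.90
    max_5p_sites: int = 2
    max_star_mismatches: int = 4
    min_site_fraction: float = 0.10
    min_stem_pairs: int = 15
    cpm_cutoff: float = 500.0
    de_q: float = 0.05
    de_fold: float = 2.0
    max_loci: int = 5

    # simulation
    n_valid_precursors: int = 20
    defects_per_kind: int = 2
    spacer_len: int = 500
    library_size: int = 300_000
    predominance: float = 0.95
    offset_jitter: int = 2
    background_fraction: float = 0.90
    star_fraction: float = 0.02
    targets_per_mirna: int = 3

    # reproducibility / backends
    seed: int = 0
    fold_backend: str = "builtin"

    def validate(self) -> None:
        checks = [
            (self.max_gap > 0, "max_gap must be positive"),
            (self.flank >= 0, "flank must be >= 0"),
            (0 < self.predominance_min <= 1, "predominance_min must be in (0, 1]"),
            (self.max_5p_sites >= 1, "max_5p_sites must be >= 1"),
            (self.max_star_mismatches >= 0, "max_star_mismatches must be >= 0"),
            (0 < self.min_site_fraction <= 1, "min_site_fraction must be in (0, 1]"),
            (self.min_stem_pairs >= 1, "min_stem_pairs must be >= 1"),
            (self.cpm_cutoff >= 0, "cpm_cutoff must be >= 0"),
            (0 < self.de_q <= 1, "de_q must be in (0, 1]"),
            (self.de_fold >= 1, "de_fold must be >= 1"),
            (self.max_loci >= 1, "max_loci must be >= 1"),
            (self.fold_backend in ("builtin", "external"), "unknown fold_backend"),
            (0 < self.predominance <= 1, "predominance must be in (0, 1]"),
            (0 <= self.background_fraction < 1, "background_fraction in [0, 1)"),
            (self.spacer_len > 200, "spacer_len must exceed 200"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        for library in self.alignments:
            if library not in self.conditions:
                raise ConfigError(f"library {library!r} has no condition assigned")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def apply_override(self, override: str) -> None:
        """Apply a ``key=value`` command-line override, with type coercion."""
        if "=" not in override:
            raise ConfigError(f"override {override!r} is not of the form key=value")
        key, raw = override.split("=", 1)
        key = key.strip()
        matching = {f.name: f for f in fields(self)}
        if key not in matching:
            raise ConfigError(f"unknown config key {key!r}")
        current = getattr(self, key)
        try:
            if isinstance(current, bool):
                value = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            elif isinstance(current, dict):
                value = yaml.safe_load(raw)
                if not isinstance(value, dict):
                    raise ValueError("expected a mapping")
            else:
                value = raw
        except ValueError as exc:
            raise ConfigError(f"cannot coerce {raw!r} for key {key!r}: {exc}") from exc
        setattr(self, key, value)
        self.validate()
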