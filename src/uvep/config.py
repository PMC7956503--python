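"""Pipeline configuration: YAML in, validated dataclass out.

Defaults are the thresholds the analysis is designed around: detection
frequency > 25% of runs, F-ratio screen at F >= 5 / p <= 0.01, DEP calls
at |DAve| > 0.2 and |DCI| > 5 (|DCI| > 10 for the CD-marker report),
k = 3 proteome groups and a 6-protein monitoring panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # ingest
    run_table: str | None = None
    run_table_format: str = "long_tsv"
    run_table_sidecar: str | None = None
    fot_table: str | None = None
    cd_list: str | None = None
    outdir: str = "uvep_out"
    # thresholds
    min_frac: float = 0.25
    qc_min_correlation: float = 0.8
    qc_slope_lo: float = 0.8
    qc_slope_hi: float = 1.25
    f_min: float = 5.0
    p_max: float = 0.01
    dave_threshold: float = 0.2
    dci_threshold: float = 5.0
    cd_dci_threshold: float = 10.0
    lda_shrinkage: float = 0.5
    k: int = 3
    panel_size: int = 6
    cluster_transform: str = "none"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.min_frac < 1):
            raise ConfigError(f"min_frac must be in [0, 1), got {self.min_frac}")
        if not (0 <= self.lda_shrinkage <= 1):
            raise ConfigError(f"lda_shrinkage must be in [0, 1], got {self.lda_shrinkage}")
        if not (0 < self.p_max <= 1):
            raise ConfigError(f"p_max must be in (0, 1], got {self.p_max}")
        for name in ("f_min", "dave_threshold", "dci_threshold", "cd_dci_threshold"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.k < 1 or self.panel_size < 1:
            raise ConfigError("k and panel_size must be >= 1")
        if self.cluster_transform not in ("none", "log2p1"):
            raise ConfigError(f"unknown cluster_transform {self.cluster_transform!r}")
        if self.run_table_format not in ("long_tsv", "wide_csv"):
            raise ConfigError(f"unknown run_table_format {self.run_table_format!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        """Snapshot the effective configuration (for output provenance)."""
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file, fill defaults, reject unknown keys."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {unknown}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
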