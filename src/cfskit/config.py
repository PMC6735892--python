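"""Strict YAML run configuration with recorded default provenance."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from cfskit.errors import ConfigError
from cfskit.simulate.cytogenetics import CytoSimParams
from cfskit.simulate.imaging import ImageSimParams
from cfskit.simulate.proteomics import ProteomicsSimParams


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.05
    min_score: float = 0.4

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 <= self.min_score <= 1:
            raise ConfigError("min_score must lie in [0, 1]")


@dataclass(frozen=True)
class QibcConfig:
    min_area: int = 120
    max_area: int = 5000
    spot_sigma: float = 1.5
    rel_threshold: float = 6.0
    overlap_radius: float = 3.0
    max_mn_area: int = 80
    search_radius: float = 20.0


@dataclass(frozen=True)
class ColocConfig:
    block_px: int = 5
    n_rand: int = 1000
    n_cells: int = 25  # G2 cells sampled for the Costes test

    def __post_init__(self):
        if self.n_rand < 99:
            raise ConfigError("n_rand must be >= 99")
        if self.block_px < 1:
            raise ConfigError("block_px must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "cfs_run"
    seed: int = 0
    fold_threshold: float = 1.5
    log_level: str = "INFO"
    proteomics: ProteomicsSimParams = field(default_factory=ProteomicsSimParams)
    imaging: ImageSimParams = field(default_factory=ImageSimParams)
    cyto: CytoSimParams = field(default_factory=CytoSimParams)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    qibc: QibcConfig = field(default_factory=QibcConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ConfigError(
                f"fold_threshold must exceed 1, got {self.fold_threshold}"
            )


def _build(cls, raw: dict, where: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


_SECTIONS = {
    "proteomics": ProteomicsSimParams,
    "imaging": ImageSimParams,
    "cyto": CytoSimParams,
    "enrichment": EnrichmentConfig,
    "qibc": QibcConfig,
    "coloc": ColocConfig,
}


def validate_config(path) -> RunConfig:
    """Load, type and validate a YAML config; unknown keys are errors.

    Every value not present in the file is recorded as a default in
    ``config.provenance`` (section.key -> "default" | "file").
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top_known = {f.name for f in fields(RunConfig)} - {"provenance"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    provenance: dict[str, str] = {}
    kwargs: dict = {}
    for key in ("outdir", "seed", "fold_threshold", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
            provenance[key] = "file"
        else:
            provenance[key] = "default"
    seed = int(kwargs.get("seed", 0))

    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        if name in ("proteomics", "imaging", "cyto") and "seed" not in section:
            # per-module seeds fan out deterministically from the global seed
            section = {**section, "seed": _child_seed(seed, name)}
        obj = _build(cls, section, f"section {name!r}")
        for f in fields(cls):
            provenance[f"{name}.{f.name}"] = (
                "file" if f.name in (raw.get(name) or {}) else "default"
            )
        kwargs[name] = obj

    cfg = _build(RunConfig, kwargs, "run config")
    object.__setattr__(cfg, "provenance", provenance)
    return cfg


def _child_seed(seed: int, name: str) -> int:
    import numpy as np

    digest = sum(ord(c) * 31**i for i, c in enumerate(name)) % (2**16)
    return int(np.random.SeedSequence([seed, digest]).generate_state(1)[0] % 2**31)


def default_config() -> RunConfig:
    return RunConfig()


def write_template(path) -> None:
    """Write a minimal commented config template."""
    Path(path).write_text(
        "# cfskit run configuration (all keys optional; defaults shown)\n"
        "outdir: cfs_run\n"
        "seed: 0\n"
        "fold_threshold: 1.5\n"
        "enrichment:\n  min_score: 0.4\n  alpha: 0.05\n"
        "coloc:\n  n_rand: 1000\n"
    )
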