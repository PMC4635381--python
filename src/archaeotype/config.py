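"""One run-configuration document for the whole pipeline.

A single schema-versioned JSON file carries every tunable parameter —
preprocessing, MSP construction, matching tolerance, clustering, biomarker
window — so a published run is reproducible from one artifact.  The shipped
defaults reproduce the standard fingerprinting parameter set literally:
S/N threshold 3, at most 100 peaks, peak width 5 m/z, smoothing width
5 m/z with 1 cycle, replicate reproducibility gate 0.6, 1% biomarker mass
window, score bands at 2.00 and 2.30.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .msp import MatchTolerance, MspBuildConfig
from .preprocess import PreprocessConfig

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClusteringConfig:
    linkage: str = "average"
    gel_bin_width: float = 10.0

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "single", "complete"):
            raise ConfigError(f"clustering.linkage: unknown method {self.linkage!r}")
        if self.gel_bin_width <= 0:
            raise ConfigError("clustering.gel_bin_width must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one validated document."""

    schema_version: int = SCHEMA_VERSION
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    msp: MspBuildConfig = field(default_factory=MspBuildConfig)
    tolerance: MatchTolerance = field(default_factory=MatchTolerance)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    biomarker_window_percent: float = 1.0

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"schema_version: unsupported value {self.schema_version!r} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        if self.biomarker_window_percent <= 0:
            raise ConfigError("biomarker_window_percent must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def sha256(self) -> str:
        """Hash of the canonical JSON form, for provenance blocks."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected an object")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown field")
    try:
        return cls(**data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "msp": MspBuildConfig,
    "tolerance": MatchTolerance,
    "clustering": ClusteringConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig; errors name the offending field path."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    known = set(_SECTIONS) | {"schema_version", "biomarker_window_percent"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown field")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name], name)
    for name in ("schema_version", "biomarker_window_percent"):
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run-configuration JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from None
    return config_from_dict(data)


def default_config() -> RunConfig:
    return RunConfig()


def provenance_block(config: RunConfig, inputs: dict | None = None) -> dict:
    """Provenance metadata embedded in every result file.

    Contains the package version, the config hash, and a SHA-256 per input
    file; no timestamps, so reruns are byte-identical.
    """
    input_hashes = {}
    for name, path in (inputs or {}).items():
        input_hashes[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return {
        "package_version": __version__,
        "config_sha256": config.sha256(),
        "inputs": input_hashes,
    }
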