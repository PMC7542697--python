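"""Workflow configuration with documented defaults.

All thresholds used anywhere in the pipeline live here so they can be
overridden from a single YAML file.  Unknown keys are rejected eagerly —
a typo in a config file must fail loudly, not silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from igkit.model import IgkitError


class ConfigError(IgkitError):
    pass


@dataclass
class QCConfig:
    min_phred: float = 12.0  # minimum mean Phred over the whole read
    min_len: int = 50  # minimum read length in nt


@dataclass
class AlignConfig:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    v_score_floor: float = 50.0  # below this, "no V gene"
    j_score_floor: float = 15.0
    d_min_run: int = 5  # min consecutive exact matches to report a D


@dataclass
class IsotypeConfig:
    min_aligned_len: int = 30  # nt of constant region that must align
    min_identity: float = 0.9
    kmer_size: int = 12
    # label -> k-mer; empty means "derive from the loaded constant references"
    kmer_tags: dict[str, str] = field(default_factory=dict)


@dataclass
class CompareConfig:
    primer_region_nt: int = 25  # window flagged as primer-influenced at each end
    low_quality_phred: int = 20  # diff positions below this are not trusted


@dataclass
class ColorConfig:
    green: str = "C6EFCE"
    red: str = "FFC7CE"
    brown: str = "D9B38C"


@dataclass
class SeqIOConfig:
    # Named groups mab_id and chain are required; chain must be heavy/kappa/lambda.
    filename_regex: str = r"(?P<mab_id>[^_]+)_(?P<chain>heavy|kappa|lambda).*"


@dataclass
class Config:
    qc: QCConfig = field(default_factory=QCConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    isotype: IsotypeConfig = field(default_factory=IsotypeConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    colors: ColorConfig = field(default_factory=ColorConfig)
    seqio: SeqIOConfig = field(default_factory=SeqIOConfig)


def _update_section(section: Any, values: dict[str, Any], path: str) -> None:
    valid = {f.name for f in dataclasses.fields(section)}
    for key, value in values.items():
        if key not in valid:
            raise ConfigError(f"unknown config key {path}.{key}")
        setattr(section, key, value)


def load_config(path: Optional[str | Path] = None) -> Config:
    """Build a Config from defaults, overlaying a YAML file if given."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    sections = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)}
    for name, values in data.items():
        if name not in sections:
            raise ConfigError(f"unknown config section {name!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        _update_section(sections[name], values, name)
    return cfg
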