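"""Run configuration: one YAML file mirroring the module sub-configs.

Every random draw in a run flows from ``RunConfig.seed`` through named
sub-seeds, so a run is reproducible from its logged config alone.  Unknown
keys are rejected by name; invalid values raise errors naming the offending
``section.field``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import RFConfig
from .features import BackboneSpec
from .lyrebird import LOAConfig
from .phantom import DEFAULT_CLASS_COUNTS, AugmentConfig
from .preprocess import RoiConfig

__all__ = ["CohortConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class CohortConfig:
    counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    size: int = 256
    modalities: tuple = ("t1", "t2", "ce")
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    modality: str = "t2"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    roi: RoiConfig = field(default_factory=RoiConfig)
    loa: LOAConfig = field(default_factory=LOAConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    split_fractions: tuple = (0.70, 0.15, 0.15)
    cv_folds: int = 5
    n_bootstrap: int = 1000
    #: free-form provenance block (e.g. a deep-training recipe recorded from
    #: an experiment log); stored and echoed verbatim, drives nothing.
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")


_SECTIONS = {
    "cohort": CohortConfig,
    "backbone": BackboneSpec,
    "roi": RoiConfig,
    "loa": LOAConfig,
    "rf": RFConfig,
    "augment": AugmentConfig,
}
_SCALARS = {"seed", "modality", "split_fractions", "cv_folds", "n_bootstrap",
            "provenance"}

_TUPLE_FIELDS = {"intensity_scale_range", "noise_sigma_range", "modalities",
                 "split_fractions"}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
    coerced = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
               for k, v in data.items()}
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid value in section {name!r}: {name}.{exc}") from exc


def load_config(path) -> RunConfig:
    """Parse a YAML run config; defaults fill unset fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key in _SCALARS & set(raw):
        v = raw[key]
        kwargs[key] = tuple(v) if key in _TUPLE_FIELDS and isinstance(v, list) else v
    for key, cls in _SECTIONS.items():
        if key in raw:
            kwargs[key] = _build_section(key, cls, raw[key] or {})
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
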