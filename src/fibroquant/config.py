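"""YAML configuration with a strict schema.

A config file holds one optional section per pipeline stage (``mt``,
``if``, ``qc``, ``stats``); omitted keys take the dataclass defaults,
unknown keys are rejected with the offending field path, and invariant
violations raised by the parameter dataclasses are reported with the same
path. ``save_config(load_config(x))`` is a normalized round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .mt import MTParams
from .ifq import IFParams
from .sc import QCParams

__all__ = ["StatsParams", "PipelineConfig", "load_config", "save_config"]


@dataclass
class StatsParams:
    """Options of the statistics helpers."""

    equal_var: bool = True  # pooled-variance Student's t-test; False = Welch
    n_repeats: int = 3
    livak_fold_change: bool = False  # report 2**(-ddCt) instead of 2**ddCt

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class PipelineConfig:
    mt: MTParams = field(default_factory=MTParams)
    if_: IFParams = field(default_factory=IFParams)
    qc: QCParams = field(default_factory=QCParams)
    stats: StatsParams = field(default_factory=StatsParams)

    _SECTIONS = {"mt": MTParams, "if": IFParams, "qc": QCParams, "stats": StatsParams}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"{path}.{key}: unknown key (expected one of {sorted(known)})")
        if isinstance(value, list):
            value = tuple(value) if known[key].name == "pca_components" else value
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def load_config(path: str | Path | None = None, text: str | None = None) -> PipelineConfig:
    """Parse and validate a YAML config; an empty file yields all defaults."""
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    sections = PipelineConfig._SECTIONS
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}; expected {sorted(sections)}")
    built = {}
    for name, cls in sections.items():
        attr = "if_" if name == "if" else name
        built[attr] = _build(cls, data.get(name, {}) or {}, name)
    return PipelineConfig(**built)


def save_config(cfg: PipelineConfig) -> str:
    """Serialize a config back to normalized YAML."""
    def clean(d: dict) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    data = {
        "mt": clean(asdict(cfg.mt)),
        "if": clean(asdict(cfg.if_)),
        "qc": clean(asdict(cfg.qc)),
        "stats": clean(asdict(cfg.stats)),
    }
    return yaml.safe_dump(data, sort_keys=True)
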