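"""Run configuration: YAML loading, defaults, and CLI-flag precedence."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .abm import ABMConfig
from .errors import FormatError, ParameterError
from .hierarchy import EloConfig
from .strategy import PermutationConfig, SplineConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings (exactly one of input_path / simulate)."""

    input_path: str | None = None
    simulate: ABMConfig | None = None
    group: str | None = None
    category: str | None = None
    elo: EloConfig = field(default_factory=EloConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    spline: SplineConfig = field(default_factory=SplineConfig)
    n_iterations: int = 500
    hier_fraction: float = 0.3
    difference_kind: str = "rank"
    n_boot: int = 1000
    output_dir: str = "domstrat_out"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ParameterError(
                "exactly one of input_path / simulate must be set"
            )
        if self.difference_kind not in ("rank", "score"):
            raise ParameterError("difference_kind must be 'rank' or 'score'")
        if not 0.0 < self.hier_fraction < 1.0:
            raise ParameterError("hier_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")


_SECTION_TYPES = {
    "simulate": ABMConfig,
    "elo": EloConfig,
    "permutation": PermutationConfig,
    "spline": SplineConfig,
}
_TOP_KEYS = {
    "input", "simulate", "group", "category", "elo", "permutation", "spline",
    "iterations", "hier_fraction", "difference", "n_boot", "output_dir",
    "seed",
}


def _build_section(cls, mapping: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise FormatError(
            f"unknown keys in section {where!r}: {sorted(unknown)}"
        )
    return cls(**mapping)


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over file values.

    Top-level keys: input (path) OR simulate (section), group, category,
    elo / permutation / spline (sections), iterations, hier_fraction,
    difference, n_boot, output_dir, seed. Unknown keys raise FormatError.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "input" in raw:
        kwargs["input_path"] = str(raw["input"])
    if "simulate" in raw:
        kwargs["simulate"] = _build_section(
            ABMConfig, dict(raw["simulate"] or {}), "simulate"
        )
    for key, target in (("group", "group"), ("category", "category"),
                        ("iterations", "n_iterations"),
                        ("hier_fraction", "hier_fraction"),
                        ("difference", "difference_kind"),
                        ("n_boot", "n_boot"), ("output_dir", "output_dir"),
                        ("seed", "seed")):
        if key in raw:
            kwargs[target] = raw[key]
    for section, cls in _SECTION_TYPES.items():
        if section in raw and section != "simulate":
            kwargs[section if section != "elo" else "elo"] = _build_section(
                cls, dict(raw[section] or {}), section
            )
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    if "input_path" not in kwargs and "simulate" not in kwargs:
        # no data source named: default to simulating the standard scenario
        kwargs["simulate"] = ABMConfig()
    return RunConfig(**kwargs)
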