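"""Pipeline configuration: a single YAML file, validated before anything runs.

Unknown keys are rejected outright so a typo cannot silently fall back to a
default, and value constraints (threshold ordering, positive rates, ...) are
checked up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

__all__ = ["GroupConfig", "PipelineConfig", "load_config", "validate_config"]


@dataclass(frozen=True)
class GroupConfig:
    """Per-group generative settings (deficiency shifts, composition rates)."""

    deficiency_shift_N: float = 0.0
    deficiency_shift_M: float = 0.0
    alpha_fraction: float = 0.07
    beta_fraction: float = 0.88
    bihormonal_fraction: float = 0.005
    ki67_rate_alpha: float = 0.002
    ki67_rate_beta: float = 0.002
    tunel_islet_rate: float = 0.02


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    reference_group: str = "WT"
    age: str = "44w"
    n_mice_per_group: int = 4
    islets_per_mouse: int = 50
    islets_per_mouse_composition: int = 25
    cells_per_islet: float = 120.0
    thresholds: tuple[float, float] = (-2.0, -3.0)
    core_erosion: float = 0.3
    pixel_size_um: float = 0.31
    summary_style: str = "mean_ci"
    groups: Mapping[str, GroupConfig] = field(
        default_factory=lambda: {
            "WT": GroupConfig(),
            "MUT": GroupConfig(
                deficiency_shift_N=2.5,
                deficiency_shift_M=0.5,
                alpha_fraction=0.24,
                beta_fraction=0.72,
                ki67_rate_alpha=0.008,
            ),
        }
    )

    @property
    def reference_selector(self) -> str:
        return f"genotype == '{self.reference_group}'"


def _check_keys(d: Mapping[str, Any], allowed: set[str], where: str) -> list[str]:
    unknown = set(d) - allowed
    return [f"unknown key {k!r} in {where}" for k in sorted(unknown)]


def validate_config(raw: Mapping[str, Any]) -> list[str]:
    """Return an itemised list of problems; empty means valid."""
    errors: list[str] = []
    top_allowed = {f for f in PipelineConfig.__dataclass_fields__}
    errors += _check_keys(raw, top_allowed, "config")
    for gname, gcfg in (raw.get("groups") or {}).items():
        if not isinstance(gcfg, Mapping):
            errors.append(f"group {gname!r} must be a mapping")
            continue
        errors += _check_keys(
            gcfg, set(GroupConfig.__dataclass_fields__), f"groups.{gname}"
        )
    thr = raw.get("thresholds")
    if thr is not None:
        if len(thr) != 2 or not thr[0] > thr[1]:
            errors.append(
                f"thresholds must be (low, deficient) with low > deficient, got {thr}"
            )
    for key, lo, hi in (("core_erosion", 0.0, 1.0), ("pixel_size_um", 0.0, float("inf"))):
        v = raw.get(key)
        if v is not None and not (lo <= v < hi if hi < float("inf") else v > lo):
            errors.append(f"{key} out of range: {v}")
    for key in ("n_mice_per_group", "islets_per_mouse", "islets_per_mouse_composition"):
        v = raw.get(key)
        if v is not None and (not isinstance(v, int) or v < 1):
            errors.append(f"{key} must be a positive integer, got {v!r}")
    if raw.get("reference_group") is not None and raw.get("groups") is not None:
        if raw["reference_group"] not in raw["groups"]:
            errors.append(f"reference_group {raw['reference_group']!r} not in groups")
    return errors


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Load and validate a YAML config; keyword overrides win over the file."""
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    problems = validate_config(raw)
    if problems:
        raise ConfigurationError("; ".join(problems))
    groups = {
        name: GroupConfig(**gcfg) for name, gcfg in (raw.pop("groups", None) or {}).items()
    }
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    cfg = PipelineConfig(**raw) if not groups else PipelineConfig(**raw, groups=groups)
    return cfg
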