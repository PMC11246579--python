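"""YAML configuration loading with workflow-style parameter aliases.

Config keys may use either the library's internal names or the
upper-case names familiar from capture-genotyping workflow config files
(``BED_MIN_MEAN_COV`` etc.).  Unknown keys are rejected by name rather
than silently ignored, since a typo in a threshold would otherwise
change results without warning.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Optional

import yaml

__all__ = ["ResolvedConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


# alias -> internal name
_ALIASES = {
    "BED_MIN_MEAN_COV": "min_mean_cov",
    "BED_MIN_DIST": "min_dist",
    "BED_MIN_LENGTH": "min_length",
    "REMOVE_DUP_MARKDUPLICATES": "drop_duplicates",
    "REQUIRE_PROPER_PAIR": "require_proper_pair",
    "DROP_SECONDARY_SUPPLEMENTARY": "drop_secondary_supplementary",
    "MIN_MAPQ": "min_mapq",
    "MIN_DP": "min_dp",
    "MIN_GQ": "min_gq",
    "MIN_QUAL": "min_qual",
    "MAX_F_MISSING": "max_f_missing",
    "MAX_SAMPLE_MISSING": "max_sample_missing",
    "BIALLELIC_ONLY": "biallelic_only",
    "MIN_FIS": "min_fis",
    "REQUIRE_MINOR_HOMOZYGOTE": "require_minor_homozygote",
}

_BOOL_FIELDS = {
    "drop_duplicates", "require_proper_pair", "drop_secondary_supplementary",
    "biallelic_only", "require_minor_homozygote",
}
_INT_FIELDS = {"min_dist", "min_length", "min_mapq", "min_dp", "min_gq"}
_FLOAT_FIELDS = {
    "min_mean_cov", "min_qual", "max_f_missing", "max_sample_missing", "min_fis",
}


@dataclass
class ResolvedConfig:
    """Union of the tunable parameters across all pipeline stages."""

    # zone calling
    min_mean_cov: float = 1.0
    min_dist: int = 100
    min_length: int = 100
    # alignment filtering
    drop_duplicates: bool = True
    require_proper_pair: bool = True
    drop_secondary_supplementary: bool = True
    min_mapq: Optional[int] = 30
    # VCF filtering cascade
    min_dp: Optional[int] = 5
    min_gq: Optional[int] = 15
    min_qual: Optional[float] = 30.0
    max_f_missing: Optional[float] = None
    max_sample_missing: Optional[float] = None
    biallelic_only: bool = True
    min_fis: Optional[float] = 0.8
    require_minor_homozygote: bool = True


def _coerce(name: str, value: Any) -> Any:
    if value is None:
        return None
    try:
        if name in _BOOL_FIELDS:
            if isinstance(value, bool):
                return value
            if isinstance(value, str) and value.upper() in ("TRUE", "FALSE"):
                return value.upper() == "TRUE"
            raise ValueError
        if name in _INT_FIELDS:
            if isinstance(value, bool) or int(value) != float(value):
                raise ValueError
            return int(value)
        if name in _FLOAT_FIELDS:
            return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"parameter {name!r}: cannot interpret value {value!r}")
    return value


def load_config(path) -> ResolvedConfig:
    """Load a YAML config, resolving workflow-style aliases; empty file -> defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    known = {f.name for f in fields(ResolvedConfig)}
    resolved: dict[str, Any] = {}
    for key, value in raw.items():
        name = _ALIASES.get(key, key)
        if name not in known:
            raise ConfigError(f"unknown configuration key {key!r}")
        resolved[name] = _coerce(name, value)
    return ResolvedConfig(**resolved)
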