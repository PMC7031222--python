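"""Run configuration: a validated, nested key-value file binding all stages.

The config is YAML with sections ``inputs``, ``thresholds``, ``policies``,
``method``, plus top-level ``seed`` and ``output_dir``.  Unknown keys are
rejected before any stage executes, and the resolved configuration (with the
tool version) is written into every output directory for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]

_SECTIONS = {
    "inputs": {
        "de_tables", "signatures_gmt", "ortholog_map", "profile_matrix",
        "annotations", "matrix_dialect", "values_are_ranks",
    },
    "thresholds": {"lfc_min", "q_max", "min_size", "max_size"},
    "policies": {"ortholog_policy"},
    "method": {"method", "budget", "integration"},
}
_TOP_LEVEL = set(_SECTIONS) | {"seed", "output_dir"}


@dataclass
class RunConfig:
    """All inputs, stage parameters and output location for one run."""

    profile_matrix: str
    annotations: str
    output_dir: str
    de_tables: Optional[list[str]] = None
    signatures_gmt: Optional[str] = None
    ortholog_map: Optional[str] = None
    matrix_dialect: str = "gct"
    values_are_ranks: Optional[bool] = None
    lfc_min: float = 1.0
    q_max: float = 0.05
    min_size: int = 10
    max_size: int = 500
    ortholog_policy: str = "expand"
    method: str = "auto"
    budget: int = 10**7
    integration: str = "rankprod"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.de_tables is None) == (self.signatures_gmt is None):
            raise ConfigError(
                "exactly one of inputs.de_tables / inputs.signatures_gmt "
                "must be given"
            )
        if self.matrix_dialect not in ("gct", "tsv"):
            raise ConfigError(f"unknown matrix_dialect {self.matrix_dialect!r}")
        if self.method not in ("exact", "gamma", "auto"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.integration not in ("rankprod", "fisher"):
            raise ConfigError(f"unknown integration {self.integration!r}")
        if self.ortholog_policy not in ("expand", "drop_ambiguous", "first"):
            raise ConfigError(f"unknown ortholog_policy {self.ortholog_policy!r}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
        flat: dict[str, Any] = {}
        for section, allowed in _SECTIONS.items():
            sub = raw.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(
                    f"unknown config key {section}.{sorted(bad)[0]}"
                )
            flat.update(sub)
        for key in ("seed", "output_dir"):
            if key in raw:
                flat[key] = raw[key]
        missing = {"profile_matrix", "annotations", "output_dir"} - set(flat)
        if missing:
            raise ConfigError(f"missing required config key {sorted(missing)[0]!r}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from None
        if not isinstance(raw, dict):
            raise ConfigError(f"config root in {path} must be a mapping")
        return cls.from_dict(raw)

    def ensure_output_dir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out

    def write_resolved(self, outdir: Path) -> None:
        from . import __version__

        resolved = {"tool_version": __version__, **asdict(self)}
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(resolved, sort_keys=True), encoding="utf-8"
        )
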