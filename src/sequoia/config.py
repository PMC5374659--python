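"""Flat dotted-key configuration with typed defaults.

All pipeline stages read their tunables from a single :class:`Config`
mapping of ``section.key`` strings. Values loaded from YAML files or
command-line overrides are coerced to the type of the built-in default.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "preprocess.threshold": 0.0,
    "preprocess.pseudo_sim_quantile": 0.0,
    "preprocess.enable_pseudo_edges": True,
    "csrw.tol": 1e-10,
    "csrw.max_iter": 10000,
    "csrw.laziness": 0.5,
    "seeds.n_q": None,  # None -> |V_Q|
    "extend.reduction": 0.05,
    "extend.cap_factor": 2.0,
    "prune.threshold": 0,
    "conductance.mode": "sequoia",
    "eval.match_threshold": 0.5,
    "eval.p_threshold": 0.05,
    "eval.ic_min": 2.0,
}


class ConfigError(ValueError):
    """Raised for unknown keys or values that cannot be coerced."""


def _coerce(key: str, value: Any) -> Any:
    default = DEFAULTS[key]
    if value is None or default is None:
        # seeds.n_q accepts None or an int
        if value is None:
            return None
        return int(value)
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        if str(value).lower() in {"true", "1", "yes"}:
            return True
        if str(value).lower() in {"false", "0", "no"}:
            return False
        raise ConfigError(f"cannot interpret {value!r} as a boolean for {key}")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return str(value)


class Config:
    """Dotted-key configuration mapping with defaults.

    >>> cfg = Config({"extend.reduction": 0.1})
    >>> cfg["extend.reduction"]
    0.1
    >>> cfg["extend.cap_factor"]
    2.0
    """

    def __init__(self, overrides: Mapping[str, Any] | None = None):
        self._values = dict(DEFAULTS)
        if overrides:
            for key, value in overrides.items():
                self.set(key, value)

    def set(self, key: str, value: Any) -> None:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        self._values[key] = _coerce(key, value)

    def __getitem__(self, key: str) -> Any:
        if key not in self._values:
            raise ConfigError(f"unknown configuration key: {key!r}")
        return self._values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self._values.get(key, default)

    def items(self):
        return self._values.items()

    @classmethod
    def from_yaml(cls, path) -> "Config":
        """Load overrides from a flat or nested ``key: value`` YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}

        def _flatten(prefix: str, obj: Any) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    _flatten(f"{prefix}.{k}" if prefix else str(k), v)
            else:
                flat[prefix] = obj

        _flatten("", raw)
        return cls(flat)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Config({self._values!r})"
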