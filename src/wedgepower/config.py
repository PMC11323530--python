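"""Configuration parsing, validation and result serialization.

Design configurations are plain YAML or JSON mappings mirroring
:class:`~wedgepower.design.DesignSpec`.  Effect sizes are accepted as odds
ratios by default (``theta1_or``, ``theta2_or``, ``theta3_or`` — converted
by natural log) or directly on the log-odds scale (``theta1`` etc.);
mixing the two scales for the same coefficient is rejected.  Validation is
exhaustive: every schema violation is reported, not just the first.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .design import ConfigurationError, DesignSpec

_REQUIRED = ("n_clusters", "n_periods", "cluster_size", "theta0", "gammas", "prevalence", "icc")
_OR_FIELDS = ("theta1", "theta2", "theta3")
_OPTIONAL = {
    "cac": 1.0,
    "sig_level": 0.05,
    "test": "wald_z",
    "t_df": None,
}
_KNOWN = set(_REQUIRED) | set(_OPTIONAL) | set(_OR_FIELDS) | {
    f + "_or" for f in _OR_FIELDS
} | {"theta0_or"}


def _coerce_effects(raw: dict, errors: list[str]) -> dict:
    out = {}
    for name in _OR_FIELDS:
        has_log = name in raw
        has_or = f"{name}_or" in raw
        if has_log and has_or:
            errors.append(f"give either {name} (log-odds) or {name}_or (odds ratio), not both")
        elif has_or:
            value = raw[f"{name}_or"]
            if not isinstance(value, (int, float)) or value <= 0:
                errors.append(f"{name}_or must be a positive number, got {value!r}")
            else:
                out[name] = math.log(value)
        elif has_log:
            out[name] = float(raw[name])
        else:
            out[name] = 0.0
    return out


def parse_config(raw: dict[str, Any]) -> DesignSpec:
    """Validate a raw mapping into a DesignSpec, reporting all violations."""
    errors: list[str] = []
    unknown = sorted(set(raw) - _KNOWN)
    if unknown:
        errors.append(f"unknown configuration keys: {', '.join(unknown)}")
    for key in _REQUIRED:
        if key not in raw:
            errors.append(f"missing required key: {key}")
    effects = _coerce_effects(raw, errors)
    if errors:
        raise ConfigurationError("; ".join(errors))
    kwargs = dict(
        n_clusters=raw["n_clusters"],
        n_periods=raw["n_periods"],
        cluster_size=raw["cluster_size"],
        theta0=float(raw["theta0"]),
        gammas=tuple(float(g) for g in raw["gammas"]),
        prevalence=float(raw["prevalence"]),
        icc=float(raw["icc"]),
        **effects,
    )
    for key, default in _OPTIONAL.items():
        kwargs[key] = raw.get(key, default)
    return DesignSpec(**kwargs)


def load_config(path: str | pathlib.Path) -> DesignSpec:
    """Load and validate a YAML or JSON design configuration file."""
    text = pathlib.Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return parse_config(raw)


def spec_to_dict(spec: DesignSpec) -> dict:
    d = asdict(spec)
    d["gammas"] = list(d["gammas"])
    return d


def write_results(result: Any, path: str | pathlib.Path, fmt: str | None = None) -> None:
    """Serialize a result (dataclass, mapping, or DataFrame) to CSV or JSON.

    Floats are written at full precision so that reading the file back
    reproduces the values exactly; any display rounding is the caller's
    concern.
    """
    path = pathlib.Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "csv"
    if isinstance(result, pd.DataFrame):
        df = result
    else:
        record = asdict(result) if hasattr(result, "__dataclass_fields__") else dict(result)
        for key, value in record.items():
            if isinstance(value, np.ndarray):
                record[key] = value.tolist()
        if fmt == "json":
            path.write_text(json.dumps(record, indent=2, default=float) + "\n")
            return
        df = pd.DataFrame([record])
    if fmt == "json":
        path.write_text(df.to_json(orient="records", indent=2, double_precision=15) + "\n")
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | pathlib.Path) -> Any:
    path = pathlib.Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path)
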