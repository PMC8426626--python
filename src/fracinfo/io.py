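"""CSV data input and model configuration files.

Data interchange is plain CSV with a configurable missing-value token
(default "NA"; empty cells are always treated as missing).  Model
configuration is YAML or JSON with a ``kind`` key; CFA blocks may be
given either as a factor -> indicators mapping or in the compact
measurement syntax ``F1 =~ x1 + x2 + x3`` (one factor per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .models import (
    ModelSpec,
    make_cfa_model,
    make_regression_model,
    make_saturated_model,
)


def read_data_csv(
    path, na_token: str = "NA", columns: list[str] | None = None
) -> pd.DataFrame:
    """Read a numeric data table; missing cells as ``na_token`` or empty."""
    df = pd.read_csv(path, na_values=[na_token], keep_default_na=False)
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ConfigurationError(f"columns not found in {path}: {sorted(missing)}")
        df = df.loc[:, columns]
    try:
        return df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(
            f"non-numeric cells in {path}; is the NA token ({na_token!r}) right?"
        ) from exc


def parse_cfa_syntax(text: str) -> dict[str, list[str]]:
    """Parse measurement-model lines of the form ``F1 =~ x1 + x2 + x3``."""
    factors: dict[str, list[str]] = {}
    for raw in text.strip().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" not in line:
            raise ConfigurationError(f"cannot parse model line: {raw!r}")
        lhs, rhs = line.split("=~", 1)
        name = lhs.strip()
        inds = [tok.strip() for tok in rhs.split("+")]
        if not name or any(not tok for tok in inds):
            raise ConfigurationError(f"cannot parse model line: {raw!r}")
        if name in factors:
            raise ConfigurationError(f"factor {name!r} defined twice")
        factors[name] = inds
    if not factors:
        raise ConfigurationError("model syntax defines no factors")
    return factors


def model_from_config(source) -> ModelSpec:
    """Build a ModelSpec from a config mapping or a YAML/JSON file path.

    Recognized keys: ``kind`` (saturated | regression | cfa); for
    saturated, ``p`` or ``variables``; for regression, optional
    ``variables`` (two names); for cfa, either ``factors`` (mapping) or
    ``model`` (measurement syntax), plus optional ``variables`` order.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            config = yaml.safe_load(text)
        except yaml.YAMLError:
            config = json.loads(text)
    else:
        config = source
    if not isinstance(config, dict) or "kind" not in config:
        raise ConfigurationError("model config must be a mapping with a 'kind' key")
    kind = config["kind"]
    variables = config.get("variables")
    if kind == "saturated":
        if variables:
            return make_saturated_model(len(variables), tuple(variables))
        if "p" not in config:
            raise ConfigurationError("saturated model config needs 'p' or 'variables'")
        return make_saturated_model(int(config["p"]))
    if kind == "regression":
        if variables:
            if len(variables) != 2:
                raise ConfigurationError("regression needs exactly two variables")
            return make_regression_model(tuple(variables))
        return make_regression_model()
    if kind == "cfa":
        if "factors" in config:
            factors = {f: list(v) for f, v in config["factors"].items()}
        elif "model" in config:
            factors = parse_cfa_syntax(config["model"])
        else:
            raise ConfigurationError("cfa config needs 'factors' or 'model'")
        return make_cfa_model(factors, tuple(variables) if variables else None)
    raise ConfigurationError(f"unknown model kind {kind!r}")
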