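"""Plain-text (YAML) configuration round-trip for model and cost inputs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml

from .costing import CostParams
from .model_core import ConfigurationError, ModelParameters, config_digest


def parameters_to_dict(params: ModelParameters, costs: Optional[CostParams] = None) -> dict:
    payload: dict = {"model": params.to_dict()}
    if costs is not None:
        payload["costs"] = costs.to_dict()
    return payload


def save_parameters(path, params: ModelParameters, costs: Optional[CostParams] = None) -> str:
    """Write a parameter file; returns its content digest."""
    payload = parameters_to_dict(params, costs)
    digest = config_digest(payload)
    text = yaml.safe_dump(payload, sort_keys=True)
    Path(path).write_text(f"# remisim parameter file (digest {digest})\n{text}")
    return digest


def load_parameters(path) -> Tuple[ModelParameters, CostParams, str]:
    """Read a parameter file: (model parameters, cost parameters, digest).

    A file without a ``costs`` block falls back to the published base-case
    cost inputs.
    """
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "model" not in payload:
        raise ConfigurationError(f"{path}: not a remisim parameter file")
    params = ModelParameters.from_dict(payload["model"])
    costs = CostParams.from_dict(payload["costs"]) if "costs" in payload else CostParams()
    return params, costs, config_digest(parameters_to_dict(params, costs))
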