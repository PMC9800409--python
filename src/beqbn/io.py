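"""Reading and writing network specification files.

A network spec is a small YAML (or JSON, which YAML subsumes) mapping:

.. code-block:: yaml

    prior_a1: 0.5
    p_b1_given_a1: 0.97
    p_b1_given_a2: 0.84
    labels:            # optional
      a: [defect, cooperate]
      b: [defect, cooperate]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .network import TwoStageNetwork

__all__ = [
    "NetworkSpecError",
    "parse_network_spec",
    "network_from_mapping",
    "network_to_mapping",
    "write_network_spec",
]

REQUIRED_KEYS = ("prior_a1", "p_b1_given_a1", "p_b1_given_a2")


class NetworkSpecError(ValueError):
    """A network spec file is malformed, incomplete, or out of range."""


def network_from_mapping(data) -> TwoStageNetwork:
    """Build a validated network from a parsed spec mapping."""
    if not isinstance(data, dict):
        raise NetworkSpecError(
            f"malformed network spec: expected a mapping, got {type(data).__name__}"
        )
    missing = [k for k in REQUIRED_KEYS if k not in data]
    if missing:
        raise NetworkSpecError(f"network spec missing required key(s): {', '.join(missing)}")
    labels = data.get("labels")
    if labels is not None:
        try:
            labels = (tuple(labels["a"]), tuple(labels["b"]))
        except (TypeError, KeyError) as exc:
            raise NetworkSpecError(
                "malformed labels: expected mapping with 'a' and 'b' outcome pairs"
            ) from exc
    try:
        return TwoStageNetwork(
            p_a1=data["prior_a1"],
            p_b1_given_a1=data["p_b1_given_a1"],
            p_b1_given_a2=data["p_b1_given_a2"],
            labels=labels,
        )
    except (TypeError, ValueError) as exc:
        raise NetworkSpecError(f"invalid probability in network spec: {exc}") from exc


def parse_network_spec(path) -> TwoStageNetwork:
    """Parse and validate a network spec file (YAML or JSON)."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkSpecError(f"malformed network spec file {path}: {exc}") from exc
    return network_from_mapping(data)


def network_to_mapping(net: TwoStageNetwork) -> dict:
    """Serializable mapping; round-trips through ``network_from_mapping``."""
    data = {
        "prior_a1": net.p_a1,
        "p_b1_given_a1": net.p_b1_given_a1,
        "p_b1_given_a2": net.p_b1_given_a2,
    }
    if net.labels is not None:
        data["labels"] = {"a": list(net.labels[0]), "b": list(net.labels[1])}
    return data


def write_network_spec(net: TwoStageNetwork, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(network_to_mapping(net), sort_keys=False), encoding="utf-8"
    )
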