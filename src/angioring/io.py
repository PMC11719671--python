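"""Serialisation: network JSON, tidy measurement CSV, configs, run manifests.

Network JSON schema (all coordinates in micrometres)::

    {
      "ring": {"center": [x, y], "radius": r}            # or "boundary": [[x,y],...]
      "segments": [
        {"id": "...", "kind": "initial"|"branch",
         "parent_id": null|"...", "polyline": [[x, y], ...]},
        ...
      ]
    }

The measurement CSV is the tidy long table with columns
``donor,group,ring_id,day,imaging_time_h,parameter,category,value,units``;
missing (undefined) values are empty cells, never zeros.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aai import AaiConfig
from .model import RingExplant, VesselNetwork, VesselSegment
from .simulate import GrowthParams, SimulationConfig
from .tables import TABLE_COLUMNS

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network_json",
    "load_network_json",
    "save_measurements_csv",
    "load_measurements_csv",
    "load_aai_config",
    "load_simulation_config",
    "RunManifest",
]


def network_to_dict(net: VesselNetwork) -> dict:
    ring: dict = {"center": list(map(float, net.ring.center))}
    if net.ring.radius is not None:
        ring["radius"] = float(net.ring.radius)
    else:
        ring["boundary"] = np.asarray(net.ring.boundary, dtype=float).tolist()
    return {
        "ring": ring,
        "segments": [
            {
                "id": s.id,
                "kind": s.kind,
                "parent_id": s.parent_id,
                "generation": s.generation,
                "polyline": np.asarray(s.polyline, dtype=float).tolist(),
            }
            for s in net.segments.values()
        ],
    }


def network_from_dict(d: dict) -> VesselNetwork:
    try:
        ring_d = d["ring"]
        ring = RingExplant(
            center=tuple(ring_d.get("center", (0.0, 0.0))),
            radius=ring_d.get("radius"),
            boundary=(
                np.asarray(ring_d["boundary"], dtype=float)
                if "boundary" in ring_d
                else None
            ),
        )
        net = VesselNetwork(ring=ring, segments={})
        for sd in d.get("segments", []):
            net.segments[sd["id"]] = VesselSegment(
                id=sd["id"],
                polyline=np.asarray(sd["polyline"], dtype=float),
                kind=sd["kind"],
                parent_id=sd.get("parent_id"),
                generation=int(sd.get("generation", 0)),
            )
    except KeyError as exc:
        raise ValueError(f"network JSON missing required field: {exc}") from exc
    net.validate()
    return net


def save_network_json(net: VesselNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh)


def load_network_json(path) -> VesselNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def save_measurements_csv(table: pd.DataFrame, path) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def load_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"donor": str, "group": str, "ring_id": str})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df[TABLE_COLUMNS]


def _load_config_file(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_aai_config(path) -> AaiConfig:
    """AAI config from YAML/JSON; unknown keys are rejected with their path."""
    data = _load_config_file(path) or {}
    known = set(AaiConfig.__dataclass_fields__)
    for key in data:
        if key not in known:
            raise ValueError(f"aai config: unknown field {key!r}")
    return AaiConfig(**data)


def load_simulation_config(path) -> SimulationConfig:
    data = _load_config_file(path) or {}
    for side in ("params_control", "params_treatment"):
        if side in data:
            known = set(GrowthParams.__dataclass_fields__)
            for key in data[side]:
                if key not in known:
                    raise ValueError(f"simulation config: unknown field {side}.{key!r}")
            if "branch_angle_deg" in data[side]:
                data[side]["branch_angle_deg"] = tuple(data[side]["branch_angle_deg"])
            data[side] = GrowthParams(**data[side])
    known = set(SimulationConfig.__dataclass_fields__)
    for key in data:
        if key not in known:
            raise ValueError(f"simulation config: unknown field {key!r}")
    if "days" in data:
        data["days"] = tuple(data["days"])
    return SimulationConfig(**data)


@dataclass
class RunManifest:
    """Provenance record written by every CLI run."""

    command: str
    inputs: list[str]
    rng_seed: int | None
    config_sha256: str | None
    tool_version: str = ""
    started_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def config_hash(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
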