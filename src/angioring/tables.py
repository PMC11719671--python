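"""Tidy parameter tables: the bridge from networks to AAI scoring.

The canonical long format has one row per (donor, group, ring, day,
parameter) with columns::

    donor, group, ring_id, day, imaging_time_h, parameter, category, value, units

Growth-speed parameters compare consecutive imaging days of the same ring
and are attributed to the later day of each interval, so a day-4 speed
covers day 1 -> 4 and a day-7 speed covers day 4 -> 7.
"""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd

from .metrics import PARAMETER_REGISTRY, growth_speeds, quantify
from .model import ExplantObservation, UndefinedParameterError

__all__ = ["TABLE_COLUMNS", "records_to_frame", "quantify_experiment"]

TABLE_COLUMNS = [
    "donor",
    "group",
    "ring_id",
    "day",
    "imaging_time_h",
    "parameter",
    "category",
    "value",
    "units",
]


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df[TABLE_COLUMNS]


def quantify_experiment(
    observations: list[ExplantObservation],
    merge_tol: float = 5.0,
    include_auxiliary: bool = False,
    include_speeds: bool = True,
) -> pd.DataFrame:
    """Quantify every observation and assemble the tidy parameter table."""
    records = []
    for obs in observations:
        records.extend(quantify(obs, merge_tol, include_auxiliary))
    rows = [asdict(r) for r in records]

    if include_speeds:
        by_ring: dict[tuple[str, str, str], list[ExplantObservation]] = {}
        for obs in observations:
            by_ring.setdefault((obs.donor, obs.group, obs.ring_id), []).append(obs)
        for key, series in by_ring.items():
            series.sort(key=lambda o: o.imaging_time_h)
            for early, late in zip(series[:-1], series[1:]):
                try:
                    sp = growth_speeds(early, late)
                    mean_v, max_v = sp["mean_um_per_day"], sp["max_um_per_day"]
                except UndefinedParameterError:
                    mean_v = max_v = float("nan")
                for name, value in (
                    ("speed_mean_initial_length", mean_v),
                    ("speed_max_initial_length", max_v),
                ):
                    cat, units = PARAMETER_REGISTRY[name]
                    rows.append(
                        dict(
                            donor=late.donor,
                            group=late.group,
                            ring_id=late.ring_id,
                            day=late.day,
                            imaging_time_h=late.imaging_time_h,
                            parameter=name,
                            category=cat,
                            value=value,
                            units=units,
                        )
                    )

    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    return df.sort_values(
        ["group", "donor", "ring_id", "day", "parameter"], kind="stable"
    ).reset_index(drop=True)
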