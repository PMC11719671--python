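"""Angiogenic Activity Index (AAI) and the angiogenic profile.

The AAI expresses the change of an assay parameter under treatment relative
to its change under the control condition, between an early and a late day
of treatment (default days 4 and 7)::

    AAI = ((T_late - T_early) - (C_late - C_early)) / (C_late - C_early)

so 0 means control-like behaviour, +1 means the treatment change doubled
the control change, and -1 means no change under treatment while the control
changed.  Because the index is a ratio of differences it is invariant to
affine rescaling of a parameter's units.

Per-parameter values are aggregated into four weighted subindices (explant,
pattern, network properties, sprouting) and the final AAI is the mean of the
subindices.  The subindex uses the *literal* form (1/n) * sum(w_i * AAI_i)
by default: with predictive-importance weights above 1 the subindex can then
leave the unit range, which is what allows strongly pro-angiogenic samples
to score above 1.  A weight-normalised variant is available for sensitivity
analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import CATEGORY_ORDER, PARAMETER_REGISTRY

__all__ = [
    "AaiConfig",
    "AaiReport",
    "DegenerateControlError",
    "MissingControlError",
    "parameter_aai",
    "subindex_aai",
    "final_aai",
    "compute_report",
    "build_profile",
    "AngiogenicProfile",
]

logger = logging.getLogger(__name__)


class DegenerateControlError(ValueError):
    """The control group did not change between the two scoring days."""


class MissingControlError(ValueError):
    """The parameter table lacks control rows at one of the scoring days."""


def _default_categories() -> dict[str, str]:
    # circumference is a covariate of the explant, not a scored parameter
    return {
        name: cat
        for name, (cat, _units) in PARAMETER_REGISTRY.items()
        if name != "circumference"
    }


@dataclass
class AaiConfig:
    """Scoring configuration.

    ``weights`` holds predictive-importance factors (default 1 for every
    parameter); ``orientation`` (+1/-1) lets users flip the sign of
    parameters they consider anti-angiogenic when increasing.  Parameters
    are scored only if they appear in ``categories``.
    """

    weights: dict[str, float] = field(default_factory=dict)
    orientation: dict[str, int] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=_default_categories)
    day_early: int = 4
    day_late: int = 7
    control_group: str = "control"
    subindex_mode: str = "literal"  # literal | normalized
    aggregation: str = "per_donor"  # per_donor | pooled
    degenerate_policy: str = "error"  # error | epsilon | drop
    epsilon: float = 1e-9
    degenerate_rel_tol: float = 0.0  # |dC| below this fraction of the control
    # level counts as degenerate too; 0 = exact zeros only

    def __post_init__(self) -> None:
        if self.day_late <= self.day_early:
            raise ValueError("day_late must be after day_early")
        if self.subindex_mode not in ("literal", "normalized"):
            raise ValueError(f"unknown subindex mode {self.subindex_mode!r}")
        if self.aggregation not in ("per_donor", "pooled"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.degenerate_policy not in ("error", "epsilon", "drop"):
            raise ValueError(f"unknown degenerate policy {self.degenerate_policy!r}")
        for w in self.weights.values():
            if w <= 0:
                raise ValueError("predictive importance factors must be positive")

    def weight(self, parameter: str) -> float:
        return float(self.weights.get(parameter, 1.0))

    def orient(self, parameter: str) -> int:
        return int(self.orientation.get(parameter, +1))

    @classmethod
    def simulation_default(cls, **kwargs) -> "AaiConfig":
        """Config for simulator-driven runs.

        Migration is excluded from the scored set: in the outgrowth
        simulator every ring sprouts by day 4, so the control migration
        fraction cannot change between the scoring days.
        """
        cats = _default_categories()
        cats.pop("migration", None)
        kwargs.setdefault("categories", cats)
        kwargs.setdefault("degenerate_policy", "drop")
        # a control change within 2% of the control level is statistically
        # indistinguishable from no change at simulated sample sizes, and
        # dividing by it would manufacture arbitrarily large indices
        kwargs.setdefault("degenerate_rel_tol", 0.02)
        return cls(**kwargs)


@dataclass
class AaiReport:
    """Per-parameter AAIs, subindex values and the final AAI of one group."""

    group: str
    per_parameter_aai: dict[str, float]
    subindex_values: dict[str, float]
    final_aai: float
    aggregation: str
    n_donors: int
    dropped_parameters: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "per_parameter_aai": self.per_parameter_aai,
            "subindex_values": self.subindex_values,
            "final_aai": self.final_aai,
            "aggregation": self.aggregation,
            "n_donors": self.n_donors,
            "dropped_parameters": self.dropped_parameters,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def parameter_aai(
    t_early: float,
    t_late: float,
    c_early: float,
    c_late: float,
    orientation: int = +1,
    degenerate_policy: str = "error",
    epsilon: float = 1e-9,
    degenerate_rel_tol: float = 0.0,
    parameter: str = "<unnamed>",
) -> float:
    """AAI of one parameter from its treatment and control values.

    The control change in the denominator is degenerate when it is exactly
    zero or, with ``degenerate_rel_tol`` > 0, smaller than that fraction of
    the control level -- a stagnating control cannot normalise a treatment
    effect.
    """
    dt = t_late - t_early
    dc = c_late - c_early
    scale = max(abs(c_early), abs(c_late))
    if dc == 0 or abs(dc) <= degenerate_rel_tol * scale:
        if degenerate_policy == "error":
            raise DegenerateControlError(
                f"control change is zero for parameter {parameter!r}"
            )
        if degenerate_policy == "drop":
            return float("nan")
        dc = epsilon
    return orientation * (dt - dc) / dc


def subindex_aai(
    aai_values, weights=None, mode: str = "literal"
) -> float:
    """Weighted aggregate of the parameter AAIs of one category."""
    values = np.asarray(list(aai_values), dtype=float)
    if values.size == 0:
        raise ValueError("subindex of an empty parameter list is undefined")
    w = (
        np.ones_like(values)
        if weights is None
        else np.asarray(list(weights), dtype=float)
    )
    if w.shape != values.shape:
        raise ValueError("weights and AAI values must have equal length")
    if mode == "literal":
        return float(np.sum(w * values) / values.size)
    if mode == "normalized":
        return float(np.sum(w * values) / np.sum(w))
    raise ValueError(f"unknown subindex mode {mode!r}")


def final_aai(subindices: dict[str, float]) -> float:
    """Mean of the available subindex values."""
    vals = [v for v in subindices.values() if np.isfinite(v)]
    if not vals:
        raise ValueError("no subindex values available")
    if len(vals) < len(subindices):
        missing = [k for k, v in subindices.items() if not np.isfinite(v)]
        logger.warning("final AAI excludes undefined subindices: %s", missing)
    return float(np.mean(vals))


def _group_day_means(df: pd.DataFrame, by_donor: bool) -> pd.DataFrame:
    keys = ["group", "parameter", "day"] + (["donor"] if by_donor else [])
    return df.groupby(keys, as_index=False)["value"].mean()


def compute_report(table: pd.DataFrame, group: str, config: AaiConfig) -> AaiReport:
    """Score one treatment group against the control group.

    ``per_donor`` aggregation computes the AAI separately for each donor
    (treatment vs. that donor's control rings) and then averages across
    donors; ``pooled`` takes group means over all rings first.
    """
    df = table[table["day"].isin([config.day_early, config.day_late])]
    scored = [p for p in config.categories if p in set(df["parameter"])]
    if not scored:
        raise ValueError("no scored parameters present in the table")
    df = df[df["parameter"].isin(scored)]

    ctrl = df[df["group"] == config.control_group]
    trt = df[df["group"] == group]
    for day in (config.day_early, config.day_late):
        if ctrl[ctrl["day"] == day].empty:
            raise MissingControlError(f"no control rows at day {day}")
        if trt[trt["day"] == day].empty:
            raise ValueError(f"no rows for group {group!r} at day {day}")

    per_donor = config.aggregation == "per_donor"
    means = _group_day_means(df, by_donor=per_donor)

    def cell(frame, g, p, day, donor=None):
        m = (frame["group"] == g) & (frame["parameter"] == p) & (frame["day"] == day)
        if donor is not None:
            m &= frame["donor"] == donor
        vals = frame.loc[m, "value"]
        return float(vals.iloc[0]) if len(vals) else float("nan")

    per_param: dict[str, float] = {}
    dropped: list[str] = []
    donors = sorted(trt["donor"].unique()) if per_donor else [None]
    for p in scored:
        vals = []
        for donor in donors:
            te = cell(means, group, p, config.day_early, donor)
            tl = cell(means, group, p, config.day_late, donor)
            ce = cell(means, config.control_group, p, config.day_early, donor)
            cl = cell(means, config.control_group, p, config.day_late, donor)
            if not all(np.isfinite(v) for v in (te, tl, ce, cl)):
                continue
            vals.append(
                parameter_aai(
                    te,
                    tl,
                    ce,
                    cl,
                    orientation=config.orient(p),
                    degenerate_policy=config.degenerate_policy,
                    epsilon=config.epsilon,
                    degenerate_rel_tol=config.degenerate_rel_tol,
                    parameter=p,
                )
            )
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            per_param[p] = float(np.mean(vals))
        else:
            dropped.append(p)
            logger.warning(
                "parameter %r dropped from AAI for group %r (undefined or "
                "degenerate control change)",
                p,
                group,
            )

    subindices: dict[str, float] = {}
    for cat in CATEGORY_ORDER:
        members = [p for p in per_param if config.categories[p] == cat]
        if members:
            subindices[cat] = subindex_aai(
                [per_param[p] for p in members],
                [config.weight(p) for p in members],
                mode=config.subindex_mode,
            )
    return AaiReport(
        group=group,
        per_parameter_aai=per_param,
        subindex_values=subindices,
        final_aai=final_aai(subindices),
        aggregation=config.aggregation,
        n_donors=len(set(trt["donor"])),
        dropped_parameters=dropped,
    )


@dataclass
class AngiogenicProfile:
    """Radar-chart layout of per-parameter AAIs grouped by subindex category."""

    group: str
    parameters: list[str]
    values: list[float]
    categories: list[str]
    category_spans: dict[str, tuple[int, int]]  # category -> [start, stop) index

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "parameters": self.parameters,
            "values": self.values,
            "categories": self.categories,
            "category_spans": {k: list(v) for k, v in self.category_spans.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def render(self, path, title: str | None = None) -> None:
        """Render the profile as a radar (spider) chart to SVG or PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.parameters)
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
        vals = np.asarray(self.values, dtype=float)
        fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(7, 7))
        closed_a = np.concatenate([angles, angles[:1]])
        closed_v = np.concatenate([vals, vals[:1]])
        ax.plot(closed_a, closed_v, lw=1.5)
        ax.fill(closed_a, closed_v, alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(self.parameters, fontsize=7)
        # zero circle = control level
        ax.plot(np.linspace(0, 2 * np.pi, 200), np.zeros(200), "k--", lw=0.8)
        for cat, (start, stop) in self.category_spans.items():
            mid = angles[(start + stop - 1) // 2]
            ax.annotate(
                cat.replace("_", " "),
                xy=(mid, ax.get_ylim()[1]),
                ha="center",
                fontsize=9,
                fontweight="bold",
            )
        ax.set_title(title or f"Angiogenic profile: {self.group}")
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)


def build_profile(report: AaiReport, config: AaiConfig) -> AngiogenicProfile:
    """Order the per-parameter AAIs by subindex category for the radar chart."""
    params: list[str] = []
    cats: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for cat in CATEGORY_ORDER:
        members = [
            p for p in report.per_parameter_aai if config.categories.get(p) == cat
        ]
        if members:
            spans[cat] = (len(params), len(params) + len(members))
            params.extend(sorted(members))
            cats.extend([cat] * len(members))
    return AngiogenicProfile(
        group=report.group,
        parameters=params,
        values=[report.per_parameter_aai[p] for p in params],
        categories=cats,
        category_spans=spans,
    )
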