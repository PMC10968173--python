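"""Progression labelling for knee osteoarthritis cohorts.

A knee followed at months 0, 24 and 48 is classified from two rule-based
definitions:

* **Radiographic progression** — the medial (or lateral) joint space width
  (JSW) loses *less than* 0.7 mm over the first 24 months but *at least*
  0.7 mm between months 24 and 48, i.e. structural narrowing that accelerates
  in the second period.
* **Symptomatic progression** — the normalised WOMAC pain score (0-100)
  worsens by *less than* 9 points in the first period but by *at least*
  9 points in the second.

Four mutually exclusive groups follow: (1) radio-symptomatic progressors
(both rules met on the index knee, medial plateau), (2) radiographic-only,
(3) symptomatic-only, and (4) non-progressors, defined stringently as no
radiographic progression in either tibial plateau *and* no symptomatic
progression in either the index or the contralateral knee. Knees matching no
definition (e.g. lateral-only structural progression) are marked excluded.

Case/control scenarios built on the groups:

===========  ======================  =======================
scenario     cases                   controls
===========  ======================  =======================
primary      group 1                 groups 2, 3, 4
s1 (any)     groups 1, 2, 3          group 4
s2 (all)     groups 2, 3             group 4
s3 (radio)   group 2                 groups 3, 4
s4 (sympt)   group 3                 groups 2, 4
===========  ======================  =======================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "JSW_LOSS_THRESHOLD_MM",
    "PAIN_INCREASE_THRESHOLD",
    "SCENARIOS",
    "OutcomeTrajectories",
    "ProgressionStatus",
    "radiographic_progression",
    "symptomatic_progression",
    "assign_group",
    "label_cohort",
    "build_scenario",
    "scenario_mask",
]

JSW_LOSS_THRESHOLD_MM = 0.7
PAIN_INCREASE_THRESHOLD = 9.0

SCENARIOS = ("primary", "s1", "s2", "s3", "s4")

#: case groups and control groups per scenario
_SCENARIO_GROUPS: dict[str, tuple[set[int], set[int]]] = {
    "primary": ({1}, {2, 3, 4}),
    "s1": ({1, 2, 3}, {4}),
    "s2": ({2, 3}, {4}),
    "s3": ({2}, {3, 4}),
    "s4": ({3}, {2, 4}),
}


@dataclass(frozen=True)
class OutcomeTrajectories:
    """Longitudinal outcomes of one knee at months 0, 24 and 48.

    JSW values are millimetres (medial and lateral tibial plateau of the
    index knee); pain values are normalised WOMAC pain scores in [0, 100]
    for the index and contralateral knees.
    """

    jsw_medial_mm: tuple[float, float, float]
    jsw_lateral_mm: tuple[float, float, float]
    pain_index: tuple[float, float, float]
    pain_contra: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("jsw_medial_mm", "jsw_lateral_mm"):
            if any(v < 0 for v in getattr(self, name)):
                raise ParameterError(f"{name} must be non-negative")
        for name in ("pain_index", "pain_contra"):
            if any(not 0 <= v <= 100 for v in getattr(self, name)):
                raise ParameterError(f"{name} must lie in [0, 100]")


@dataclass(frozen=True)
class ProgressionStatus:
    """The four progression flags and the resulting group of one knee."""

    rad_medial: bool
    rad_lateral: bool
    symp_index: bool
    symp_contra: bool
    group: int | str  # 1..4 or "excluded"


def radiographic_progression(jsw0: float, jsw24: float, jsw48: float) -> bool:
    """Late-accelerating JSW loss: < 0.7 mm in months 0-24, >= 0.7 mm in 24-48."""
    for v in (jsw0, jsw24, jsw48):
        if v < 0:
            raise ParameterError("joint space widths must be non-negative")
    return (jsw0 - jsw24 < JSW_LOSS_THRESHOLD_MM) and (
        jsw24 - jsw48 >= JSW_LOSS_THRESHOLD_MM
    )


def symptomatic_progression(p0: float, p24: float, p48: float) -> bool:
    """Late-accelerating pain worsening: < 9 points in 0-24, >= 9 in 24-48."""
    for v in (p0, p24, p48):
        if not 0 <= v <= 100:
            raise ParameterError("pain scores must lie in [0, 100]")
    return (p24 - p0 < PAIN_INCREASE_THRESHOLD) and (
        p48 - p24 >= PAIN_INCREASE_THRESHOLD
    )


def assign_group(traj: OutcomeTrajectories) -> ProgressionStatus:
    """Compute the four progression flags of one knee and its group.

    The case-defining radiographic criterion uses the medial plateau; the
    lateral plateau and the contralateral knee's pain enter only the
    non-progressor (group 4) definition.
    """
    rad_medial = radiographic_progression(*traj.jsw_medial_mm)
    rad_lateral = radiographic_progression(*traj.jsw_lateral_mm)
    symp_index = symptomatic_progression(*traj.pain_index)
    symp_contra = symptomatic_progression(*traj.pain_contra)

    if rad_medial and symp_index:
        group: int | str = 1
    elif rad_medial:
        group = 2
    elif symp_index:
        group = 3
    elif not (rad_lateral or symp_contra):
        group = 4
    else:
        group = "excluded"
    return ProgressionStatus(rad_medial, rad_lateral, symp_index, symp_contra, group)


_TRAJ_COLS = {
    "jsw_medial_mm": ("jsw_med_0", "jsw_med_24", "jsw_med_48"),
    "jsw_lateral_mm": ("jsw_lat_0", "jsw_lat_24", "jsw_lat_48"),
    "pain_index": ("pain_idx_0", "pain_idx_24", "pain_idx_48"),
    "pain_contra": ("pain_con_0", "pain_con_24", "pain_con_48"),
}


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the progression rules to every row of a cohort table.

    Returns a copy with columns ``rad_medial``, ``rad_lateral``,
    ``symp_index``, ``symp_contra`` and ``group`` (re)computed from the
    trajectory columns ``jsw_med_*``, ``jsw_lat_*``, ``pain_idx_*``,
    ``pain_con_*``.
    """
    out = cohort.copy()
    statuses = [
        assign_group(
            OutcomeTrajectories(
                **{
                    field: tuple(row[c] for c in cols)
                    for field, cols in _TRAJ_COLS.items()
                }
            )
        )
        for _, row in cohort.iterrows()
    ]
    out["rad_medial"] = [s.rad_medial for s in statuses]
    out["rad_lateral"] = [s.rad_lateral for s in statuses]
    out["symp_index"] = [s.symp_index for s in statuses]
    out["symp_contra"] = [s.symp_contra for s in statuses]
    out["group"] = [s.group for s in statuses]
    return out


def scenario_mask(groups: np.ndarray | pd.Series, scenario: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (case, control) masks for *scenario* over an array of group ids."""
    if scenario not in _SCENARIO_GROUPS:
        raise ParameterError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    groups = np.asarray(groups)
    case_groups, control_groups = _SCENARIO_GROUPS[scenario]
    case = np.isin(groups, list(case_groups))
    control = np.isin(groups, list(control_groups))
    return case, control


def build_scenario(
    groups: pd.Series | dict | np.ndarray, scenario: str
) -> tuple[list, list]:
    """Split knee ids into (case ids, control ids) for one scenario.

    *groups* maps knee id -> group (a Series, dict, or array indexed by
    position); ids in neither set (group 1 under s2-s4) are dropped.
    Every id must carry a group in {1, 2, 3, 4} — excluded knees are removed
    beforehand.
    """
    series = pd.Series(groups)
    bad = series[~series.isin([1, 2, 3, 4])]
    if len(bad):
        raise ParameterError(
            f"ids {list(bad.index[:5])} have group outside {{1,2,3,4}}; "
            "drop excluded knees first"
        )
    case, control = scenario_mask(series.to_numpy(), scenario)
    return list(series.index[case]), list(series.index[control])
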