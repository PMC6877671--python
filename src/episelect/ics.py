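"""Intracellular-cytokine-staining (ICS) positivity criteria and
longitudinal response classification.

After in vitro stimulation of PBMCs with a candidate peptide, five
activation parameters are read out per T cell subset (CD4+/CD8+): IFNg, TNF
and IL-2 production plus CD107a and CD154 upregulation. A marker is
positive versus the matched negative control (DMSO, no stimulation) when

I.  the percentage of marker-positive cells is at least ``min_fold`` (2x)
    the control percentage, and
II. the marker-positive *event count* exceeds the control count by at least
    ``min_excess`` (20) cells

and a stimulus is positive at a timepoint when at least two of the five
markers are positive (criterion III). Criterion II deliberately subtracts
raw gated event counts, not percentages.

Across timepoints a stimulus is classified as absent, induced (negative
before treatment, positive after), or pre-existing; a pre-existing response
is additionally *enhanced* when the best post-treatment magnitude (summed
background-subtracted percentages over positive markers) reaches
``enhancement_fold`` (2x) the pre-treatment magnitude. The enhancement fold
is a package convention — the qualitative category has no printed
quantitative definition — and is therefore surfaced as a parameter and in
report metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .errors import ClassificationError, ConfigurationError

MARKERS = ("IFNG", "TNF", "IL2", "CD107a", "CD154")
CONTROL_STIMULUS = "DMSO"


class TimecourseClass(str, Enum):
    ABSENT = "absent"
    INDUCED = "induced"
    PRE_EXISTING = "pre_existing"
    PRE_EXISTING_NOT_ENHANCED = "pre_existing_not_enhanced"
    ENHANCED = "enhanced"


def marker_percentage(positive_events: int, subset_total: int) -> float:
    """Percent marker-positive cells within the subset."""
    if subset_total <= 0:
        raise ValueError("subset total must be positive")
    if not 0 <= positive_events <= subset_total:
        raise ValueError("positive events outside [0, subset total]")
    return 100.0 * positive_events / subset_total


def call_marker(sample_events: int, sample_total: int,
                control_events: int, control_total: int,
                min_fold: float = 2.0, min_excess: int = 20) -> bool:
    """Criteria I and II for one marker.

    Criterion I is inclusive (>= min_fold x control percentage); criterion
    II subtracts raw event counts (>= min_excess cells).
    """
    sample_pct = marker_percentage(sample_events, sample_total)
    control_pct = marker_percentage(control_events, control_total)
    fold_ok = sample_pct >= min_fold * control_pct
    excess_ok = (sample_events - control_events) >= min_excess
    return fold_ok and excess_ok


def call_response(marker_calls: Mapping[str, bool], min_positive: int = 2,
                  allow_partial: bool = False) -> bool:
    """Criterion III: positive iff >= ``min_positive`` of the five markers are.

    With fewer than five marker calls the rule is applied to the available
    markers only when ``allow_partial`` is set; otherwise a configuration
    error is raised after a warning.
    """
    if len(marker_calls) < len(MARKERS):
        warnings.warn(
            f"only {len(marker_calls)} of {len(MARKERS)} markers present",
            stacklevel=2)
        if not allow_partial:
            raise ConfigurationError(
                "fewer than five marker calls; pass allow_partial=True to "
                "apply the rule to the available markers")
    return sum(bool(v) for v in marker_calls.values()) >= min_positive


@dataclass
class IcsObservation:
    """Event counts for one (patient, timepoint, stimulus, subset).

    ``marker_events`` maps marker name -> positive event count within the
    subset; ``control`` is the matched DMSO observation."""

    patient_id: str
    timepoint: str
    stimulus: str
    subset: str                       # "CD4" | "CD8"
    marker_events: dict[str, int]
    subset_total: int
    control: "IcsObservation | None" = None

    def percentages(self) -> dict[str, float]:
        return {m: marker_percentage(e, self.subset_total)
                for m, e in self.marker_events.items()}


@dataclass
class ResponseCall:
    """Per-timepoint call: marker-level booleans, the overall verdict, and a
    response magnitude (sum of background-subtracted percentages over the
    positive markers)."""

    timepoint: str
    per_marker: dict[str, bool]
    overall: bool
    magnitude: float


def call_observation(obs: IcsObservation, min_fold: float = 2.0,
                     min_excess: int = 20, allow_partial: bool = False
                     ) -> ResponseCall:
    if obs.control is None:
        raise ConfigurationError(
            f"observation {obs.stimulus}@{obs.timepoint} has no matched control")
    per_marker: dict[str, bool] = {}
    magnitude = 0.0
    for marker, events in sorted(obs.marker_events.items()):
        ctrl_events = obs.control.marker_events.get(marker, 0)
        positive = call_marker(events, obs.subset_total,
                               ctrl_events, obs.control.subset_total,
                               min_fold, min_excess)
        per_marker[marker] = positive
        if positive:
            delta = (marker_percentage(events, obs.subset_total)
                     - marker_percentage(ctrl_events, obs.control.subset_total))
            magnitude += max(delta, 0.0)
    overall = call_response(per_marker, allow_partial=allow_partial)
    return ResponseCall(timepoint=obs.timepoint, per_marker=per_marker,
                        overall=overall, magnitude=magnitude)


def classify_timecourse(calls: Sequence[ResponseCall], pre_timepoint: str,
                        enhancement_fold: float = 2.0) -> TimecourseClass:
    """Classify an ordered series of per-timepoint calls.

    ``pre_timepoint`` names the pre-treatment timepoint, which must be
    present. absent: never positive. induced: pre negative, >= 1 post
    positive. pre-existing: pre positive; additionally *enhanced* when the
    maximum post magnitude >= enhancement_fold x the pre magnitude (a
    positive pre magnitude is required for the ratio; a zero pre magnitude
    with a positive post magnitude counts as enhanced).
    """
    by_tp = {c.timepoint: c for c in calls}
    if pre_timepoint not in by_tp:
        raise ClassificationError(
            f"no pre-treatment timepoint {pre_timepoint!r} among calls")
    pre = by_tp[pre_timepoint]
    post = [c for c in calls if c.timepoint != pre_timepoint]
    if not post:
        raise ClassificationError("at least one post-treatment timepoint required")
    any_post_positive = any(c.overall for c in post)
    if not pre.overall:
        if any_post_positive:
            return TimecourseClass.INDUCED
        return TimecourseClass.ABSENT
    max_post_magnitude = max((c.magnitude for c in post if c.overall), default=0.0)
    if pre.magnitude > 0:
        enhanced = max_post_magnitude >= enhancement_fold * pre.magnitude
    else:
        enhanced = max_post_magnitude > 0
    return (TimecourseClass.ENHANCED if enhanced
            else TimecourseClass.PRE_EXISTING_NOT_ENHANCED)


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

REQUIRED_PANEL_COLUMNS = ("patient", "timepoint", "timepoint_order", "stimulus",
                          "subset", "marker", "positive_events", "subset_total")


def observations_from_table(df: pd.DataFrame) -> list[IcsObservation]:
    """Build matched observation/control pairs from a long-format table.

    One row per (patient, timepoint, stimulus, subset, marker); control rows
    have stimulus == "DMSO" and are matched by (patient, timepoint, subset).
    """
    missing = set(REQUIRED_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"ICS table missing column(s) {sorted(missing)}")
    controls: dict[tuple, IcsObservation] = {}
    samples: dict[tuple, IcsObservation] = {}
    for (patient, tp, stim, subset), grp in df.groupby(
            ["patient", "timepoint", "stimulus", "subset"], sort=True):
        totals = grp["subset_total"].unique()
        if len(totals) != 1:
            raise ConfigurationError(
                f"inconsistent subset_total for {patient}/{tp}/{stim}/{subset}")
        obs = IcsObservation(
            patient_id=str(patient), timepoint=str(tp), stimulus=str(stim),
            subset=str(subset),
            marker_events={str(r["marker"]): int(r["positive_events"])
                           for _, r in grp.iterrows()},
            subset_total=int(totals[0]))
        key = (patient, tp, subset)
        if stim == CONTROL_STIMULUS:
            controls[key] = obs
        else:
            samples[(patient, tp, stim, subset)] = obs
    out = []
    for (patient, tp, stim, subset), obs in sorted(samples.items()):
        ctrl = controls.get((patient, tp, subset))
        if ctrl is None:
            raise ConfigurationError(
                f"no DMSO control for {patient}/{tp}/{subset}")
        obs.control = ctrl
        out.append(obs)
    return out


def call_panel(df: pd.DataFrame, min_fold: float = 2.0, min_excess: int = 20,
               enhancement_fold: float = 2.0) -> pd.DataFrame:
    """Call every stimulus in a long-format panel table.

    The pre-treatment timepoint is the one with the smallest
    ``timepoint_order``. Returns one row per (patient, stimulus, subset)
    with positive timepoints and the longitudinal class; enhancement-fold
    metadata is carried in ``df.attrs`` of the result.
    """
    observations = observations_from_table(df)
    order = (df[["timepoint", "timepoint_order"]].drop_duplicates()
             .set_index("timepoint")["timepoint_order"].to_dict())
    pre_tp = min(order, key=lambda tp: order[tp])
    rows = []
    grouped: dict[tuple, list[IcsObservation]] = {}
    for obs in observations:
        grouped.setdefault((obs.patient_id, obs.stimulus, obs.subset), []).append(obs)
    for (patient, stim, subset), obs_list in sorted(grouped.items()):
        obs_list.sort(key=lambda o: order[o.timepoint])
        calls = [call_observation(o, min_fold, min_excess) for o in obs_list]
        cls = classify_timecourse(calls, pre_tp, enhancement_fold)
        rows.append({
            "patient": patient, "stimulus": stim, "subset": subset,
            "positive_timepoints": ";".join(
                c.timepoint for c in calls if c.overall),
            "pre_positive": next(c.overall for c in calls
                                 if c.timepoint == pre_tp),
            "max_post_magnitude": max(
                (c.magnitude for c in calls
                 if c.timepoint != pre_tp and c.overall), default=0.0),
            "timecourse_class": cls.value,
        })
    result = pd.DataFrame(rows)
    result.attrs["enhancement_fold"] = enhancement_fold
    result.attrs["note"] = ("'enhanced' uses a package-defined fold threshold "
                            "on summed background-subtracted percentages")
    return result
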