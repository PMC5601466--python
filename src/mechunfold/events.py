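"""Unfolding-event detection from contact-area series.

A feature (an intra-repeat helix pair or an inter-domain interface) is
considered to unfold once its contact area falls irreversibly.  The
threshold is anchored in the equilibrium fluctuations: with Q1/Q3 the
quartiles of the equilibrium contact-area distribution, the lower outlier
fence is

    CA_low = Q1 − 1.5·(Q3 − Q1)

and an event starts at the first frame with CA < ½·CA_low and ends at the
first later frame with CA < 0.002 nm² (the numerical floor of the area
computation).  One event per feature per trajectory; for display, events
narrower than 2 nm of elongation are widened symmetrically to 2 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import ContactAreaSeries

__all__ = [
    "END_THRESHOLD",
    "EquilibriumBaseline",
    "UnfoldingEvent",
    "baseline",
    "detect_event",
    "widen_for_display",
    "event_catalog",
    "events_to_table",
    "EVENT_COLUMNS",
]

#: nm² — contact area regarded as numerically zero.
END_THRESHOLD = 0.002

EVENT_COLUMNS = ["traj_id", "feature", "start_nm", "end_nm",
                 "disp_start_nm", "disp_end_nm", "open_ended"]


@dataclass(frozen=True)
class EquilibriumBaseline:
    """IQR fence of the equilibrium contact-area distribution for one feature."""

    pair_label: str
    q1: float
    q3: float
    ca_low: float

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")


@dataclass
class UnfoldingEvent:
    """Loss of one feature's contact area, in elongation coordinates (nm)."""

    traj_id: str
    feature: str
    start: float
    end: float
    disp_start: float = np.nan
    disp_end: float = np.nan
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start must not exceed end")


def baseline(equilibrium_ca: Sequence[float], pair_label: str = "") -> EquilibriumBaseline:
    """Quartiles and lower fence of an equilibrium contact-area sample.

    Quantiles use linear interpolation between order statistics (type 7).
    CA_low may come out non-positive for very wide equilibrium distributions;
    the detector clamps the start threshold in that case.
    """
    values = np.asarray(equilibrium_ca, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 equilibrium samples for quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return EquilibriumBaseline(pair_label=pair_label, q1=float(q1), q3=float(q3),
                               ca_low=float(q1 - 1.5 * (q3 - q1)))


def detect_event(
    series: ContactAreaSeries,
    base: EquilibriumBaseline,
    traj_id: str = "",
    end_threshold: float = END_THRESHOLD,
) -> UnfoldingEvent | None:
    """First-crossing unfolding event of one feature, or None.

    Start: elongation of the first frame with CA < ½·CA_low (strict).
    End: elongation of the first subsequent frame with CA < ``end_threshold``.
    If the start threshold is crossed but the floor never is, the event is
    open-ended at the last sampled elongation.  If ½·CA_low would fall below
    the floor (e.g. CA_low ≤ 0), the start threshold is clamped to the floor
    with a warning so the detector stays total.
    """
    if len(series) == 0:
        raise ValueError("empty contact-area series")
    if np.any(np.diff(series.elongation) < 0):
        raise ValueError("elongation must be monotone non-decreasing")
    start_threshold = 0.5 * base.ca_low
    if start_threshold < end_threshold:
        warnings.warn(
            f"{base.pair_label or series.pair_label}: ½·CA_low = "
            f"{start_threshold:.4g} nm² below the {end_threshold} nm² floor; "
            "clamping start threshold", stacklevel=2)
        start_threshold = end_threshold
    below_start = series.ca < start_threshold
    if not below_start.any():
        return None
    i_start = int(np.argmax(below_start))
    below_end = series.ca[i_start:] < end_threshold
    if below_end.any():
        i_end = i_start + int(np.argmax(below_end))
        open_ended = False
    else:
        i_end = len(series) - 1
        open_ended = True
    return UnfoldingEvent(
        traj_id=traj_id,
        feature=series.pair_label,
        start=float(series.elongation[i_start]),
        end=float(series.elongation[i_end]),
        open_ended=open_ended,
    )


def widen_for_display(ev: UnfoldingEvent, min_width: float = 2.0) -> UnfoldingEvent:
    """Attach a display window of at least ``min_width`` nm around the event.

    Narrow events are widened symmetrically about their midpoint; the window
    is clamped at elongation 0 (shifted right, preserving its width).
    """
    width = ev.end - ev.start
    if width >= min_width:
        lo, hi = ev.start, ev.end
    else:
        mid = 0.5 * (ev.start + ev.end)
        lo = mid - 0.5 * min_width
        hi = mid + 0.5 * min_width
        if lo < 0:
            hi -= lo
            lo = 0.0
    return replace(ev, disp_start=lo, disp_end=hi)


def events_to_table(events: Sequence[UnfoldingEvent]) -> pd.DataFrame:
    """Event rows as a DataFrame with the canonical TSV columns."""
    rows = [
        {"traj_id": e.traj_id, "feature": e.feature, "start_nm": e.start,
         "end_nm": e.end, "disp_start_nm": e.disp_start,
         "disp_end_nm": e.disp_end, "open_ended": e.open_ended}
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def event_catalog(
    series_by_feature: Mapping[str, ContactAreaSeries],
    baselines: Mapping[str, EquilibriumBaseline],
    traj_id: str = "",
    min_width: float = 2.0,
) -> pd.DataFrame:
    """Detect one event per feature and return them ordered by start elongation.

    Features whose start threshold is never crossed contribute no row; the
    result may be empty.  Each detected event carries its display window.
    """
    events: list[UnfoldingEvent] = []
    for feature, series in series_by_feature.items():
        if feature not in baselines:
            raise KeyError(f"no equilibrium baseline for feature {feature!r}")
        ev = detect_event(series, baselines[feature], traj_id=traj_id)
        if ev is not None:
            ev.feature = feature
            events.append(widen_for_display(ev, min_width=min_width))
    events.sort(key=lambda e: e.start)
    return events_to_table(events)
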