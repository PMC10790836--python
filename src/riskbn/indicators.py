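"""Per-manoeuvre indicator extraction.

Subjective indicators, from the slider trace:

* ``mSA`` — maximum slider amplitude during the manoeuvre;
* ``iSA`` — area under the slider curve (trapezoidal integral), the dynamic
  indicator combining amplitude and duration.

Electrodermal indicators, from the detected SCR events:

* ``nSCR`` — number of responses whose onset falls in the manoeuvre window
  ``[t_level - w_start, t_level + w_end)``;
* ``mSCR`` — maximum amplitude among those responses (0 when there are none).

``w_start`` is participant-specific: for each manoeuvre the anticipation
delay is the gap between the first strictly positive slider sample and the
moment the vehicle is level with the pedestrian; ``w_start`` is the mean of
those delays over the manoeuvres with a response.  ``w_end`` defaults to 3 s:
a response can only be attributed to a manoeuvre within the 3 s after the
vehicle passes the pedestrian.  Windows are closed on the left and open on
the right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionDesign
from .eda import ScrEvent
from .synthesize import SliderTrace

__all__ = [
    "WindowParams",
    "compute_sa_indicators",
    "compute_w_start",
    "assign_scr_indicators",
    "extract_indicators",
]

#: "strictly positive" slider guard against quantization noise (full scale 1)
SLIDER_EPS = 1e-6
DEFAULT_W_END_S = 3.0


@dataclass(frozen=True)
class WindowParams:
    """SCR attribution window around the vehicle-level moment."""

    w_start: float
    w_end: float = DEFAULT_W_END_S

    def __post_init__(self) -> None:
        if self.w_start < 0 or self.w_end <= 0:
            raise ValueError("require w_start >= 0 and w_end > 0")


def _trial_windows(slider: SliderTrace, design: SessionDesign) -> list[tuple[float, float]]:
    """Per-trial slider windows: the zero-bounded interval around t_level.

    A trial's window runs between the last return-to-zero before its level
    moment and the first return-to-zero after it.  If the slider has not
    returned to zero by the midpoint to the neighbouring trial, a warning is
    issued and the window falls back to the midpoint split.
    """
    t, y = slider.t, slider.y
    levels = [tr.t_level for tr in design.trials]
    windows = []
    for i, t_level in enumerate(levels):
        lo_bound = t[0] if i == 0 else 0.5 * (levels[i - 1] + t_level)
        hi_bound = t[-1] if i == len(levels) - 1 else 0.5 * (t_level + levels[i + 1])
        sel = (t >= lo_bound) & (t < hi_bound)
        tt, yy = t[sel], y[sel]
        if len(yy) and (yy[0] > SLIDER_EPS or yy[-1] > SLIDER_EPS):
            warnings.warn(
                f"trial {design.trials[i].trial_id}: slider did not return to "
                "zero at window edges; using midpoint-split window",
                stacklevel=2,
            )
        windows.append((lo_bound, hi_bound))
    return windows


def compute_sa_indicators(slider: SliderTrace, design: SessionDesign) -> pd.DataFrame:
    """mSA (window maximum) and iSA (trapezoidal area) for every trial."""
    t, y = slider.t, slider.y
    rows = []
    for tr, (lo, hi) in zip(design.trials, _trial_windows(slider, design)):
        sel = (t >= lo) & (t < hi)
        yy = y[sel]
        if not len(yy):
            raise ValueError(f"slider does not cover trial {tr.trial_id}")
        msa = float(yy.max())
        if msa <= SLIDER_EPS:
            msa, isa = 0.0, 0.0
        else:
            isa = float(np.trapezoid(yy, t[sel]))
        rows.append(
            {
                "participant_id": design.participant_id,
                "trial_id": tr.trial_id,
                "ttc_s": tr.ttc,
                "offset_m": tr.offset,
                "msa": msa,
                "isa": isa,
            }
        )
    return pd.DataFrame(rows)


def compute_w_start(slider: SliderTrace, design: SessionDesign) -> float:
    """Participant anticipation delay: mean over trials of
    ``t_level - t(first strictly positive slider sample)``.

    Trials with no positive slider response have no defined delay and are
    excluded from the mean; if no trial responded, the delay is undefined.
    """
    t, y = slider.t, slider.y
    deltas = []
    for tr, (lo, hi) in zip(design.trials, _trial_windows(slider, design)):
        sel = (t >= lo) & (t < hi) & (y > SLIDER_EPS)
        if np.any(sel):
            deltas.append(tr.t_level - float(t[sel][0]))
    if not deltas:
        raise ValueError(
            f"participant {design.participant_id}: no trial has a positive "
            "slider response; w_start is undefined"
        )
    return float(np.mean(deltas))


def assign_scr_indicators(
    events: list[ScrEvent],
    design: SessionDesign,
    w: WindowParams,
) -> pd.DataFrame:
    """nSCR and mSCR per trial from the detected event list.

    An event belongs to a trial when its onset lies in
    ``[t_level - w_start, t_level + w_end)``.  The design's 25 s spacing
    guarantees disjoint windows; overlapping windows raise an error.
    """
    onsets = np.array([e.t_onset for e in events])
    amps = np.array([e.amplitude for e in events])
    if len(onsets) > 1 and np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted by onset")

    bounds = [(tr.t_level - w.w_start, tr.t_level + w.w_end) for tr in design.trials]
    for (_, hi_prev), (lo_next, _) in zip(bounds[:-1], bounds[1:]):
        if lo_next < hi_prev:
            raise ValueError("adjacent trial windows overlap; w_start too large")

    rows = []
    for tr, (lo, hi) in zip(design.trials, bounds):
        if len(onsets):
            in_win = (onsets >= lo) & (onsets < hi)
            n = int(in_win.sum())
            m = float(amps[in_win].max()) if n else 0.0
        else:
            n, m = 0, 0.0
        rows.append(
            {
                "participant_id": design.participant_id,
                "trial_id": tr.trial_id,
                "ttc_s": tr.ttc,
                "offset_m": tr.offset,
                "nscr": n,
                "mscr": m,
            }
        )
    return pd.DataFrame(rows)


def extract_indicators(
    slider: SliderTrace,
    events: list[ScrEvent],
    design: SessionDesign,
    w_end: float = DEFAULT_W_END_S,
) -> pd.DataFrame:
    """Full per-trial indicator table for one participant.

    Computes the participant's ``w_start`` from the slider, then joins the
    subjective and electrodermal indicators.
    """
    w = WindowParams(w_start=compute_w_start(slider, design), w_end=w_end)
    sa = compute_sa_indicators(slider, design)
    scr = assign_scr_indicators(events, design, w)
    return sa.merge(scr, on=["participant_id", "trial_id", "ttc_s", "offset_m"])
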