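"""Synthetic data generator: indicator-level and trace-level simulation of the
risk-perception experiment, with known ground truth.

Two simulation paths are provided.

* ``simulate_indicators`` draws per-manoeuvre indicator values directly from
  the generative model: the subjective assessment (SA) is Gaussian within each
  (TTC, offset) condition cell; the SCR count indicator nSCR follows a Tweedie
  compound-Poisson law with log-link mean ``exp(b0 + b1 * SA)`` (the
  exponential link between the two risk-perception systems); the SCR amplitude
  indicator mSCR follows a Tweedie law whose mean depends on the TTC level.
* ``simulate_traces`` builds the raw signals that those indicators would be
  extracted from: a 20 Hz slider trace that returns to zero between
  manoeuvres with a piecewise-linear bump per trial, and a 625 Hz skin
  conductance trace made of a slowly drifting tonic level, Bateman-shaped
  phasic responses at compound-Poisson event times, and Gaussian sensor noise.

Default ground-truth parameters encode the study conditions: SA condition
means follow the low / mid / high pattern (low risk when TTC >= 3 s and
offset >= 1 m, moderate when TTC = 2.5 s or offset = 0.5 m, high when
TTC = 2 s), and the Tweedie parameters put roughly 46% of the SCR indicator
mass at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CONDITION_FREQUENCIES, SessionDesign, observed_conditions
from .eda import EDATrace, bateman_irf
from .tweedie import sample_tweedie, tweedie_zero_prob

__all__ = [
    "GroundTruth",
    "SliderTrace",
    "TraceSimulation",
    "default_ground_truth",
    "independent_ground_truth",
    "simulate_indicators",
    "simulate_traces",
]


@dataclass(frozen=True)
class SliderTrace:
    """The 20 Hz subjective-assessment signal (0 = no perceived risk)."""

    t: np.ndarray
    y: np.ndarray
    rate: float = 20.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "value": self.y})


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters (and, after trace simulation, the event list)."""

    sa_cell_means: dict
    sa_sigma: float
    scr_link_coeffs: tuple  # (b0, b1): log mean of nSCR = b0 + b1 * SA
    scr_dispersion: float
    scr_index: float
    mscr_ttc_means: dict
    iSA_scale: float = 3.5  # area indicator per unit peak (bump base / 2)
    scr_events: tuple = ()  # per-trial tuples of (t_onset_s, amplitude_uS)

    def __post_init__(self) -> None:
        if not (1.0 < self.scr_index < 2.0):
            raise ValueError("scr_index must lie strictly in (1, 2)")
        if self.scr_dispersion <= 0 or self.sa_sigma < 0:
            raise ValueError("scr_dispersion must be > 0 and sa_sigma >= 0")

    def sa_mean(self, ttc: float, offset: float) -> float:
        return self.sa_cell_means[(ttc, offset)]

    def nscr_mean(self, sa: float) -> float:
        b0, b1 = self.scr_link_coeffs
        return float(np.exp(b0 + b1 * sa))


def default_ground_truth() -> GroundTruth:
    """Study-condition defaults.

    SA cell means (slider scale 0-1) follow the low/mid/high risk pattern;
    Tweedie parameters are set so the marginal zero probability of the SCR
    indicators is about 0.45, matching the observed preponderance of
    manoeuvres without any electrodermal response.
    """
    means = {}
    for ttc, off in observed_conditions():
        if ttc == 2.0:
            means[(ttc, off)] = 0.75          # high perceived risk
        elif ttc == 2.5 or off == 0.5:
            means[(ttc, off)] = 0.45          # moderate
        else:
            means[(ttc, off)] = 0.25          # low (TTC >= 3 and offset >= 1)
    return GroundTruth(
        sa_cell_means=means,
        sa_sigma=0.12,
        scr_link_coeffs=(-1.1, 1.6),
        scr_dispersion=2.5,
        scr_index=1.6,
        mscr_ttc_means={2.0: 0.45, 2.5: 0.30, 3.0: 0.22, 3.5: 0.18},
    )


def independent_ground_truth() -> GroundTruth:
    """Null-model variant: SCR count independent of SA (zero link slope).

    The nSCR mean is constant at the value the default model attains at the
    average SA level, so the marginal behaviour matches while SA and SCR are
    conditionally independent given the factors.
    """
    gt = default_ground_truth()
    b0, b1 = gt.scr_link_coeffs
    mean_sa = float(np.mean(list(gt.sa_cell_means.values())))
    return replace(gt, scr_link_coeffs=(b0 + b1 * mean_sa, 0.0))


def simulate_indicators(
    designs: SessionDesign | list[SessionDesign],
    gt: GroundTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-manoeuvre indicator values from the generative model.

    Returns one row per participant x trial with columns ``msa``, ``isa``
    (the subjective indicators; the area indicator is the peak indicator
    scaled by the bump geometry), ``nscr`` and ``mscr`` (Tweedie draws).
    """
    gt = gt or default_ground_truth()
    if isinstance(designs, SessionDesign):
        designs = [designs]
    rng = np.random.default_rng(seed)

    rows = []
    for design in designs:
        for tr in design.trials:
            rows.append((design.participant_id, tr.trial_id, tr.ttc, tr.offset))
    df = pd.DataFrame(rows, columns=["participant_id", "trial_id", "ttc_s", "offset_m"])

    cell_mean = np.array([gt.sa_mean(t, o) for t, o in zip(df.ttc_s, df.offset_m)])
    sa = cell_mean + gt.sa_sigma * rng.standard_normal(len(df))
    sa = np.clip(sa, 0.0, None)

    b0, b1 = gt.scr_link_coeffs
    mu_n = np.exp(b0 + b1 * sa)
    nscr = sample_tweedie(mu_n, gt.scr_dispersion, gt.scr_index, seed=rng)

    mu_m = np.array([gt.mscr_ttc_means[t] for t in df.ttc_s])
    mscr = sample_tweedie(mu_m, gt.scr_dispersion, gt.scr_index, seed=rng)

    df["msa"] = sa
    df["isa"] = gt.iSA_scale * sa
    df["nscr"] = nscr
    df["mscr"] = mscr
    return df


@dataclass(frozen=True)
class TraceSimulation:
    """One participant's simulated session signals plus per-trial truth."""

    slider: SliderTrace
    eda: EDATrace
    ground_truth: GroundTruth
    truth: pd.DataFrame  # per-trial msa, isa, nscr, mscr ground truth


def simulate_traces(
    design: SessionDesign,
    gt: GroundTruth | None = None,
    seed: int = 0,
    noise_sd_us: float = 0.01,
    tonic_level_us: float = 2.0,
    tonic_drift_us_per_min: float = 0.05,
    slider_rate_hz: float = 20.0,
    eda_rate_hz: float = 625.0,
    bump_rise_s: float = 4.0,
    bump_fall_s: float = 3.0,
    tau1: float = 0.75,
    tau2: float = 2.0,
    event_window: tuple = (-1.0, 2.5),
    min_event_separation_s: float = 1.0,
    amplitude_floor_us: float = 0.0,
) -> TraceSimulation:
    """Generate the raw slider and conductance signals for one session.

    The slider shows one triangular bump per manoeuvre: it rises linearly
    from zero starting ``bump_rise_s`` before the vehicle is level with the
    pedestrian, peaks at the trial's ground-truth SA exactly when the vehicle
    is level, and falls back to zero over ``bump_fall_s`` — so the area
    indicator equals ``peak * (bump_rise_s + bump_fall_s) / 2``.  Bump
    breakpoints land on the 20 Hz grid, making the trapezoid integral exact.

    Skin conductance is tonic drift + sum of Bateman responses at the drawn
    SCR events + Gaussian noise.  Event counts are Poisson with the Tweedie
    rate implied by the trial's SA; amplitudes are the compound-Poisson gamma
    jumps whose mean scales with the TTC-dependent amplitude level; onsets
    fall inside ``event_window`` around the level moment, at least
    ``min_event_separation_s`` apart (the temporal resolution of response
    scoring).  Setting ``amplitude_floor_us`` discards smaller events from
    both the signal and the truth (useful for detector benchmarks).
    """
    gt = gt or default_ground_truth()
    rng = np.random.default_rng(seed)
    duration = design.duration_s
    xi, phi = gt.scr_index, gt.scr_dispersion
    shape = (2.0 - xi) / (xi - 1.0)

    t_slider = np.arange(int(round(duration * slider_rate_hz))) / slider_rate_hz
    slider_y = np.zeros_like(t_slider)
    t_eda = np.arange(int(round(duration * eda_rate_hz))) / eda_rate_hz
    phasic = np.zeros_like(t_eda)

    truth_rows = []
    events_per_trial = []
    for tr in design.trials:
        peak = gt.sa_mean(tr.ttc, tr.offset) + gt.sa_sigma * rng.standard_normal()
        peak = float(np.clip(peak, 0.0, 1.0))
        # triangular bump with grid-aligned breakpoints
        up = (t_slider >= tr.t_level - bump_rise_s) & (t_slider <= tr.t_level)
        down = (t_slider > tr.t_level) & (t_slider <= tr.t_level + bump_fall_s)
        slider_y[up] = peak * (1.0 - (tr.t_level - t_slider[up]) / bump_rise_s)
        slider_y[down] = peak * (1.0 - (t_slider[down] - tr.t_level) / bump_fall_s)

        # compound-Poisson SCR events for this manoeuvre
        lam = gt.nscr_mean(peak) ** (2.0 - xi) / (phi * (2.0 - xi))
        n_events = int(rng.poisson(lam))
        lo, hi = tr.t_level + event_window[0], tr.t_level + event_window[1]
        max_fit = int((hi - lo) / min_event_separation_s) + 1
        n_events = min(n_events, max_fit)
        onsets = _spaced_onsets(rng, lo, hi, n_events, min_event_separation_s)
        scale = phi * (xi - 1.0) * gt.mscr_ttc_means[tr.ttc] ** (xi - 1.0)
        amps = rng.gamma(shape, scale, size=n_events) if n_events else np.array([])
        keep = amps > amplitude_floor_us
        onsets, amps = onsets[keep], amps[keep]

        for t0, a in zip(onsets, amps):
            mask = t_eda >= t0
            phasic[mask] += a * bateman_irf(t_eda[mask] - t0, tau1, tau2)
        events_per_trial.append(tuple((float(t0), float(a))
                                      for t0, a in zip(onsets, amps)))
        retained = amps[amps > 0.05]
        truth_rows.append(
            {
                "participant_id": design.participant_id,
                "trial_id": tr.trial_id,
                "ttc_s": tr.ttc,
                "offset_m": tr.offset,
                "msa": peak,
                "isa": peak * (bump_rise_s + bump_fall_s) / 2.0,
                "nscr": int(len(retained)),
                "mscr": float(retained.max()) if len(retained) else 0.0,
            }
        )

    # slowly varying tonic level: a 1 Hz random walk with the stated per-minute
    # drift scale, interpolated (cubic-smooth via linear interp is sufficient
    # at this bandwidth) onto the acquisition grid
    walk_rate = 1.0
    n_walk = int(np.ceil(duration * walk_rate)) + 2
    drift_step = tonic_drift_us_per_min / np.sqrt(60.0 * walk_rate)
    walk = tonic_level_us + np.cumsum(drift_step * rng.standard_normal(n_walk))
    tonic = np.interp(t_eda, np.arange(n_walk) / walk_rate, walk)
    eda_y = tonic + phasic + noise_sd_us * rng.standard_normal(len(t_eda))

    gt_out = replace(gt, scr_events=tuple(events_per_trial))
    return TraceSimulation(
        slider=SliderTrace(t=t_slider, y=slider_y, rate=slider_rate_hz),
        eda=EDATrace(t=t_eda, y=eda_y, rate=eda_rate_hz),
        ground_truth=gt_out,
        truth=pd.DataFrame(truth_rows),
    )


def _spaced_onsets(rng: np.random.Generator, lo: float, hi: float,
                   n: int, min_sep: float) -> np.ndarray:
    """n onset times in [lo, hi], pairwise at least min_sep apart."""
    if n == 0:
        return np.array([])
    # draw in the shrunk interval, then re-inflate: classic spacing trick
    slack = (hi - lo) - (n - 1) * min_sep
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + min_sep * np.arange(n)
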