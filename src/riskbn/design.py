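"""Experimental design: the within-subject pedestrian-avoidance session layout.

Each participant experiences 32 avoidance manoeuvres of an autonomous vehicle
driving at 30 kph past pedestrians walking at 4.5 kph, one pedestrian every
25 s.  Two factors are manipulated: the time-to-collision (TTC) at manoeuvre
onset (2.0, 2.5, 3.0 or 3.5 s) and the lateral offset left between vehicle and
pedestrian (0.5, 1.0 or 1.5 m).  Only 8 of the 12 level combinations occur;
their relative frequencies are fixed by the design table below.  Walking
direction and avoidance side are balanced nuisance factors with no effect in
the generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorLevels",
    "TrialSpec",
    "SessionDesign",
    "CONDITION_FREQUENCIES",
    "ttc_marginal",
    "offset_marginal",
    "observed_conditions",
    "build_design",
    "build_designs",
]

#: Relative frequency of each tested (ttc_s, offset_m) combination.
#: Offset 1.5 m is crossed with all four TTC levels; offsets 1.0 and 0.5 m
#: only with the two largest TTC values.  Frequencies sum to 1.
CONDITION_FREQUENCIES: dict[tuple[float, float], float] = {
    (3.5, 1.5): 0.125,
    (3.0, 1.5): 0.125,
    (2.5, 1.5): 0.125,
    (2.0, 1.5): 0.125,
    (3.5, 1.0): 0.125,
    (3.0, 1.0): 0.125,
    (3.5, 0.5): 0.125,
    (3.0, 0.5): 0.125,
}

N_TRIALS = 32
TRIAL_SPACING_S = 25.0
SESSION_LEAD_IN_S = 20.0


def observed_conditions() -> list[tuple[float, float]]:
    """The 8 tested (ttc, offset) combinations, in a stable order."""
    return sorted(CONDITION_FREQUENCIES)


def ttc_marginal() -> dict[float, float]:
    out: dict[float, float] = {}
    for (ttc, _), f in CONDITION_FREQUENCIES.items():
        out[ttc] = out.get(ttc, 0.0) + f
    return out


def offset_marginal() -> dict[float, float]:
    out: dict[float, float] = {}
    for (_, off), f in CONDITION_FREQUENCIES.items():
        out[off] = out.get(off, 0.0) + f
    return out


@dataclass(frozen=True)
class FactorLevels:
    """Levels of the two manipulated factors, strictly increasing."""

    ttc_levels: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5)
    offset_levels: tuple[float, ...] = (0.5, 1.0, 1.5)

    def __post_init__(self) -> None:
        for name, levels in (("ttc_levels", self.ttc_levels),
                             ("offset_levels", self.offset_levels)):
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"{name} must be strictly increasing: {levels}")


@dataclass(frozen=True)
class TrialSpec:
    """One avoidance manoeuvre: factor levels and session-clock timing.

    ``t_start`` is the manoeuvre initiation (when TTC equals the trial's
    level); ``t_level`` the moment the vehicle is level with the pedestrian.
    """

    trial_id: int
    ttc: float
    offset: float
    walk_direction: str  # "same" | "opposite"
    avoid_side: str      # "left" | "right"
    t_start: float
    t_level: float

    def __post_init__(self) -> None:
        if self.t_level <= self.t_start:
            raise ValueError("t_level must be after t_start")
        if (self.ttc, self.offset) not in CONDITION_FREQUENCIES:
            raise ValueError(f"untested condition ({self.ttc}, {self.offset})")


@dataclass(frozen=True)
class SessionDesign:
    """The trial layout for one participant.

    ``build_design`` always produces the canonical 32-trial session; the
    container itself accepts any chronologically ordered trial list so that
    reduced layouts can be constructed for exploratory work.
    """

    participant_id: int
    trials: tuple[TrialSpec, ...]
    vehicle_speed_kph: float = 30.0
    pedestrian_speed_kph: float = 4.5
    spacing_s: float = TRIAL_SPACING_S
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a session needs at least one trial")
        levels = [tr.t_level for tr in self.trials]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("trials must be in chronological order")

    @property
    def duration_s(self) -> float:
        return self.trials[-1].t_level + self.spacing_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "trial_id": [tr.trial_id for tr in self.trials],
                "ttc_s": [tr.ttc for tr in self.trials],
                "offset_m": [tr.offset for tr in self.trials],
                "walk_dir": [tr.walk_direction for tr in self.trials],
                "avoid_side": [tr.avoid_side for tr in self.trials],
                "t_start_s": [tr.t_start for tr in self.trials],
                "t_level_s": [tr.t_level for tr in self.trials],
            }
        )


def build_design(
    factor_levels: FactorLevels | None = None,
    participant_id: int = 0,
    seed: int = 0,
) -> SessionDesign:
    """Generate one participant's randomized 32-trial session.

    Condition counts follow the design-table frequencies exactly (each tested
    combination appears ``frequency x 32`` times); walking direction and
    avoidance side are balanced 16/16; trial order is shuffled by ``seed``.
    """
    factor_levels = factor_levels or FactorLevels()
    freqs = CONDITION_FREQUENCIES
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"condition frequencies sum to {total}, expected 1")
    for ttc, off in freqs:
        if ttc not in factor_levels.ttc_levels or off not in factor_levels.offset_levels:
            raise ValueError(f"condition ({ttc}, {off}) outside factor levels")

    conditions: list[tuple[float, float]] = []
    for cond in sorted(freqs):
        count = freqs[cond] * N_TRIALS
        if abs(count - round(count)) > 1e-9:
            raise ValueError(f"frequency {freqs[cond]} x {N_TRIALS} is not integral")
        conditions.extend([cond] * int(round(count)))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    walk = np.array(["same"] * (N_TRIALS // 2) + ["opposite"] * (N_TRIALS // 2))
    side = np.array(["left"] * (N_TRIALS // 2) + ["right"] * (N_TRIALS // 2))
    rng.shuffle(walk)
    rng.shuffle(side)

    trials = []
    for i, idx in enumerate(order):
        ttc, off = conditions[idx]
        t_level = SESSION_LEAD_IN_S + i * TRIAL_SPACING_S
        trials.append(
            TrialSpec(
                trial_id=i,
                ttc=ttc,
                offset=off,
                walk_direction=str(walk[i]),
                avoid_side=str(side[i]),
                t_start=t_level - ttc,
                t_level=t_level,
            )
        )
    return SessionDesign(participant_id=participant_id, trials=tuple(trials), seed=seed)


def build_designs(n_participants: int, seed: int = 0) -> list[SessionDesign]:
    """Independent randomized sessions for ``n_participants`` participants."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_participants)
    return [
        build_design(participant_id=p, seed=int(child_seeds[p]) % (2**31))
        for p in range(n_participants)
    ]
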