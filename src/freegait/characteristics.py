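"""The 14 spatiotemporal gait characteristics and their domain mapping.

Five base quantities (step velocity, step length, step time, swing time,
stance time) are averaged over all steps of a bout; variability is the
sample standard deviation over all steps; asymmetry is the absolute
difference between the means of the two alternation-parity classes (the
lumbar sensor cannot label absolute left/right, but alternation suffices).
Swing time variability appears in both the pace and variability domains of
the conventional five-domain model; it is stored once.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np

from .events import StepEvent

BASE = ["step_velocity", "step_length", "step_time", "swing_time", "stance_time"]
VARIABILITY = [f"{b}_var" for b in BASE]
ASYMMETRY = ["step_time_asym", "swing_time_asym", "stance_time_asym", "step_length_asym"]
CHARACTERISTICS = BASE + VARIABILITY + ASYMMETRY

DOMAINS = {
    "pace": ["step_velocity", "step_length", "swing_time_var"],
    "rhythm": ["step_time", "swing_time", "stance_time"],
    "variability": VARIABILITY,
    "asymmetry": ["step_time_asym", "swing_time_asym", "stance_time_asym"],
    "postural_control": ["step_length_asym"],
}


@dataclass
class GaitCharacteristics14:
    step_velocity: float = np.nan
    step_length: float = np.nan
    step_time: float = np.nan
    swing_time: float = np.nan
    stance_time: float = np.nan
    step_velocity_var: float = np.nan
    step_length_var: float = np.nan
    step_time_var: float = np.nan
    swing_time_var: float = np.nan
    stance_time_var: float = np.nan
    step_time_asym: float = np.nan
    swing_time_asym: float = np.nan
    stance_time_asym: float = np.nan
    step_length_asym: float = np.nan
    n_steps: int = 0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _nanmean(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.mean(x)) if len(x) else np.nan


def _sample_sd(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1)) if len(x) >= 2 else np.nan


def _asym(x: np.ndarray, parity: np.ndarray, method: str) -> float:
    """|mean(even steps) - mean(odd steps)|, or mean absolute consecutive
    difference when ``method='pair'``."""
    ok = np.isfinite(x)
    if method == "pair":
        xv = x[ok]
        return float(np.mean(np.abs(np.diff(xv)))) if len(xv) >= 2 else np.nan
    ev, od = x[ok & (parity == 0)], x[ok & (parity == 1)]
    if len(ev) == 0 or len(od) == 0:
        return np.nan
    return float(abs(np.mean(ev) - np.mean(od)))


def summarize(steps: Sequence[StepEvent] | Iterable[StepEvent],
              asym_method: str = "class_mean") -> GaitCharacteristics14:
    """Condense a bout's (or pooled collection's) steps into the 14
    characteristics.  Fields whose inputs are insufficient (fewer than two
    finite values for variability, a missing parity class for asymmetry)
    come back as NaN, never as zero.
    """
    steps = list(steps)
    if len(steps) < 3:
        raise ValueError("a walking bout requires at least three steps")
    if asym_method not in ("class_mean", "pair"):
        raise ValueError("asym_method must be 'class_mean' or 'pair'")
    get = lambda attr: np.array([getattr(s, attr) for s in steps], dtype=float)
    parity = np.array([s.parity for s in steps])
    vel, length = get("step_velocity"), get("step_length")
    st, sw, stn = get("step_time"), get("swing_time"), get("stance_time")
    return GaitCharacteristics14(
        step_velocity=_nanmean(vel),
        step_length=_nanmean(length),
        step_time=_nanmean(st),
        swing_time=_nanmean(sw),
        stance_time=_nanmean(stn),
        step_velocity_var=_sample_sd(vel),
        step_length_var=_sample_sd(length),
        step_time_var=_sample_sd(st),
        swing_time_var=_sample_sd(sw),
        stance_time_var=_sample_sd(stn),
        step_time_asym=_asym(st, parity, asym_method),
        swing_time_asym=_asym(sw, parity, asym_method),
        stance_time_asym=_asym(stn, parity, asym_method),
        step_length_asym=_asym(length, parity, asym_method),
        n_steps=len(steps),
    )
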