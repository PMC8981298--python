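"""Gait event detection and per-step parameters.

Initial contacts (heel strikes) and final contacts (toe-offs) are found with
a Gaussian continuous wavelet transform of the integrated vertical
acceleration: the first-derivative-of-Gaussian transform is minimised at
heel strikes, and a second-derivative-of-Gaussian transform is maximised
near toe-offs.  The wavelet scale adapts to the bout's dominant step
frequency so smoothing tracks cadence.  Step length comes from the inverted
pendulum model applied to the doubly-integrated vertical acceleration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend, find_peaks

G_MS2 = 9.80665
STEP_BAND_HZ = (0.5, 3.0)
FALLBACK_STEP_HZ = 1.8


class TooFewStepsError(ValueError):
    """Raised when a candidate bout yields fewer than three initial contacts."""


@dataclass
class StepEvent:
    """One detected step.

    ``parity`` indexes the left/right alternation (absolute side is unknown
    from a single lumbar sensor); ``fc_time`` is the toe-off of the foot that
    struck at ``ic_time``.  Edge steps lacking the events needed for
    stance/swing or a length estimate carry NaN there.
    """

    ic_time: float
    fc_time: float
    parity: int
    step_time: float
    swing_time: float
    stance_time: float
    step_length: float
    step_velocity: float


def dominant_step_frequency(x: np.ndarray, fs: float,
                            band: tuple[float, float] = STEP_BAND_HZ) -> float:
    """FFT-peak frequency of ``x`` within the human step-frequency band."""
    n = len(x)
    if n < 16:
        return FALLBACK_STEP_HZ
    xd = np.asarray(x, float) - np.mean(x)
    spec = np.abs(np.fft.rfft(xd * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(m) or np.all(spec[m] == 0):
        return FALLBACK_STEP_HZ
    return float(freqs[m][np.argmax(spec[m])])


def _refine(idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Parabolic sub-sample refinement of extremum positions."""
    idx = np.asarray(idx, dtype=float)
    out = idx.copy()
    for k, i in enumerate(idx.astype(int)):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if abs(denom) > 1e-30:
                out[k] = i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return out


def detect_ic_fc(vert_filt: np.ndarray, fs: float, t0: float = 0.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Detect initial- and final-contact times in one walking bout.

    ``vert_filt``: gravity-aligned, 20 Hz low-passed vertical acceleration
    (g or m/s^2 — the method is scale invariant); gravity is removed
    internally by mean subtraction.  Events are returned as absolute times
    and strictly alternate starting at an IC.  Raises ``TooFewStepsError``
    when fewer than three ICs are found.
    """
    x = np.asarray(vert_filt, dtype=float)
    x = x - np.mean(x)
    n = len(x)
    if n < 8:
        raise TooFewStepsError("segment too short")
    v = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    # cadence from the acceleration spectrum: integration tilts the spectrum
    # toward low-frequency envelope content and would bias the scale
    f0 = dominant_step_frequency(x, fs)
    pad = min(n - 1, int(round(fs / f0)))
    vp = np.pad(v, pad, mode="reflect")

    s1 = pywt.frequency2scale("gaus1", f0 / fs)
    c1 = pywt.cwt(vp, [s1], "gaus1")[0][0][pad:pad + n]
    s2 = pywt.frequency2scale("gaus2", f0 / fs)
    c2 = pywt.cwt(vp, [s2], "gaus2")[0][0][pad:pad + n]

    dist = max(2, int(round(0.45 * fs / f0)))
    amp1 = np.std(c1)
    if amp1 == 0:
        raise TooFewStepsError("flat signal, no events")
    ic_idx, _ = find_peaks(-c1, distance=dist, prominence=0.3 * amp1)
    fc_idx, _ = find_peaks(c2, distance=dist, prominence=0.3 * np.std(c2))
    if len(ic_idx) < 3:
        raise TooFewStepsError(f"only {len(ic_idx)} initial contacts found")

    ic_t = t0 + _refine(ic_idx, -c1) / fs
    fc_t = t0 + _refine(fc_idx, c2) / fs
    ic_t, fc_t = _enforce_alternation(ic_t, -c1[ic_idx], fc_t, c2[fc_idx])
    if len(ic_t) < 3:
        raise TooFewStepsError(f"only {len(ic_t)} initial contacts after alternation")
    return ic_t, fc_t


def _enforce_alternation(ic_t, ic_mag, fc_t, fc_mag):
    """Keep an IC, FC, IC, FC ... sequence; among same-kind runs keep the
    most extreme event."""
    events = ([(t, 0, m) for t, m in zip(ic_t, ic_mag)]
              + [(t, 1, m) for t, m in zip(fc_t, fc_mag)])
    events.sort()
    # drop leading FCs: the sequence must start at a heel strike
    while events and events[0][1] == 1:
        events.pop(0)
    kept: list[tuple[float, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    ics = np.array([t for t, k, _ in kept if k == 0])
    fcs = np.array([t for t, k, _ in kept if k == 1])
    return ics, fcs


def temporal_params(ics: np.ndarray, fcs: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-step (step_time, stance_time, swing_time, fc_of_same_foot).

    step_time_i = IC_{i+1} - IC_i.  The foot striking at IC_i lifts off at
    the second FC after IC_i, so stance_time_i = FC* - IC_i and
    swing_time_i = stride_i - stance_time_i with stride_i = IC_{i+2} - IC_i.
    Steps at the bout edges that lack the needed events carry NaN.
    """
    ics = np.asarray(ics, float)
    fcs = np.asarray(fcs, float)
    if np.any(np.diff(ics) <= 0):
        raise ValueError("IC times must be strictly increasing")
    n = len(ics) - 1
    step_time = np.diff(ics)
    stance = np.full(n, np.nan)
    swing = np.full(n, np.nan)
    fc_own = np.full(n, np.nan)
    for i in range(n):
        after = fcs[fcs > ics[i] + 1e-9]
        if len(after) >= 2:
            fc_star = after[1]
            if i + 2 < len(ics) and fc_star < ics[i + 2]:
                stance[i] = fc_star - ics[i]
                swing[i] = (ics[i + 2] - ics[i]) - stance[i]
                fc_own[i] = fc_star
    return step_time, stance, swing, fc_own


def step_length_pendulum(vert_filt: np.ndarray, fs: float, ics: np.ndarray,
                         sensor_height: float, t0: float = 0.0,
                         in_g: bool = True) -> np.ndarray:
    """Inverted-pendulum step lengths from consecutive-IC windows.

    The vertical acceleration is doubly integrated per step; linear
    detrending of the displacement suppresses integration drift; the
    peak-to-peak excursion h gives step length 2*sqrt(2*l*h - h^2).  Steps
    with h >= l are rejected (NaN) as artifacts.
    """
    if sensor_height <= 0:
        raise ValueError("sensor_height must be positive")
    a = np.asarray(vert_filt, dtype=float)
    a = (a - np.mean(a)) * (G_MS2 if in_g else 1.0)
    idx = np.round((np.asarray(ics, float) - t0) * fs).astype(int)
    out = np.full(max(len(ics) - 1, 0), np.nan)
    for i in range(len(ics) - 1):
        lo, hi = max(idx[i], 0), min(idx[i + 1] + 1, len(a))
        if hi - lo < 4:
            continue
        seg = a[lo:hi] - np.mean(a[lo:hi])
        vel = cumulative_trapezoid(seg, dx=1.0 / fs, initial=0.0)
        disp = cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)
        disp = detrend(disp, type="linear")
        h = float(disp.max() - disp.min())
        if h >= sensor_height:
            continue
        out[i] = 2.0 * math.sqrt(2.0 * sensor_height * h - h * h)
    return out


def extract_steps(vert_filt: np.ndarray, fs: float, sensor_height: float,
                  t0: float = 0.0,
                  ics: np.ndarray | None = None,
                  fcs: np.ndarray | None = None) -> list[StepEvent]:
    """Full per-step parameter extraction for one bout.

    Runs event detection (unless events are supplied), temporal parameters
    and pendulum step lengths; emits one StepEvent per IC interval with
    ``step_velocity = step_length / step_time`` exactly.
    """
    if ics is None or fcs is None:
        ics, fcs = detect_ic_fc(vert_filt, fs, t0=t0)
    st, stance, swing, fc_own = temporal_params(ics, fcs)
    lengths = step_length_pendulum(vert_filt, fs, ics, sensor_height, t0=t0)
    steps = []
    for i in range(len(st)):
        length = lengths[i]
        vel = length / st[i] if np.isfinite(length) else np.nan
        steps.append(StepEvent(
            ic_time=float(ics[i]), fc_time=float(fc_own[i]), parity=i % 2,
            step_time=float(st[i]), swing_time=float(swing[i]),
            stance_time=float(stance[i]), step_length=float(length),
            step_velocity=float(vel)))
    return steps
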