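"""Orientation correction, low-pass filtering and walking-bout detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import AccelRecording

from . import events as _events


@dataclass(frozen=True)
class BoutDetectionParams:
    """Windowed-SD walking detector settings.

    The acceleration magnitude is band-passed to the human step-frequency
    band before the moving SD, so broadband sensor noise does not trigger
    the threshold.
    """

    window_s: float = 0.8
    overlap: float = 0.5
    sd_threshold_g: float = 0.05
    band_hz: tuple[float, float] = (0.5, 3.0)
    margin_s: float = 0.4  # candidate extension before event detection


@dataclass
class WalkingBout:
    start: float
    end: float
    step_count: int
    day_index: int = 0
    ic_times: np.ndarray | None = None
    fc_times: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def estimate_vertical(rec: AccelRecording) -> AccelRecording:
    """Rotate axes so the mean low-passed gravity vector maps onto vertical.

    Gravity direction is the mean of the 0.5 Hz low-passed signal; the
    rotation is the minimal (Rodrigues) rotation taking that direction to the
    vertical axis, so a static tilted recording ends up with vertical mean
    1 g.  Raises on a degenerate (near-zero) gravity vector.
    """
    if rec.duration < 5.0:
        raise ValueError("need at least 5 s of data to estimate orientation")
    sos = signal.butter(2, 0.5, btype="low", fs=rec.fs, output="sos")
    grav = signal.sosfiltfilt(sos, rec.data, axis=0).mean(axis=0)
    norm = np.linalg.norm(grav)
    if norm < 0.5:
        raise ValueError(f"degenerate gravity vector (|g|={norm:.3f} g)")
    u = grav / norm
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, target)
    s, c = np.linalg.norm(v), float(u @ target)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    return AccelRecording(rec.data @ R.T, rec.fs, t0=rec.t0, meta=dict(rec.meta))


def lowpass20(x: np.ndarray, fs: float, cutoff_hz: float = 20.0,
              order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward-backward so gait
    event times are not shifted)."""
    if fs <= 2 * cutoff_hz:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _windowed_sd(x: np.ndarray, fs: float, window_s: float,
                 overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """SD per window; returns (window start times in samples, sd values)."""
    w = max(4, int(round(window_s * fs)))
    hop = max(1, int(round(w * (1.0 - overlap))))
    if len(x) < w:
        return np.array([], dtype=int), np.array([])
    starts = np.arange(0, len(x) - w + 1, hop)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    ssum = c1[starts + w] - c1[starts]
    ssq = c2[starts + w] - c2[starts]
    var = np.maximum(ssq / w - (ssum / w) ** 2, 0.0)
    return starts, np.sqrt(var)


def detect_walking_bouts(rec: AccelRecording,
                         params: BoutDetectionParams | None = None,
                         keep_events: bool = True) -> list[WalkingBout]:
    """Detect walking bouts in a gravity-aligned real-world recording.

    Moving-window SD of the band-passed acceleration magnitude is
    thresholded; contiguous active runs become candidates; a candidate is
    kept only if the wavelet event detector finds at least three initial
    contacts in it.  Bout boundaries are snapped to the first and last
    detected contact so the duration reflects walking time.  Candidates are
    never merged across a rest gap, however short.
    """
    params = params or BoutDetectionParams()
    if rec.n == 0:
        return []
    mag = np.linalg.norm(rec.data, axis=1)
    lo, hi = params.band_hz
    if rec.fs <= 2 * hi:
        raise ValueError("sampling rate too low for the detection band")
    sos = signal.butter(4, [lo, hi], btype="band", fs=rec.fs, output="sos")
    magf = signal.sosfiltfilt(sos, mag - mag.mean())
    starts, sd = _windowed_sd(magf, rec.fs, params.window_s, params.overlap)
    if len(sd) == 0:
        return []
    active = sd > params.sd_threshold_g
    w = max(4, int(round(params.window_s * rec.fs)))

    bouts: list[WalkingBout] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    vert_filt_full = lowpass20(rec.vertical, rec.fs)
    candidates: list[list[float]] = []
    for a, b in zip(edges[::2], edges[1::2]):
        t_lo = rec.t0 + starts[a] / rec.fs - params.margin_s
        t_hi = rec.t0 + (starts[b - 1] + w) / rec.fs + params.margin_s
        # candidates overlapping after margin expansion are one active region
        # (detector flicker inside low-amplitude walking, not a rest gap)
        if candidates and t_lo <= candidates[-1][1]:
            candidates[-1][1] = max(candidates[-1][1], t_hi)
        else:
            candidates.append([t_lo, t_hi])
    for t_lo, t_hi in candidates:
        i0 = max(0, int((t_lo - rec.t0) * rec.fs))
        i1 = min(rec.n, int((t_hi - rec.t0) * rec.fs) + 1)
        seg = vert_filt_full[i0:i1]
        if len(seg) < int(1.5 * rec.fs):
            continue
        try:
            ics, fcs = _events.detect_ic_fc(seg, rec.fs, t0=rec.t0 + i0 / rec.fs)
        except _events.TooFewStepsError:
            continue
        def _rms(a: float, b: float) -> float:
            lo = max(0, int((a - rec.t0) * rec.fs))
            hi = min(rec.n, int((b - rec.t0) * rec.fs))
            return float(np.sqrt(np.mean(magf[lo:hi] ** 2))) if hi > lo else 0.0

        def _in_walking(tt: float) -> bool:
            # a genuine contact has walking energy on at least one side;
            # wavelet edge artifacts in rest are quiet on both sides
            return (_rms(tt - 0.3, tt - 0.05) >= params.sd_threshold_g
                    or _rms(tt + 0.05, tt + 0.3) >= params.sd_threshold_g)

        ics = ics[np.array([_in_walking(tt) for tt in ics])]
        if len(ics) < 3:
            continue
        fcs = fcs[np.array([_in_walking(tt) for tt in fcs])]

        # never merge across a rest gap: a long inter-contact stretch whose
        # centre is quiet (band-passed magnitude at the noise floor) is rest,
        # not a missed step — walking leaves energy throughout the gap
        def _rest_gap(t_a: float, t_b: float) -> bool:
            if t_b - t_a <= 1.05:
                return False
            if t_b - t_a > 2.5:
                return True
            mid = 0.5 * (t_a + t_b)
            lo = max(0, int((mid - 0.15 - rec.t0) * rec.fs))
            hi = min(rec.n, int((mid + 0.15 - rec.t0) * rec.fs))
            if hi <= lo:
                return False
            rms = float(np.sqrt(np.mean(magf[lo:hi] ** 2)))
            return rms < params.sd_threshold_g

        breaks = np.array([k for k in range(len(ics) - 1)
                           if _rest_gap(ics[k], ics[k + 1])], dtype=int)
        gap_thr = 1.05
        pieces = np.split(np.arange(len(ics)), breaks + 1)
        for piece in pieces:
            sub_ics = ics[piece]
            if len(sub_ics) < 3:
                continue
            nxt = ics[piece[-1] + 1] - 0.05 if piece[-1] + 1 < len(ics) else np.inf
            hi_fc = min(sub_ics[-1] + gap_thr, nxt)
            sub_fcs = fcs[(fcs >= sub_ics[0]) & (fcs <= hi_fc)]
            end = float(max(sub_ics[-1], sub_fcs[-1] if len(sub_fcs) else sub_ics[-1]))
            # a bout straddling midnight belongs to the day containing its start
            bouts.append(WalkingBout(start=float(sub_ics[0]), end=end,
                                     step_count=len(sub_ics),
                                     day_index=int(sub_ics[0] // 86400.0),
                                     ic_times=sub_ics if keep_events else None,
                                     fc_times=sub_fcs if keep_events else None))
    return bouts
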