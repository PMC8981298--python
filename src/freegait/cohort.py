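"""Synthetic cohort generator: lab and free-living lumbar accelerometry with ground truth.

Emulates the measurement setting of a lower-back tri-axial accelerometer
(100 Hz, +/-8 g) worn by people with Parkinson's disease (PD) and healthy
controls (HC): a 2-minute continuous lab walk and multi-day free-living
recordings composed of many short walking bouts.  Every recording comes with
step-level ground truth (initial/final contact times, step time, step length,
step velocity and foot side), so the whole downstream extraction pipeline can
be validated without access to clinical data.

The per-step model is an inverted pendulum: during each step the centre of
mass rises and falls by ``h = l - sqrt(l^2 - (SL/2)^2)`` where ``l`` is the
sensor (pendulum) height and ``SL`` the step length.  The vertical channel is
the second time-derivative of that excursion, plus gravity, plus short
impact transients at each initial and final contact, plus sensor noise.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .io import AccelRecording, write_recording

G_MS2 = 9.80665
DAY_S = 86400.0


# ---------------------------------------------------------------------------
# bout duration law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutDurationLaw:
    """Shifted lognormal walking-bout duration law.

    duration = min_s + LogNormal(mu, sigma), capped at cap_s.  The shift
    guarantees every bout is long enough to hold at least three steps; the
    two free parameters are fitted in closed form to the two tail fractions
    the free-living literature reports (share of bouts <= 10 s and > 120 s).
    """

    mu: float
    sigma: float
    min_s: float = 2.0
    cap_s: float = 1800.0

    @classmethod
    def from_tail_probs(cls, p_le10: float, p_gt120: float,
                        min_s: float = 2.0, cap_s: float = 1800.0,
                        knots: tuple[float, float] = (10.0, 120.0)) -> "BoutDurationLaw":
        k1, k2 = knots
        if not (min_s < k1 < k2):
            raise ValueError("knots must exceed min_s and be ordered")
        z1 = norm.ppf(p_le10)
        z2 = norm.ppf(1.0 - p_gt120)
        sigma = (math.log(k2 - min_s) - math.log(k1 - min_s)) / (z2 - z1)
        mu = math.log(k1 - min_s) - z1 * sigma
        return cls(mu=mu, sigma=sigma, min_s=min_s, cap_s=cap_s)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        m = x > self.min_s
        out[m] = norm.cdf((np.log(x[m] - self.min_s) - self.mu) / self.sigma)
        out[x >= self.cap_s] = 1.0
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        d = self.min_s + np.exp(self.mu + self.sigma * rng.standard_normal(n))
        return np.minimum(d, self.cap_s)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class GaitProfile:
    """Per-participant gait parameters.

    Times in seconds, lengths in metres.  ``asym_*`` are systematic
    left/right offsets (half added to one side, subtracted from the other);
    ``swing_fraction`` is swing time divided by step time; ``sensor_height``
    is the inverted-pendulum length l.  The ``short_*`` / ``long_bout_boost``
    fields implement the context model: very short bouts (indoor shuffling)
    are slower and converge between groups, long bouts (purposeful outdoor
    walking) express each participant's full gait signature.
    """

    group: str  # "PD" | "HC"
    mean_step_time: float = 0.55
    mean_step_length: float = 0.65
    step_time_sd: float = 0.02
    step_length_sd: float = 0.02
    asym_step_time: float = 0.01
    asym_step_length: float = 0.01
    swing_fraction: float = 0.76
    sensor_height: float = 1.05
    bout_rate: float = 400.0
    bout_duration_law: BoutDurationLaw = field(
        default_factory=lambda: BoutDurationLaw.from_tail_probs(0.87, 0.018))
    context_slowdown: float = 0.85
    short_bout_blend: float = 0.6
    short_common_length: float = 0.60
    short_time_factor: float = 1.05
    short_bout_length_offset: float = 0.0
    short_bout_time_offset: float = 0.0
    long_bout_boost: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError(f"group must be PD or HC, got {self.group!r}")
        for name in ("mean_step_time", "mean_step_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("step_time_sd", "step_length_sd", "asym_step_time",
                     "asym_step_length", "bout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.swing_fraction < 1.0:
            raise ValueError("swing_fraction must lie in (0, 1)")
        if not 0.7 <= self.sensor_height <= 1.3:
            raise ValueError("sensor_height must lie in [0.7, 1.3] m")
        p10 = float(self.bout_duration_law.cdf(10.0))
        if not 0.5 < p10 < 0.95:
            raise ValueError(
                f"bout_duration_law gives P(duration<=10s)={p10:.3f}, outside (0.5, 0.95)")

    def bout_modifiers(self, duration: float) -> tuple[float, float]:
        """(length_factor_target, time_factor) for a bout of this duration.

        Returns the effective mean step length (m) and the multiplicative
        step-time factor.  Shortness weight is 1 for <=10 s, fading to 0 at
        30 s; the long-bout boost ramps in between 30 and 120 s.
        """
        s = min(1.0, max(0.0, (30.0 - duration) / 20.0))
        long_w = min(1.0, max(0.0, (duration - 30.0) / 90.0))
        base = self.mean_step_length * (1.0 + self.long_bout_boost * long_w)
        short_len = (self.context_slowdown
                     * (self.short_bout_blend * self.mean_step_length
                        + (1.0 - self.short_bout_blend) * self.short_common_length)
                     + self.short_bout_length_offset)
        length = (1.0 - s) * base + s * short_len
        tfac = 1.0 + s * ((self.short_time_factor - 1.0)
                          + self.short_bout_time_offset / self.mean_step_time)
        return max(length, 0.1), max(tfac, 0.5)


@dataclass(frozen=True)
class GroupParams:
    """Group-level distribution from which per-participant profiles are drawn."""

    group: str
    step_time_mean: float
    step_time_bsd: float          # between-subject SD
    step_length_mean: float
    step_length_bsd: float
    step_time_sd_mean: float      # within-subject (step-to-step) SD, group mean
    step_time_sd_bsd: float
    step_length_sd_mean: float
    step_length_sd_bsd: float
    asym_time_mean: float
    asym_time_bsd: float
    asym_length_mean: float
    asym_length_bsd: float
    swing_fraction: float
    sensor_height_mean: float
    sensor_height_bsd: float
    bout_rate: float
    p_le10: float
    p_gt120: float
    long_bout_boost: float
    short_offset_len_bsd: float
    short_offset_time_bsd: float

    def draw_profile(self, rng: np.random.Generator) -> GaitProfile:
        def pos(mean, sd, lo):
            return max(lo, mean + sd * rng.standard_normal())
        return GaitProfile(
            group=self.group,
            mean_step_time=pos(self.step_time_mean, self.step_time_bsd, 0.35),
            mean_step_length=pos(self.step_length_mean, self.step_length_bsd, 0.30),
            step_time_sd=pos(self.step_time_sd_mean, self.step_time_sd_bsd, 0.004),
            step_length_sd=pos(self.step_length_sd_mean, self.step_length_sd_bsd, 0.004),
            asym_step_time=pos(self.asym_time_mean, self.asym_time_bsd, 0.0),
            asym_step_length=pos(self.asym_length_mean, self.asym_length_bsd, 0.0),
            swing_fraction=self.swing_fraction,
            sensor_height=float(np.clip(
                self.sensor_height_mean + self.sensor_height_bsd * rng.standard_normal(),
                0.8, 1.25)),
            bout_rate=self.bout_rate,
            bout_duration_law=BoutDurationLaw.from_tail_probs(self.p_le10, self.p_gt120),
            long_bout_boost=self.long_bout_boost,
            short_bout_length_offset=self.short_offset_len_bsd * rng.standard_normal(),
            short_bout_time_offset=self.short_offset_time_bsd * rng.standard_normal(),
        )


# Cohort-level defaults.  PD walks with shorter, slower, more variable and
# more asymmetric steps than HC; the group contrast is strongest in long
# bouts (long_bout_boost) and attenuated in very short ones (the shared
# short-bout context model plus participant-level short-bout idiosyncrasies).
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "HC": GroupParams(
        group="HC",
        step_time_mean=0.53, step_time_bsd=0.030,
        step_length_mean=0.66, step_length_bsd=0.050,
        step_time_sd_mean=0.020, step_time_sd_bsd=0.004,
        step_length_sd_mean=0.020, step_length_sd_bsd=0.005,
        asym_time_mean=0.010, asym_time_bsd=0.005,
        asym_length_mean=0.010, asym_length_bsd=0.005,
        swing_fraction=0.76,
        sensor_height_mean=1.05, sensor_height_bsd=0.05,
        bout_rate=468.0, p_le10=0.85, p_gt120=0.019,
        long_bout_boost=0.05,
        short_offset_len_bsd=0.05, short_offset_time_bsd=0.03,
    ),
    "PD": GroupParams(
        group="PD",
        step_time_mean=0.56, step_time_bsd=0.040,
        step_length_mean=0.615, step_length_bsd=0.055,
        step_time_sd_mean=0.030, step_time_sd_bsd=0.007,
        step_length_sd_mean=0.028, step_length_sd_bsd=0.007,
        asym_time_mean=0.018, asym_time_bsd=0.008,
        asym_length_mean=0.016, asym_length_bsd=0.008,
        swing_fraction=0.74,
        sensor_height_mean=1.05, sensor_height_bsd=0.05,
        bout_rate=408.0, p_le10=0.87, p_gt120=0.018,
        long_bout_boost=-0.02,
        short_offset_len_bsd=0.05, short_offset_time_bsd=0.03,
    ),
}


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class Step:
    ic_time: float
    fc_time: float
    side: str            # "L" | "R"
    step_time: float
    step_length: float
    step_velocity: float


@dataclass
class BoutTruth:
    start: float
    end: float
    steps: list[Step]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    bouts: list[BoutTruth]

    def all_steps(self) -> list[Step]:
        return [s for b in self.bouts for s in b.steps]

    def validate(self) -> None:
        for b in self.bouts:
            ics = [s.ic_time for s in b.steps]
            if len(ics) < 3:
                raise ValueError("each bout must hold >= 3 initial contacts")
            if any(t2 <= t1 for t1, t2 in zip(ics, ics[1:])):
                raise ValueError("IC times must be strictly increasing")
            for s in b.steps:
                if abs(s.step_velocity * s.step_time - s.step_length) > 1e-12:
                    raise ValueError("velocity * time != length")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_bout_schedule(profile: GaitProfile, n_days: int,
                         rng_seed: int | np.random.SeedSequence,
                         mean_gap_s: float = 6.0) -> list[list[tuple[float, float]]]:
    """Sample non-overlapping bout intervals for each of ``n_days`` days.

    Bout count per day is Poisson(bout_rate); durations follow the profile's
    duration law; consecutive bouts are separated by a rest gap of at least
    1 s (1 + exponential).  Times are seconds since the session start
    (midnight of day 0); each day occupies [d*86400, (d+1)*86400).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(rng_seed)
    days: list[list[tuple[float, float]]] = []
    for d in range(n_days):
        if profile.bout_rate == 0:
            days.append([])
            continue
        n = int(rng.poisson(profile.bout_rate))
        durs = profile.bout_duration_law.sample(n, rng)
        gaps = 1.0 + rng.exponential(max(mean_gap_s - 1.0, 0.1), size=n)
        if durs.sum() > DAY_S:
            raise ValueError(
                f"requested bout time {durs.sum():.0f}s exceeds 24 h on day {d}")
        t = d * DAY_S + 60.0  # first activity a minute after midnight
        bouts = []
        for dur, gap in zip(durs, gaps):
            start = t + gap
            end = start + dur
            if end >= (d + 1) * DAY_S:
                break  # day full; drop the remainder
            bouts.append((start, end))
            t = end
        days.append(bouts)
    return days


def synthesize_step_sequence(profile: GaitProfile, duration: float,
                             rng_seed: int | np.random.SeedSequence | np.random.Generator,
                             mean_step_length: float | None = None,
                             time_factor: float = 1.0,
                             t0: float = 0.0,
                             max_retries: int = 50) -> list[Step]:
    """Generate alternating L/R steps filling ``duration`` seconds from ``t0``.

    step_time_i = time_factor * mean_step_time +/- asym/2 + N(0, sd); step
    length analogously around ``mean_step_length`` (defaults to the profile
    mean).  The final contact of the foot striking at IC_i is placed at
    IC_i + (2 - swing_fraction) * step_time so the configured swing fraction
    holds per step.  Raises if a positive step time cannot be sampled within
    ``max_retries`` draws.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    mst = time_factor * profile.mean_step_time
    msl = profile.mean_step_length if mean_step_length is None else mean_step_length
    if duration < 3 * mst:
        raise ValueError("duration too short for three steps")

    lead = min(0.15, duration / 20.0)
    steps: list[Step] = []
    t = t0 + lead
    side = "L" if rng.integers(2) == 0 else "R"
    while True:
        sgn = +0.5 if side == "L" else -0.5
        for attempt in range(max_retries + 1):
            st = mst + sgn * profile.asym_step_time + profile.step_time_sd * rng.standard_normal()
            sl = msl + sgn * profile.asym_step_length + profile.step_length_sd * rng.standard_normal()
            if st > 0.25 * mst and sl > 0.05:
                break
        else:
            raise RuntimeError("could not sample a positive step time/length")
        if t + st > t0 + duration - lead:
            break
        stance = (2.0 - profile.swing_fraction) * st
        fc = min(t + stance, t0 + duration - 0.01)
        steps.append(Step(ic_time=t, fc_time=fc, side=side,
                          step_time=st, step_length=sl, step_velocity=sl / st))
        t += st
        side = "R" if side == "L" else "L"
    if len(steps) < 3:
        raise ValueError("duration too short for three steps after sampling")
    return steps


def _ricker(width_s: float, fs: float) -> np.ndarray:
    """Zero-mean Mexican-hat pulse of total width ``width_s`` (odd length)."""
    a = width_s / 6.0
    half = int(round(width_s / 2 * fs))
    t = np.arange(-half, half + 1) / fs
    p = (1.0 - (t / a) ** 2) * np.exp(-t ** 2 / (2 * a ** 2))
    return p


def _add_pulses(sig: np.ndarray, times: np.ndarray, pulse: np.ndarray,
                amps: np.ndarray | float, fs: float, t0: float) -> None:
    half = (len(pulse) - 1) // 2
    amps = np.broadcast_to(np.asarray(amps, dtype=float), np.shape(times))
    for tt, a in zip(np.atleast_1d(times), amps):
        c = int(round((tt - t0) * fs))
        lo, hi = c - half, c + half + 1
        plo, phi = max(0, -lo), len(pulse) - max(0, hi - len(sig))
        lo, hi = max(lo, 0), min(hi, len(sig))
        if lo < hi:
            sig[lo:hi] += a * pulse[plo:phi]


def pendulum_excursion(step_length: float, sensor_height: float) -> float:
    """Vertical CoM excursion h = l - sqrt(l^2 - (SL/2)^2)."""
    half = step_length / 2.0
    if half >= sensor_height:
        raise ValueError(
            f"step length {step_length:.3f} m impossible for pendulum length "
            f"{sensor_height:.3f} m")
    return sensor_height - math.sqrt(sensor_height ** 2 - half ** 2)


def synthesize_acceleration(steps: Sequence[Step], fs: float, sensor_height: float,
                            noise_sd: float, tilt_deg: float,
                            rng_seed: int | np.random.SeedSequence | np.random.Generator,
                            t_start: float = 0.0, t_end: float | None = None,
                            ic_pulse_g: float = 0.6, fc_pulse_g: float = 0.35,
                            pulse_width_s: float = 0.08,
                            clip_g: float = 8.0) -> AccelRecording:
    """Render a tri-axial acceleration recording (g) from a step sequence.

    Vertical channel: per step, the second derivative of the inverted-pendulum
    CoM excursion (peak-to-peak h from the step's true length), plus 1 g
    gravity, a negative Ricker transient at each IC and a positive one at
    each FC; anteroposterior and mediolateral channels carry small locomotor
    oscillations.  The whole vector is rotated by ``tilt_deg`` (static sensor
    tilt in the sagittal plane), white Gaussian noise is added and values are
    clipped to +/-``clip_g``.  Rest periods are gravity plus noise only.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    steps = list(steps)
    if t_end is None:
        t_end = (max(max(s.fc_time, s.ic_time + s.step_time) for s in steps) + 1.0
                 if steps else t_start + 1.0)
    n = int(round((t_end - t_start) * fs))
    t = t_start + np.arange(n) / fs
    vert = np.zeros(n)   # x: vertical, dynamic part in g
    ap = np.zeros(n)     # z: anteroposterior
    ml = np.zeros(n)     # y: mediolateral

    for k, s in enumerate(steps):
        h = pendulum_excursion(s.step_length, sensor_height)
        i0 = int(round((s.ic_time - t_start) * fs))
        i1 = int(round((s.ic_time + s.step_time - t_start) * fs))
        i0c, i1c = max(i0, 0), min(i1, n)
        if i0c >= i1c:
            continue
        ph = 2 * np.pi * (t[i0c:i1c] - s.ic_time) / s.step_time
        amp = (h / 2.0) * (2 * np.pi / s.step_time) ** 2 / G_MS2
        vert[i0c:i1c] += amp * np.cos(ph)
        ap[i0c:i1c] += 0.12 * np.sin(ph)
        ml[i0c:i1c] += (0.06 if s.side == "L" else -0.06) * np.sin(ph / 2.0)

    pulse = _ricker(pulse_width_s, fs)
    ics = np.array([s.ic_time for s in steps])
    fcs = np.array([s.fc_time for s in steps])
    _add_pulses(vert, ics, pulse, -ic_pulse_g, fs, t_start)
    _add_pulses(vert, fcs, pulse, +fc_pulse_g, fs, t_start)

    vert += 1.0  # gravity along the vertical axis
    th = np.deg2rad(tilt_deg)
    x = np.cos(th) * vert - np.sin(th) * ap
    z = np.sin(th) * vert + np.cos(th) * ap
    data = np.column_stack([x, ml, z])
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    np.clip(data, -clip_g, clip_g, out=data)
    return AccelRecording(data=data, fs=fs, t0=t_start)


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    fs: float = 100.0
    noise_sd: float = 0.05
    tilt_deg: float = 5.0
    n_days: int = 7
    lab_duration_s: float = 120.0
    mean_gap_s: float = 6.0
    bout_level_length_sd: float = 0.01  # per-bout random length offset (m)
    groups: dict[str, GroupParams] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def scaled(self, bout_rate: float | None = None, n_days: int | None = None) -> "CohortConfig":
        """Copy with reduced bout rate / day count for desk-scale experiments."""
        cfg = CohortConfig(**{**self.__dict__})
        cfg.groups = dict(self.groups)
        if bout_rate is not None:
            cfg.groups = {g: replace(p, bout_rate=bout_rate) for g, p in cfg.groups.items()}
        if n_days is not None:
            cfg.n_days = n_days
        return cfg


def participant_rng(master_seed: int, participant_index: int,
                    stream: int = 0) -> np.random.Generator:
    """Independent substream per participant: adding participants never
    perturbs existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed,
                               spawn_key=(participant_index, stream)))


def simulate_participant(participant_id: str, group: str, profile: GaitProfile,
                         cfg: CohortConfig, master_seed: int, pidx: int,
                         ) -> list[tuple[dict, AccelRecording, GroundTruth]]:
    """Simulate one lab session plus ``cfg.n_days`` real-world days.

    Returns (metadata, recording, truth) triples; the real-world recording of
    each day covers the active window only (from one minute after midnight to
    shortly after the day's last bout) — the untracked remainder of the day
    is rest and carries no gait information.
    """
    out = []
    rng = participant_rng(master_seed, pidx, stream=1)

    # lab: one continuous 2-min walk at the profile's full (long-bout) gait
    lab_steps = synthesize_step_sequence(profile, cfg.lab_duration_s, rng)
    lab_truth = GroundTruth(bouts=[BoutTruth(
        start=lab_steps[0].ic_time - 0.15, end=lab_steps[-1].fc_time + 0.15,
        steps=lab_steps)])
    lab_rec = synthesize_acceleration(
        lab_steps, cfg.fs, profile.sensor_height, cfg.noise_sd, cfg.tilt_deg,
        rng, t_start=0.0, t_end=cfg.lab_duration_s)
    meta = dict(participant_id=participant_id, group=group, session="lab",
                day=0, fs_hz=cfg.fs, sensor_height_m=profile.sensor_height)
    lab_rec.meta = meta
    out.append((meta, lab_rec, lab_truth))

    schedule = sample_bout_schedule(profile, cfg.n_days, rng, cfg.mean_gap_s)
    for d, day_bouts in enumerate(schedule):
        steps_all: list[Step] = []
        bouts: list[BoutTruth] = []
        for (b0, b1) in day_bouts:
            dur = b1 - b0
            msl, tfac = profile.bout_modifiers(dur)
            msl = max(0.1, msl + cfg.bout_level_length_sd * rng.standard_normal())
            try:
                st = synthesize_step_sequence(profile, dur, rng, mean_step_length=msl,
                                              time_factor=tfac, t0=b0)
            except ValueError:
                continue  # bout too short for 3 steps at this cadence
            bouts.append(BoutTruth(start=st[0].ic_time - 0.15,
                                   end=max(st[-1].fc_time, st[-1].ic_time + st[-1].step_time) + 0.15,
                                   steps=st))
            steps_all.extend(st)
        t0 = d * DAY_S
        t_end = (bouts[-1].end + 5.0) if bouts else (t0 + 60.0)
        rec = synthesize_acceleration(
            steps_all, cfg.fs, profile.sensor_height, cfg.noise_sd, cfg.tilt_deg,
            rng, t_start=t0, t_end=t_end)
        meta = dict(participant_id=participant_id, group=group, session="realworld",
                    day=d, fs_hz=cfg.fs, sensor_height_m=profile.sensor_height)
        rec.meta = meta
        out.append((meta, rec, GroundTruth(bouts=bouts)))
    return out


def _truth_to_csv(truth: GroundTruth, steps_path: Path, bouts_path: Path) -> None:
    with open(steps_path, "w") as f:
        f.write("bout_id,ic_time_s,fc_time_s,side,step_time_s,step_length_m,step_velocity_mps\n")
        for bid, b in enumerate(truth.bouts):
            for s in b.steps:
                f.write(f"{bid},{s.ic_time:.6f},{s.fc_time:.6f},{s.side},"
                        f"{s.step_time:.6f},{s.step_length:.6f},{s.step_velocity:.6f}\n")
    with open(bouts_path, "w") as f:
        f.write("bout_id,start_s,end_s\n")
        for bid, b in enumerate(truth.bouts):
            f.write(f"{bid},{b.start:.6f},{b.end:.6f}\n")


def generate_cohort(n_pd: int, n_hc: int, cfg: CohortConfig, master_seed: int,
                    out_dir: str | Path, force: bool = False) -> list[dict]:
    """Write a full synthetic cohort to ``out_dir``; returns the manifest.

    Layout: ``<out>/<participant>/{lab.csv,lab.json,day0.csv,...}`` plus
    ground-truth step and bout CSVs per session.  Fully reproducible from
    ``master_seed``; per-participant substreams keep participants independent.
    """
    if n_pd < 1 or n_hc < 1:
        raise ValueError("need at least one participant per group")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} exists; pass force=True to overwrite")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = []
    labels = [("PD", i) for i in range(n_pd)] + [("HC", i) for i in range(n_hc)]
    for pidx, (group, gi) in enumerate(labels):
        pid = f"{group}{gi:03d}"
        profile = cfg.groups[group].draw_profile(participant_rng(master_seed, pidx, 0))
        pdir = out_dir / pid
        pdir.mkdir()
        sessions = simulate_participant(pid, group, profile, cfg, master_seed, pidx)
        for meta, rec, truth in sessions:
            stem = "lab" if meta["session"] == "lab" else f"day{meta['day']}"
            write_recording(rec, pdir / f"{stem}.csv", meta)
            _truth_to_csv(truth, pdir / f"{stem}_steps.csv", pdir / f"{stem}_bouts.csv")
        manifest.append(dict(participant_id=pid, group=group,
                             sensor_height_m=profile.sensor_height,
                             n_sessions=len(sessions)))
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(dict(master_seed=master_seed, n_pd=n_pd, n_hc=n_hc,
                       fs=cfg.fs, noise_sd=cfg.noise_sd, tilt_deg=cfg.tilt_deg,
                       n_days=cfg.n_days, participants=manifest), f, indent=1)
    return manifest
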