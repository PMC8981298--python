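"""End-to-end orchestration: simulate -> extract -> aggregate -> stats -> classify.

A single ``RunConfig`` (YAML-serialisable, schema-validated) drives all
stages; a master seed fans out to named substreams per stage; every stage
reads only the previous stage's files and records input hashes in a
manifest, so re-running a stage with unchanged inputs is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf_mod
from .aggregation import aggregate_cohort
from .characteristics import summarize
from .cohort import CohortConfig, DEFAULT_GROUPS, generate_cohort
from .events import TooFewStepsError, extract_steps
from .io import read_recording
from .preprocess import BoutDetectionParams, detect_walking_bouts, estimate_vertical, lowpass20
from .stats import anova_battery, group_test_battery, lab_realworld_correlation

log = logging.getLogger("freegait")


@dataclass
class RunConfig:
    """Every knob of the pipeline, serialised into the run directory."""

    n_pd: int = 10
    n_hc: int = 10
    n_days: int = 7
    master_seed: int = 0
    fs: float = 100.0
    noise_sd: float = 0.05
    tilt_deg: float = 5.0
    bout_rate: float | None = None      # None -> group defaults
    lab_duration_s: float = 120.0
    sd_threshold_g: float = 0.05
    sd_window_s: float = 0.8
    band_hz: tuple = (0.5, 3.0)
    anova_levels: list = field(default_factory=lambda: ["lab", "all_wb", "gt60"])
    classifier_seeds: list = field(default_factory=lambda: list(range(10)))
    grid: str = "default"               # "default" | "small"
    step_weighted: bool = False
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_hc < 1:
            raise ValueError("need at least one participant per group")
        if self.grid not in ("default", "small"):
            raise ValueError("grid must be 'default' or 'small'")
        if self.fs < 50:
            raise ValueError("fs must be >= 50 Hz")

    def cohort_config(self) -> CohortConfig:
        cfg = CohortConfig(fs=self.fs, noise_sd=self.noise_sd,
                           tilt_deg=self.tilt_deg, n_days=self.n_days,
                           lab_duration_s=self.lab_duration_s,
                           groups=dict(DEFAULT_GROUPS))
        if self.bout_rate is not None:
            cfg = cfg.scaled(bout_rate=self.bout_rate)
        return cfg

    def bout_params(self) -> BoutDetectionParams:
        return BoutDetectionParams(window_s=self.sd_window_s,
                                   sd_threshold_g=self.sd_threshold_g,
                                   band_hz=tuple(self.band_hz))


def _hash_paths(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(hashlib.sha256(p.read_bytes()).digest())
    return h.hexdigest()


def _stage_done(run_dir: Path, stage: str, input_hash: str) -> bool:
    f = run_dir / f".{stage}.hash"
    return f.exists() and f.read_text() == input_hash


def _mark_stage(run_dir: Path, stage: str, input_hash: str) -> None:
    (run_dir / f".{stage}.hash").write_text(input_hash)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, run_dir: Path) -> Path:
    cohort_dir = run_dir / "cohort"
    generate_cohort(cfg.n_pd, cfg.n_hc, cfg.cohort_config(), cfg.master_seed,
                    cohort_dir, force=True)
    return cohort_dir


def extract_participant(pdir: Path, bout_params: BoutDetectionParams | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-participant extraction: (lab row, per-bout rows, per-step rows).

    Lab sessions bypass bout detection — the whole 2-min walk is one bout.
    Real-world days run the windowed-SD detector, and per-bout steps feed
    the characteristic summary.
    """
    lab_rows, bout_rows, step_rows = [], [], []
    meta = json.loads((pdir / "lab.json").read_text())
    pid, grp = meta["participant_id"], meta["group"]
    # lumbar-sensor convention: pendulum length 0.53 x body height when
    # height metadata exists, else the recorded sensor height
    if "height_m" in meta:
        l_sensor = 0.53 * float(meta["height_m"])
    else:
        l_sensor = float(meta.get("sensor_height_m", 1.0))

    rec = estimate_vertical(read_recording(pdir / "lab.csv"))
    vf = lowpass20(rec.vertical, rec.fs)
    steps = extract_steps(vf, rec.fs, l_sensor, t0=rec.t0)
    ch = summarize(steps)
    lab_rows.append({"participant_id": pid, "group": grp, **ch.to_dict()})
    step_rows += [{"participant_id": pid, "day": -1, "bout_id": 0, "step_idx": i,
                   "ic_s": s.ic_time, "fc_s": s.fc_time, "step_time_s": s.step_time,
                   "swing_s": s.swing_time, "stance_s": s.stance_time,
                   "length_m": s.step_length, "velocity_mps": s.step_velocity}
                  for i, s in enumerate(steps)]

    day_files = sorted(p for p in pdir.glob("day*.csv") if "_" not in p.stem)
    for day_csv in day_files:
        dmeta = json.loads(day_csv.with_suffix(".json").read_text())
        day = int(dmeta["day"])
        rec = estimate_vertical(read_recording(day_csv))
        vf = lowpass20(rec.vertical, rec.fs)
        bouts = detect_walking_bouts(rec, bout_params)
        for bid, b in enumerate(bouts):
            i0 = int(round((b.start - rec.t0 - 0.3) * rec.fs))
            i1 = int(round((b.end - rec.t0 + 0.3) * rec.fs))
            seg = vf[max(i0, 0):min(i1, rec.n)]
            t0 = rec.t0 + max(i0, 0) / rec.fs
            try:
                steps = extract_steps(seg, rec.fs, l_sensor, t0=t0,
                                      ics=b.ic_times, fcs=b.fc_times)
                ch = summarize(steps)
            except (TooFewStepsError, ValueError):
                continue
            bout_rows.append({"participant_id": pid, "group": grp, "day": day,
                              "bout_id": bid, "start_s": b.start, "end_s": b.end,
                              "duration_s": b.duration, **ch.to_dict()})
            step_rows += [{"participant_id": pid, "day": day, "bout_id": bid,
                           "step_idx": i, "ic_s": s.ic_time, "fc_s": s.fc_time,
                           "step_time_s": s.step_time, "swing_s": s.swing_time,
                           "stance_s": s.stance_time, "length_m": s.step_length,
                           "velocity_mps": s.step_velocity}
                          for i, s in enumerate(steps)]
    return (pd.DataFrame(lab_rows), pd.DataFrame(bout_rows), pd.DataFrame(step_rows))


def stage_extract(cfg: RunConfig, run_dir: Path) -> None:
    cohort_dir = run_dir / "cohort"
    labs, bouts, steps = [], [], []
    for pdir in sorted(d for d in cohort_dir.iterdir() if d.is_dir()):
        la, bo, st = extract_participant(pdir, cfg.bout_params())
        labs.append(la); bouts.append(bo); steps.append(st)
        log.info("extracted %s: %d bouts", pdir.name, len(bo))
    (run_dir / "steps").mkdir(exist_ok=True)
    pd.concat(labs, ignore_index=True).to_csv(run_dir / "steps" / "lab.csv", index=False)
    pd.concat(bouts, ignore_index=True).to_csv(run_dir / "steps" / "bouts.csv", index=False)
    pd.concat(steps, ignore_index=True).to_csv(run_dir / "steps" / "steps.csv", index=False)


def stage_aggregate(cfg: RunConfig, run_dir: Path) -> None:
    lab = pd.read_csv(run_dir / "steps" / "lab.csv")
    bouts = pd.read_csv(run_dir / "steps" / "bouts.csv")
    agg = aggregate_cohort(bouts, lab, step_weighted=cfg.step_weighted)
    agg.to_csv(run_dir / "aggregated.csv", index=False)


def stage_stats(cfg: RunConfig, run_dir: Path) -> None:
    agg = pd.read_csv(run_dir / "aggregated.csv")
    sdir = run_dir / "stats"
    sdir.mkdir(exist_ok=True)
    anova_battery(agg, cfg.anova_levels).to_csv(sdir / "mixed_anova.csv", index=False)
    group_test_battery(agg).to_csv(sdir / "group_tests.csv", index=False)
    lab_realworld_correlation(agg).to_csv(sdir / "lab_rw_correlation.csv", index=False)


def stage_classify(cfg: RunConfig, run_dir: Path) -> None:
    agg = pd.read_csv(run_dir / "aggregated.csv")
    design = clf_mod.build_design(agg)
    grids = clf_mod.small_grids() if cfg.grid == "small" else clf_mod.default_grids()
    report = clf_mod.train_evaluate(design, seeds=cfg.classifier_seeds, grids=grids)
    cdir = run_dir / "classification"
    cdir.mkdir(exist_ok=True)
    report.summary.to_csv(cdir / "summary.csv", index=False)
    (cdir / "report.json").write_text(report.to_json())


STAGES = {"simulate": stage_simulate, "extract": stage_extract,
          "aggregate": stage_aggregate, "stats": stage_stats,
          "classify": stage_classify}
STAGE_INPUTS = {"simulate": [], "extract": ["cohort"], "aggregate": ["steps"],
                "stats": ["aggregated.csv"], "classify": ["aggregated.csv"]}


def run_all(config: RunConfig | str | Path, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in order under ``config.out_dir``.

    Each stage hashes its input files; when the hash matches the previous
    run the stage is skipped (idempotence).  Any stage failure aborts with
    the stage name.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.yaml", "w") as f:
        yaml.safe_dump(asdict(cfg), f)

    for stage in stages or list(STAGES):
        inputs = []
        for rel in STAGE_INPUTS[stage]:
            p = run_dir / rel
            inputs += ([p] if p.is_file() else sorted(p.rglob("*.csv")) if p.exists() else [])
        key = hashlib.sha256(
            (json.dumps(asdict(cfg), sort_keys=True, default=str) + stage).encode()
        ).hexdigest() if stage == "simulate" else _hash_paths(inputs)
        if _stage_done(run_dir, stage, key):
            log.info("stage %s up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            STAGES[stage](cfg, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _mark_stage(run_dir, stage, key)

    manifest = {"config": asdict(cfg),
                "stages": {s: (run_dir / f".{s}.hash").read_text()
                           for s in (stages or list(STAGES))
                           if (run_dir / f".{s}.hash").exists()}}
    (run_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return run_dir
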