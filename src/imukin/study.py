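"""End-to-end experiment orchestration.

Runs the two evaluation schemes on a simulated cohort and produces the
channel-comparison tables:

* intraparticipant — train on one participant's four treadmill segments
  (concatenated in ascending speed order), test on that participant's
  level-ground segment;
* interparticipant — leave-one-out over the cohort: each fold trains on the
  pooled treadmill frames of all other participants and tests on the held-out
  participant's level-ground segment.

Each (scheme, joint, channel, participant) cell gets an independent model and
a six-statistic report; accelerometer and gyroscope are then compared with
paired t-tests across participants, parameter by parameter.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn, metrics, prep, synthetic

SCHEMES = ("intra", "inter")
#: parameters compared with paired t-tests (ROM is reported but not tested)
TESTED_PARAMETERS = ("r2", "rmse", "nrmse", "std", "nstd")


class DataError(RuntimeError):
    """A required session or pairing is missing."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one study run."""

    n_participants: int = 10
    master_seed: int = 0
    channels: tuple[str, ...] = prep.CHANNELS
    joints: tuple[str, ...] = prep.JOINTS
    schemes: tuple[str, ...] = SCHEMES
    treadmill: synthetic.SurfaceModel = synthetic.TREADMILL
    level_ground: synthetic.SurfaceModel = synthetic.LEVEL_GROUND
    session_duration: float = synthetic.SESSION_DURATION_S
    plan: prep.SegmentationPlan = prep.SegmentationPlan()
    epochs: int = 50
    #: epochs for leave-one-out folds; None means same as ``epochs``. The
    #: full protocol trains both schemes for 50 epochs (both are at their
    #: plateau); scaled-down runs can match optimizer-step budgets across
    #: schemes instead, since an inter fold sees (n-1)x the frames per epoch.
    inter_epochs: int | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one scheme is required")
        if "inter" in self.schemes and self.n_participants < 2:
            raise ValueError("the leave-one-out scheme needs >= 2 participants")
        if abs(self.plan.session_duration - self.session_duration) > 1e-9:
            raise ValueError("segmentation plan does not cover the session duration")

    def model_config(self, seed: int, scheme: str = "intra") -> cnn.ModelConfig:
        epochs = (self.inter_epochs if scheme == "inter"
                  and self.inter_epochs is not None else self.epochs)
        return cnn.ModelConfig(epochs=epochs, rng_seed=seed)


def smoke_config(n_participants: int = 4, master_seed: int = 0,
                 joints: tuple[str, ...] = ("knee",),
                 schemes: tuple[str, ...] = SCHEMES,
                 epochs: int = 5, **kwargs) -> StudyConfig:
    """A scaled-down configuration for quick end-to-end runs.

    Sessions shrink to 30 s (10 s head buffer covering the sync preamble, one
    16 s analysis segment, 4 s tail buffer) and training to a few epochs; the
    protocol structure — speeds, schemes, per-cell models — is unchanged.
    """
    return StudyConfig(
        n_participants=n_participants, master_seed=master_seed,
        joints=joints, schemes=schemes, session_duration=30.0,
        plan=prep.SegmentationPlan(buffer_head=10.0, buffer_tail=4.0,
                                   split=(16.0,), selected_segment=0),
        epochs=epochs, **kwargs)


@dataclass
class StudyResult:
    """Per-cell metric reports plus the channel-comparison table."""

    config: StudyConfig
    reports: dict[tuple[str, str, str, str], metrics.MetricsReport]
    comparisons: list[dict]
    provenance: dict = field(default_factory=dict)

    def reports_frame(self) -> pd.DataFrame:
        rows = []
        for (scheme, joint, channel, pid), rep in sorted(self.reports.items()):
            rows.append({"scheme": scheme, "joint": joint, "channel": channel,
                         "participant": pid, **vars(rep)})
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.comparisons)

    def mean_r2(self, scheme: str, channel: str, joint: str | None = None) -> float:
        vals = [rep.r2 for (s, j, c, _), rep in self.reports.items()
                if s == scheme and c == channel and (joint is None or j == joint)]
        if not vals:
            raise DataError(f"no reports for scheme={scheme}, channel={channel}")
        return float(np.mean(vals))


def _cell_seed(master_seed: int, scheme: str, joint: str, channel: str,
               fold: int) -> int:
    ss = np.random.SeedSequence([master_seed, SCHEMES.index(scheme),
                                 prep.JOINTS.index(joint),
                                 prep.CHANNELS.index(channel), fold])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def build_frame_cache(sessions: dict[str, list[synthetic.Session]],
                      config: StudyConfig,
                      ) -> dict[tuple[str, str, str], tuple[prep.FrameSet, prep.FrameSet]]:
    """Per (participant, channel, joint): (treadmill training, level-ground test).

    Training frames pool the four treadmill segments in ascending speed order;
    frames are built per segment, so none spans a speed boundary.
    """
    cache = {}
    for pid, sess_list in sessions.items():
        treadmill = sorted((s for s in sess_list if s.surface == "treadmill"),
                           key=lambda s: s.speed)
        level = [s for s in sess_list if s.surface == "level_ground"]
        if len(treadmill) != len(synthetic.TREADMILL_SPEEDS) or len(level) != 1:
            raise DataError(f"participant {pid} is missing sessions")
        for channel in config.channels:
            for joint in config.joints:
                train = prep.concat_frames([
                    prep.session_frames(s, channel, joint, config.plan)
                    for s in treadmill])
                test = prep.session_frames(level[0], channel, joint, config.plan)
                cache[(pid, channel, joint)] = (train, test)
    return cache


def _fit_and_score(train_fs: prep.FrameSet, test_fs: prep.FrameSet,
                   joint: str, model_config: cnn.ModelConfig,
                   ) -> metrics.MetricsReport:
    model = cnn.build_model(model_config)
    trained = cnn.train(model, train_fs)
    preds, _ = cnn.predict(trained, test_fs)
    return metrics.evaluate_trace(test_fs.Y[:, 0].astype(float), preds, joint)


def run_intra(config: StudyConfig, frame_cache, participants: list[str],
              ) -> dict[tuple[str, str, str, str], metrics.MetricsReport]:
    """Train and test within each participant (treadmill -> level ground)."""
    out = {}
    for fold, pid in enumerate(participants):
        for channel in config.channels:
            for joint in config.joints:
                train_fs, test_fs = frame_cache[(pid, channel, joint)]
                seed = _cell_seed(config.master_seed, "intra", joint, channel, fold)
                out[("intra", joint, channel, pid)] = _fit_and_score(
                    train_fs, test_fs, joint, config.model_config(seed))
    return out


def inter_folds(participants: list[str]) -> list[tuple[str, list[str]]]:
    """Leave-one-out fold manifests: (held-out participant, training set)."""
    return [(pid, [p for p in participants if p != pid]) for pid in participants]


def run_inter(config: StudyConfig, frame_cache, participants: list[str],
              ) -> dict[tuple[str, str, str, str], metrics.MetricsReport]:
    """Leave-one-out: fold k pools every other participant's treadmill frames."""
    if len(participants) < 2:
        raise ValueError("the leave-one-out scheme needs >= 2 participants")
    out = {}
    for fold, (pid, others) in enumerate(inter_folds(participants)):
        for channel in config.channels:
            for joint in config.joints:
                train_fs = prep.concat_frames(
                    [frame_cache[(p, channel, joint)][0] for p in others])
                test_fs = frame_cache[(pid, channel, joint)][1]
                seed = _cell_seed(config.master_seed, "inter", joint, channel, fold)
                out[("inter", joint, channel, pid)] = _fit_and_score(
                    train_fs, test_fs, joint, config.model_config(seed, "inter"))
    return out


def compare_channels(reports: dict[tuple[str, str, str, str], metrics.MetricsReport],
                     ) -> list[dict]:
    """Paired accelerometer-vs-gyroscope t-tests per (scheme, joint, parameter).

    Rows follow the report-table layout: the five tested parameters per joint
    plus the untested ROM row (mean and SD only). Raises
    :class:`~imukin.metrics.DegenerateTestError` if a parameter's paired
    differences have zero variance, naming the row.
    """
    schemes = sorted({k[0] for k in reports}, key=SCHEMES.index)
    joints = sorted({k[1] for k in reports}, key=prep.JOINTS.index)
    rows = []
    for scheme in schemes:
        for joint in joints:
            pids = sorted({k[3] for k in reports if k[:2] == (scheme, joint)})
            by_chan = {}
            for channel in prep.CHANNELS:
                cell = {}
                for pid in pids:
                    key = (scheme, joint, channel, pid)
                    if key not in reports:
                        raise DataError(f"participant {pid} lacks a "
                                        f"{channel} report for {scheme}/{joint}")
                    cell[pid] = reports[key]
                by_chan[channel] = cell
            accel, gyro = by_chan["accel_y"], by_chan["gyro_resultant_xz"]
            for param in TESTED_PARAMETERS:
                a = np.array([getattr(accel[p], param) for p in pids])
                g = np.array([getattr(gyro[p], param) for p in pids])
                try:
                    cmp_res = metrics.paired_comparison(a, g, param)
                except metrics.DegenerateTestError as exc:
                    raise metrics.DegenerateTestError(
                        f"{scheme}/{joint}/{param}: {exc}") from exc
                rows.append({"scheme": scheme, "joint": joint, "parameter": param,
                             "mean_accel": cmp_res.mean_accel,
                             "sd_accel": cmp_res.sd_accel,
                             "mean_gyro": cmp_res.mean_gyro,
                             "sd_gyro": cmp_res.sd_gyro,
                             "t": cmp_res.t_statistic, "p": cmp_res.p_value,
                             "significant": cmp_res.significant,
                             "r2_label_accel": (cmp_res.r2_interpretation or (None, None))[0],
                             "r2_label_gyro": (cmp_res.r2_interpretation or (None, None))[1]})
            roms = np.array([accel[p].rom for p in pids])
            rows.append({"scheme": scheme, "joint": joint, "parameter": "rom",
                         "mean_accel": float(roms.mean()),
                         "sd_accel": float(roms.std(ddof=1)) if roms.size > 1 else float("nan"),
                         "mean_gyro": float(roms.mean()),
                         "sd_gyro": float(roms.std(ddof=1)) if roms.size > 1 else float("nan"),
                         "t": None, "p": None, "significant": None,
                         "r2_label_accel": None, "r2_label_gyro": None})
    return rows


def run_study(config: StudyConfig,
              cohort: list[synthetic.ParticipantProfile] | None = None,
              ) -> StudyResult:
    """Simulate, prepare, train and evaluate a complete study."""
    t_start = time.time()
    if cohort is None:
        cohort = synthetic.make_cohort(config.n_participants, config.master_seed)
    sessions = synthetic.simulate_study(
        cohort, config.master_seed, treadmill=config.treadmill,
        level_ground=config.level_ground, duration=config.session_duration)
    participants = [p.participant_id for p in cohort]
    frame_cache = build_frame_cache(sessions, config)
    reports: dict = {}
    if "intra" in config.schemes:
        reports.update(run_intra(config, frame_cache, participants))
    if "inter" in config.schemes:
        reports.update(run_inter(config, frame_cache, participants))
    comparisons = (compare_channels(reports)
                   if set(prep.CHANNELS) <= set(config.channels) else [])
    result = StudyResult(
        config=config, reports=reports, comparisons=comparisons,
        provenance={"master_seed": config.master_seed,
                    "n_participants": config.n_participants,
                    "epochs": config.epochs,
                    "session_duration_s": config.session_duration,
                    "runtime_s": round(time.time() - t_start, 1)})
    if config.outdir:
        write_result(result, config.outdir)
    return result


def write_result(result: StudyResult, outdir: str | Path) -> None:
    """Write per-cell reports, the comparison table and a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.reports_frame().to_csv(outdir / "reports.csv", index=False)
    result.comparisons_frame().to_csv(outdir / "comparisons.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.provenance, indent=1))
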