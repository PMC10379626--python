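"""Synthetic carving-run and boot-fit data with exact ground truth.

The generator emulates the study design the analysis assumes: a cohort of
expert skiers, each skiing three trials per boot configuration (BOA wrap
closure vs. Buckle), making aggressive alternating carving turns, plus an
in-lab static pressure session (three boot conditions with a recorded shell
overlap) and a post-series subjective questionnaire.

On-snow runs
------------
Time is laid out as a short lead-in followed by ``turns_per_run`` full roll
cycles of ``turn_period`` seconds; each cycle holds two turn arcs (right
then left), so force apices alternate feet every half cycle.  The boot roll
angle is a half-sine bump per arc with alternating sign; the gyroscope
reports its analytic derivative plus white noise and a per-run constant
bias (the drift that the edge-angle pipeline's endpoint-anchored linear
correction removes exactly).

Each foot's total normal force is a C1 piecewise raised-cosine curve through
per-turn keyframes: its apex peak ``P``, the valley ``V`` it reaches
``time_to_peak`` seconds before its next apex with ``V = P - RFD x
time_to_peak`` (so the rate of force development measured as the secant from
minimum to maximum equals the injected value per turn), and an intermediate
rising keyframe ``U`` pinned to the trailing edge of the other foot's
symmetric 1-s apex window — the measured uphill peak.  Zero slope at every
keyframe makes the measured quantities insensitive to small errors in peak
localisation.  The total is split 30/40/30% across heel / medial forefoot /
lateral forefoot.

Effect structure (defaults = the study's printed effect sizes): peak force
+4% (30 N) in BOA, RFD +10%, time-to-peak -7% (0.13 s), uphill peak +6%,
+40 N on left turns (off-camber slope), -10 N per trial (deteriorating
snow), subject random intercepts (SD 60 N) and subject-by-configuration
random slopes (SD 15 N).

Static trials
-------------
Dorsal pads carry a smooth instep-centred pattern scaled by 0.88 under BOA
(-12% mean); plantar insoles carry heel/metatarsal-loaded patterns with the
lateral-heel peak scaled by 0.86 (-14%) and both midfoot regions by 0.90
(-10%) under BOA; shell overlap acts as an additive covariate on every
sensel.  Subjective scores are drawn around the study's per-item means.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .force_features import ForceTrace
from .imu_edge import KinematicTrace
from .signal_core import UniformSeries
from .static_pressure import (
    DORSAL_SHAPE,
    PLANTAR_ACTIVE_SENSELS,
    PLANTAR_SHAPE,
    PressureGrid,
    build_region_scheme,
    dorsal_sensel_area_cm2,
    plantar_sensel_area_cm2,
)

__all__ = [
    "SimConfig",
    "TurnTruth",
    "RunTruth",
    "RunBundle",
    "StaticTruth",
    "StaticTrial",
    "CohortBundle",
    "SUBJECTIVE_ITEMS",
    "SUBJECTIVE_TABLE",
    "STATIC_CONDITIONS",
    "simulate_run",
    "simulate_static_trial",
    "simulate_subjective",
    "simulate_cohort",
    "plantar_active_mask",
    "cosine_keyframes",
]

CONFIGS = ("BOA", "Buckle")
STATIC_CONDITIONS = ("BOA_preferred", "Buckle_preferred", "BOA_at_buckle_overlap")
REGION_PROPORTIONS = (0.30, 0.40, 0.30)  # heel / medial forefoot / lateral forefoot

SUBJECTIVE_ITEMS = (
    "exertion", "carving", "confidence", "overall_fit",
    "forefoot", "midfoot", "heel", "cuff",
)
# Study means and SDs per item: {"item": {"BOA": (mean, sd), "Buckle": (mean, sd)}}
SUBJECTIVE_TABLE = {
    "exertion":    {"BOA": (2.5, 1.8), "Buckle": (2.5, 2.0)},
    "carving":     {"BOA": (8.5, 1.4), "Buckle": (7.9, 1.6)},
    "confidence":  {"BOA": (8.8, 1.2), "Buckle": (8.2, 1.7)},
    "overall_fit": {"BOA": (8.0, 1.7), "Buckle": (6.5, 2.1)},
    "forefoot":    {"BOA": (4.8, 1.7), "Buckle": (5.8, 2.5)},
    "midfoot":     {"BOA": (5.1, 0.9), "Buckle": (6.1, 2.2)},
    "heel":        {"BOA": (4.7, 1.0), "Buckle": (4.6, 1.5)},
    "cuff":        {"BOA": (5.0, 1.4), "Buckle": (5.8, 1.2)},
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults encode the study conditions."""

    n_subjects: int = 20
    runs_per_config: int = 3
    turns_per_run: int = 8            # full roll cycles; two turn arcs each
    turn_period: float = 3.0          # s per roll cycle
    lead_in_s: float = 1.0
    imu_rate: float = 1125.0
    force_rate: float = 100.0
    # injected on-snow effects (N, N/s, s)
    baseline_peak_force: float = 750.0
    config_effect_peak_force: float = 30.0
    baseline_rfd: float = 340.0
    config_effect_rfd: float = 34.0
    baseline_time_to_peak: float = 1.86
    config_effect_time_to_peak: float = -0.13
    baseline_uphill_peak: float = 583.0
    config_effect_uphill_peak: float = 35.0
    turn_direction_effect: float = 40.0
    trial_slope: float = -10.0
    subject_sd_intercept: float = 60.0
    subject_sd_slope: float = 15.0
    rfd_subject_sd: float = 10.0
    uphill_subject_sd: float = 45.0
    # per-turn scatter
    peak_turn_sd: float = 15.0
    rfd_turn_sd: float = 12.0
    ttp_turn_sd: float = 0.05
    uphill_turn_sd: float = 12.0
    valley_floor: float = 20.0
    # sensor noise
    force_noise_sd: float = 10.0
    gyro_noise_sd: float = 3.0
    gyro_bias_sd: float = 1.0
    edge_angle_max: float = 45.0
    edge_angle_turn_sd: float = 1.5
    # static pressure
    dorsal_baseline_mean: float = 30.0
    dorsal_config_multiplier: float = 0.88
    lateral_heel_config_multiplier: float = 0.86
    midfoot_config_multiplier: float = 0.90
    overlap_slope: float = 1.0        # kPa per overlap unit
    dorsal_subject_sd: float = 3.0
    plantar_subject_sd: float = 4.0
    dorsal_frame_noise_sd: float = 4.0
    plantar_frame_noise_sd: float = 3.0
    n_static_frames: int = 10
    n_static_subjects: int = 10
    subjective_subject_sd_frac: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.turn_period <= 0 or self.imu_rate <= 0 or self.force_rate <= 0:
            raise ValueError("rates and periods must be positive")
        for m in ("dorsal_config_multiplier", "lateral_heel_config_multiplier",
                  "midfoot_config_multiplier"):
            if getattr(self, m) <= 0:
                raise ValueError(f"{m} must be > 0")
        if self.turns_per_run < 1 or self.n_subjects < 1:
            raise ValueError("need at least one turn and one subject")

    @property
    def arc_duration(self) -> float:
        return self.turn_period / 2.0

    @property
    def run_duration(self) -> float:
        return self.lead_in_s + self.turns_per_run * self.turn_period


@dataclass(frozen=True)
class TurnTruth:
    """Exact per-arc ground truth for the force and angle pipelines."""

    arc_index: int
    downhill_foot: str        # foot under which the force peaks
    turn_direction: str       # opposite of the downhill foot
    apex_time: float          # s
    flat_time: float          # arc start (ski flat) s
    peak_force: float         # N
    uphill_force: float       # N, other foot's value in the 1-s apex window
    valley_force: float       # N, minimum before the apex
    time_to_peak: float       # s
    rfd: float                # N/s == (peak - valley) / time_to_peak
    average_force: float      # N, analytic mean of the rise segment
    edge_angle: float         # deg, arc's true peak edge angle


@dataclass(frozen=True)
class RunTruth:
    subject_id: str
    config: str
    trial_no: int
    flat_times: np.ndarray    # ski-flat boundary times incl. both ends
    turns: list[TurnTruth]
    gyro_bias: dict           # side -> deg/s


@dataclass(frozen=True)
class RunBundle:
    subject_id: str
    config: str
    trial_no: int
    imu_left: KinematicTrace
    imu_right: KinematicTrace
    force_left: ForceTrace
    force_right: ForceTrace
    truth: RunTruth


@dataclass(frozen=True)
class StaticTruth:
    subject_id: str
    condition: str
    config: str               # model-level label: BOA or Buckle
    overlap: float
    dorsal_mean: float        # noise-free whole-pad mean
    region_peaks: dict        # region -> noise-free peak (kPa)
    multipliers: dict


@dataclass(frozen=True)
class StaticTrial:
    dorsal: PressureGrid      # time-averaged over the frames
    plantar: PressureGrid
    dorsal_frames: list
    plantar_frames: list
    truth: StaticTruth


@dataclass(frozen=True)
class CohortBundle:
    config: SimConfig
    runs: list
    statics: list
    subjective: pd.DataFrame
    subject_ids: list


# ---------------------------------------------------------------------------
# primitives


def cosine_keyframes(times: np.ndarray, key_t: np.ndarray, key_v: np.ndarray) -> np.ndarray:
    """Piecewise raised-cosine interpolation through keyframes.

    Monotone between consecutive keyframes with zero slope at each one, so
    every keyframe is a robust local extremum or saddle of the curve.
    ``key_t`` must be strictly increasing and bracket ``times``.
    """
    key_t = np.asarray(key_t, float)
    key_v = np.asarray(key_v, float)
    if np.any(np.diff(key_t) <= 0):
        raise ValueError("keyframe times must be strictly increasing")
    seg = np.clip(np.searchsorted(key_t, times, side="right") - 1, 0, len(key_t) - 2)
    t0, t1 = key_t[seg], key_t[seg + 1]
    v0, v1 = key_v[seg], key_v[seg + 1]
    phase = (times - t0) / (t1 - t0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * np.clip(phase, 0, 1)))


def _rng_for(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), *key]))


@dataclass(frozen=True)
class _SubjectEffects:
    force_intercept: float
    force_slope_boa: float
    rfd_intercept: float
    uphill_intercept: float
    dorsal_intercept: float
    plantar_intercept: float
    subjective_intercept: float
    overlap_buckle: float


def _subject_effects(cfg: SimConfig, subject_index: int) -> _SubjectEffects:
    rng = _rng_for(cfg, 1, subject_index)
    return _SubjectEffects(
        force_intercept=rng.normal(0.0, cfg.subject_sd_intercept),
        force_slope_boa=rng.normal(0.0, cfg.subject_sd_slope),
        rfd_intercept=rng.normal(0.0, cfg.rfd_subject_sd),
        uphill_intercept=rng.normal(0.0, cfg.uphill_subject_sd),
        dorsal_intercept=rng.normal(0.0, cfg.dorsal_subject_sd),
        plantar_intercept=rng.normal(0.0, cfg.plantar_subject_sd),
        subjective_intercept=rng.normal(0.0, 1.0),
        overlap_buckle=rng.normal(0.0, 0.8),
    )


# ---------------------------------------------------------------------------
# on-snow runs


def _draw_arcs(cfg: SimConfig, rng, boa: int, trial: int, eff: _SubjectEffects):
    """Per-arc truth draws for virtual arcs -2..2n+1 (pads for keyframing)."""
    n_arcs = 2 * cfg.turns_per_run
    idx = np.arange(-2, n_arcs + 2)
    m = len(idx)
    left_turn = (idx % 2 != 0).astype(float)  # even arc = right turn
    peak = (
        cfg.baseline_peak_force
        + cfg.config_effect_peak_force * boa
        + cfg.turn_direction_effect * left_turn
        + cfg.trial_slope * trial
        + eff.force_intercept
        + eff.force_slope_boa * boa
        + rng.normal(0.0, cfg.peak_turn_sd, m)
    )
    # the minimum must fall between the descent keyframe 0.7 s after the
    # previous own peak and the start of the uphill plateau 1.3 s pre-peak
    ttp = np.clip(
        cfg.baseline_time_to_peak
        + cfg.config_effect_time_to_peak * boa
        + rng.normal(0.0, cfg.ttp_turn_sd, m),
        1.56,
        2.0 * cfg.arc_duration - 0.9,
    )
    rfd = (
        cfg.baseline_rfd
        + cfg.config_effect_rfd * boa
        + eff.rfd_intercept
        + rng.normal(0.0, cfg.rfd_turn_sd, m)
    )
    valley = np.maximum(peak - rfd * ttp, cfg.valley_floor)
    rfd = (peak - valley) / ttp  # re-record truth where the floor bit
    uphill = (
        cfg.baseline_uphill_peak
        + cfg.config_effect_uphill_peak * boa
        + eff.uphill_intercept
        + rng.normal(0.0, cfg.uphill_turn_sd, m)
    )
    # U for turn j sits on the rise of the *next* arc's foot (valley V[j+1]
    # up to peak P[j+1]) and doubles as that foot's descent keyframe before
    # V[j+3]; monotone cosine segments need V < U < P
    for j in range(m - 1):
        uphill[j] = min(uphill[j], peak[j + 1] - 30.0)
        lo = valley[j + 1] if j + 3 >= m else max(valley[j + 1], valley[j + 3])
        uphill[j] = max(uphill[j], lo + 70.0)
    edge = cfg.edge_angle_max + rng.normal(0.0, cfg.edge_angle_turn_sd, m)
    return {
        "idx": idx, "peak": peak, "ttp": ttp, "rfd": rfd,
        "valley": valley, "uphill": uphill, "edge": np.abs(edge),
    }


def _foot_force(cfg: SimConfig, arcs: dict, foot_parity: int, times: np.ndarray):
    """Keyframe curve for the foot that is downhill on arcs of ``foot_parity``.

    Between consecutive own apices (2 arcs apart) the foot descends from its
    peak to the next turn's valley, then rises through the intermediate
    other-foot apex window — holding the drawn uphill value at that window's
    trailing edge (a zero-slope keyframe) — up to its next peak.
    """
    pad, arc_d = cfg.lead_in_s, cfg.arc_duration
    pos = {int(a): j for j, a in enumerate(arcs["idx"])}
    key_t, key_v = [], []
    own = [int(a) for a in arcs["idx"] if a % 2 == foot_parity % 2]
    for a in own:
        j = pos[a]
        apex = pad + a * arc_d + arc_d / 2.0
        key_t.append(apex)
        key_v.append(arcs["peak"][j])
        if a + 2 in pos:
            j2 = pos[a + 2]
            other_apex = apex + arc_d
            # descent mirrors the rise's last 0.7 s so the smoothed peak
            # stays centred on the true apex
            key_t.append(apex + 0.7)
            key_v.append(arcs["uphill"][pos.get(a - 1, pos[a + 1])])
            # symmetric flanking keyframes around the true minimum time, so
            # zero-phase filtering cannot drag the minimum sideways
            t_v = apex + 2 * arc_d - arcs["ttp"][j2]
            key_t.append(t_v - 0.15)
            key_v.append(arcs["valley"][j2] + 40.0)
            key_t.append(t_v)
            key_v.append(arcs["valley"][j2])
            key_t.append(t_v + 0.15)
            key_v.append(arcs["valley"][j2] + 40.0)
            # uphill plateau spanning the other foot's apex-window edge;
            # the short ease-in keeps filter ringing below the plateau value
            u_next = arcs["uphill"][pos[a + 1]]
            key_t.append(other_apex + 0.1)
            key_v.append(u_next - 20.0)
            key_t.append(other_apex + 0.2)
            key_v.append(u_next)
            key_t.append(other_apex + 0.8)
            key_v.append(u_next)
    key_t, key_v = np.asarray(key_t), np.asarray(key_v)
    keep = np.concatenate(([True], np.diff(key_t) > 1e-9))
    return cosine_keyframes(times, key_t[keep], key_v[keep])


def _roll_rate(cfg: SimConfig, arcs: dict, times: np.ndarray) -> np.ndarray:
    """Analytic derivative of the alternating half-sine edge-angle bumps."""
    pad, arc_d = cfg.lead_in_s, cfg.arc_duration
    a = np.floor((times - pad) / arc_d).astype(int)
    a = np.clip(a, arcs["idx"][0], arcs["idx"][-1])
    j = a - arcs["idx"][0]
    amp = arcs["edge"][j]
    sign = np.where(a % 2 == 0, 1.0, -1.0)
    phase = (times - pad - a * arc_d) / arc_d
    return sign * amp * (np.pi / arc_d) * np.cos(np.pi * phase)


def simulate_run(
    subject: int,
    config: str,
    trial: int,
    seed: int | None = None,
    sim_config: SimConfig | None = None,
    include_imu: bool = True,
) -> RunBundle:
    """One carving run: bilateral IMU and insole traces plus ground truth.

    ``subject`` is the 0-based subject index, ``config`` "BOA" or "Buckle",
    ``trial`` the 1-based trial number within the configuration.  The same
    (seed, subject, config, trial) always yields identical output.
    """
    if config not in CONFIGS:
        raise ValueError(f"unknown config {config!r}")
    cfg = sim_config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    boa = int(config == "BOA")
    eff = _subject_effects(cfg, subject)
    rng = _rng_for(cfg, 2, subject, boa, trial)

    arcs = _draw_arcs(cfg, rng, boa, trial, eff)
    dur = cfg.run_duration
    n_force = int(round(dur * cfg.force_rate)) + 1
    t_force = np.arange(n_force) / cfg.force_rate

    traces = {}
    for side, parity in (("left", 0), ("right", 1)):
        total = _foot_force(cfg, arcs, parity, t_force)
        regions = []
        for prop in REGION_PROPORTIONS:
            noise = rng.normal(0.0, cfg.force_noise_sd / np.sqrt(3.0), n_force)
            regions.append(np.maximum(total * prop + noise, 0.0))
        traces[side] = ForceTrace(
            UniformSeries(regions[0], cfg.force_rate),
            UniformSeries(regions[1], cfg.force_rate),
            UniformSeries(regions[2], cfg.force_rate),
            side,
        )

    bias = {}
    imu = {}
    if include_imu:
        n_imu = int(round(dur * cfg.imu_rate)) + 1
        t_imu = np.arange(n_imu) / cfg.imu_rate
        rate = _roll_rate(cfg, arcs, t_imu)
        for side in ("left", "right"):
            bias[side] = float(rng.normal(0.0, cfg.gyro_bias_sd))
            noisy = rate + bias[side] + rng.normal(0.0, cfg.gyro_noise_sd, n_imu)
            imu[side] = KinematicTrace(UniformSeries(noisy, cfg.imu_rate), side)
    else:
        for side in ("left", "right"):
            flat = UniformSeries(np.zeros(2), cfg.imu_rate)
            imu[side] = KinematicTrace(flat, side)

    pad, arc_d = cfg.lead_in_s, cfg.arc_duration
    n_arcs = 2 * cfg.turns_per_run
    pos = {int(a): j for j, a in enumerate(arcs["idx"])}
    turns = []
    for a in range(n_arcs):
        j = pos[a]
        foot = "left" if a % 2 == 0 else "right"
        peak, valley, ttp = arcs["peak"][j], arcs["valley"][j], arcs["ttp"][j]
        # rise: 0.15 s to the flank value, climb to the plateau ease-in by
        # 1.4 s pre-peak, 0.1 s ease, 0.6 s plateau, 0.7 s climb to the peak
        u_prev = arcs["uphill"][pos[a - 1]]
        flank = valley + 40.0
        avg = (
            0.15 * (valley + flank) / 2.0
            + (ttp - 1.55) * (flank + u_prev - 20.0) / 2.0
            + 0.1 * (u_prev - 10.0)
            + 0.6 * u_prev
            + 0.7 * (u_prev + peak) / 2.0
        ) / ttp
        turns.append(
            TurnTruth(
                arc_index=a,
                downhill_foot=foot,
                turn_direction="right" if foot == "left" else "left",
                apex_time=pad + a * arc_d + arc_d / 2.0,
                flat_time=pad + a * arc_d,
                peak_force=float(peak),
                uphill_force=float(arcs["uphill"][j]),
                valley_force=float(valley),
                time_to_peak=float(ttp),
                rfd=float(arcs["rfd"][j]),
                average_force=float(avg),
                edge_angle=float(arcs["edge"][j]),
            )
        )
    truth = RunTruth(
        subject_id=f"S{subject:02d}",
        config=config,
        trial_no=trial,
        flat_times=pad + arc_d * np.arange(n_arcs + 1),
        turns=turns,
        gyro_bias=bias,
    )
    return RunBundle(
        subject_id=truth.subject_id, config=config, trial_no=trial,
        imu_left=imu["left"], imu_right=imu["right"],
        force_left=traces["left"], force_right=traces["right"], truth=truth,
    )


# ---------------------------------------------------------------------------
# static pressure


def plantar_active_mask() -> np.ndarray:
    """Deterministic foot-shaped mask with exactly 235 active sensels.

    Row 0 is the heel end; widths narrow through the midfoot (arch) and widen
    across the metatarsals.  Returned for a right foot (medial = column 0
    side); mirror with ``np.fliplr`` for a left foot.
    """
    widths = (
        [6, 7]                      # heel tip
        + [8] * 7                   # heel body (rows 2-8)
        + [6] * 7                   # midfoot / arch (rows 9-15)
        + [7] * 2                   # arch-to-met transition (rows 16-17)
        + [9] * 8                   # metatarsals (rows 18-25)
        + [9, 8, 8, 7, 6]           # toes (rows 26-30)
    )
    assert len(widths) == PLANTAR_SHAPE[0] and sum(widths) == PLANTAR_ACTIVE_SENSELS
    mask = np.zeros(PLANTAR_SHAPE, dtype=bool)
    for r, w in enumerate(widths):
        start = (PLANTAR_SHAPE[1] - w) // 2
        if 9 <= r <= 17:            # arch relief on the medial side
            start = min(start + 1, PLANTAR_SHAPE[1] - w)
        mask[r, start : start + w] = True
    return mask


def _gauss2d(shape, r0, c0, sr, sc):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return np.exp(-(((r - r0) ** 2) / (2 * sr**2) + ((c - c0) ** 2) / (2 * sc**2)))


def _dorsal_pattern(cfg: SimConfig) -> np.ndarray:
    g = _gauss2d(DORSAL_SHAPE, 9.0, 4.5, 5.0, 3.0)
    return cfg.dorsal_baseline_mean * g / g.mean()


def _plantar_pattern(cfg: SimConfig, mask: np.ndarray) -> np.ndarray:
    # right-foot geometry: medial = low columns, lateral = high columns
    base = 12.0 * np.ones(PLANTAR_SHAPE)
    base += 58.0 * _gauss2d(PLANTAR_SHAPE, 4.0, 6.5, 2.5, 2.0)    # lateral heel
    base += 50.0 * _gauss2d(PLANTAR_SHAPE, 4.0, 3.0, 2.5, 2.0)    # medial heel
    base += 68.0 * _gauss2d(PLANTAR_SHAPE, 21.0, 4.0, 2.5, 3.0)   # metatarsals
    base += 28.0 * _gauss2d(PLANTAR_SHAPE, 28.0, 4.5, 1.8, 2.5)   # toes
    return np.where(mask, base, 0.0)


def simulate_static_trial(
    subject: int,
    condition: str,
    seed: int | None = None,
    sim_config: SimConfig | None = None,
    overlap: float | None = None,
    foot_side: str = "right",
) -> StaticTrial:
    """One in-lab boot try-on trial: averaged dorsal and plantar grids.

    ``condition`` is one of BOA_preferred, Buckle_preferred or
    BOA_at_buckle_overlap; the two BOA conditions share the BOA model label
    and differ in their shell-overlap reading.  Overlap is expressed in scale
    units relative to the cohort's typical Buckle setting (so it may be
    negative); pass ``overlap`` explicitly to override the drawn value.
    """
    if condition not in STATIC_CONDITIONS:
        raise ValueError(f"unknown static condition {condition!r}")
    cfg = sim_config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    eff = _subject_effects(cfg, subject)
    cond_idx = STATIC_CONDITIONS.index(condition)
    rng = _rng_for(cfg, 3, subject, cond_idx)

    if overlap is None:
        if condition == "Buckle_preferred":
            overlap = eff.overlap_buckle
        elif condition == "BOA_at_buckle_overlap":
            overlap = eff.overlap_buckle + rng.normal(0.0, 0.1)
        else:  # BOA_preferred: the wrap closure is run at lower shell overlap
            overlap = eff.overlap_buckle - 2.0 + rng.normal(0.0, 0.5)
    overlap = float(overlap)
    config = "Buckle" if condition == "Buckle_preferred" else "BOA"
    boa = config == "BOA"

    dorsal_clean = _dorsal_pattern(cfg) * (cfg.dorsal_config_multiplier if boa else 1.0)
    dorsal_clean = dorsal_clean + cfg.overlap_slope * overlap + eff.dorsal_intercept

    mask = plantar_active_mask()
    if foot_side == "left":
        mask = np.fliplr(mask)
    plantar_clean = _plantar_pattern(cfg, plantar_active_mask())
    if foot_side == "left":
        plantar_clean = np.fliplr(plantar_clean)
    probe = PressureGrid(
        np.maximum(plantar_clean, 0.0), plantar_sensel_area_cm2(),
        "plantar", foot_side, mask,
    )
    scheme = build_region_scheme(probe)
    multipliers = {}
    if boa:
        multipliers = {
            "lateral_heel": cfg.lateral_heel_config_multiplier,
            "medial_midfoot": cfg.midfoot_config_multiplier,
            "lateral_midfoot": cfg.midfoot_config_multiplier,
        }
        for region, mult in multipliers.items():
            plantar_clean = np.where(scheme.masks[region], plantar_clean * mult, plantar_clean)
    plantar_clean = np.where(
        mask, plantar_clean + cfg.overlap_slope * overlap + eff.plantar_intercept, 0.0
    )

    region_peaks = {
        name: float(plantar_clean[m].max()) if m.any() else 0.0
        for name, m in scheme.masks.items()
    }
    truth = StaticTruth(
        subject_id=f"S{subject:02d}",
        condition=condition,
        config=config,
        overlap=overlap,
        dorsal_mean=float(np.maximum(dorsal_clean, 0.0).mean()),
        region_peaks=region_peaks,
        multipliers=multipliers,
    )

    d_frames, p_frames = [], []
    for _ in range(cfg.n_static_frames):
        dv = np.maximum(dorsal_clean + rng.normal(0, cfg.dorsal_frame_noise_sd, DORSAL_SHAPE), 0)
        d_frames.append(PressureGrid(dv, dorsal_sensel_area_cm2(), "dorsal", foot_side))
        pv = plantar_clean + rng.normal(0, cfg.plantar_frame_noise_sd, PLANTAR_SHAPE)
        pv = np.where(mask, np.maximum(pv, 0.0), 0.0)
        p_frames.append(PressureGrid(pv, plantar_sensel_area_cm2(), "plantar", foot_side, mask))
    from .static_pressure import time_average_grid

    return StaticTrial(
        dorsal=time_average_grid(d_frames),
        plantar=time_average_grid(p_frames),
        dorsal_frames=d_frames,
        plantar_frames=p_frames,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# subjective scores


def simulate_subjective(
    subject: int,
    config: str,
    seed: int | None = None,
    sim_config: SimConfig | None = None,
    item_means: dict | None = None,
) -> dict[str, int]:
    """Questionnaire responses for the eight items, on the raw 0-10 scale.

    Draws are normal around the per-item, per-configuration study means with
    a shared subject intercept, then clipped to [0, 10] and rounded.  Pass
    ``item_means`` (item -> {config: (mean, sd)}) to override the defaults,
    e.g. to simulate a null configuration effect.
    """
    if config not in CONFIGS:
        raise ValueError(f"unknown config {config!r}")
    cfg = sim_config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    table = item_means or SUBJECTIVE_TABLE
    eff = _subject_effects(cfg, subject)
    rng = _rng_for(cfg, 4, subject, int(config == "BOA"))
    out = {}
    for item in SUBJECTIVE_ITEMS:
        mean, sd = table[item][config]
        subj_part = eff.subjective_intercept * sd * cfg.subjective_subject_sd_frac
        resid_sd = sd * np.sqrt(max(1.0 - cfg.subjective_subject_sd_frac**2, 0.05))
        draw = mean + subj_part + rng.normal(0.0, resid_sd)
        out[item] = int(np.clip(round(draw), 0, 10))
    return out


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(
    sim_config: SimConfig | None = None,
    out_dir=None,
    include_imu: bool = True,
    subject_overrides: dict | None = None,
) -> CohortBundle:
    """Full synthetic dataset: runs, static trials and questionnaires.

    ``subject_overrides`` maps a 0-based subject index to SimConfig field
    overrides (e.g. ``{21: {"turns_per_run": 2}}`` to build a subject whose
    trials contain too few turns).  With ``out_dir`` set the bundle is also
    written to disk in the documented layout together with ``truth.json``
    and a checksum manifest.
    """
    cfg = sim_config or SimConfig()
    overrides = subject_overrides or {}
    runs, statics, subj_rows = [], [], []
    subject_ids = [f"S{i:02d}" for i in range(cfg.n_subjects)]
    for i in range(cfg.n_subjects):
        sub_cfg = replace(cfg, **overrides[i]) if i in overrides else cfg
        for config in CONFIGS:
            for trial in range(1, cfg.runs_per_config + 1):
                runs.append(
                    simulate_run(i, config, trial, sim_config=sub_cfg,
                                 include_imu=include_imu)
                )
            scores = simulate_subjective(i, config, sim_config=cfg)
            subj_rows.append(
                {"subject_id": subject_ids[i], "config": config, **scores}
            )
    for i in range(min(cfg.n_static_subjects, cfg.n_subjects)):
        for condition in STATIC_CONDITIONS:
            statics.append(simulate_static_trial(i, condition, sim_config=cfg))
    bundle = CohortBundle(
        config=cfg,
        runs=runs,
        statics=statics,
        subjective=pd.DataFrame(subj_rows),
        subject_ids=subject_ids,
    )
    if out_dir is not None:
        _write_cohort(bundle, Path(out_dir))
    return bundle


def _truth_record(t: RunTruth) -> dict:
    d = {
        "subject_id": t.subject_id, "config": t.config, "trial_no": t.trial_no,
        "flat_times": t.flat_times.tolist(), "gyro_bias": t.gyro_bias,
        "turns": [asdict(x) for x in t.turns],
    }
    return d


def _write_cohort(bundle: CohortBundle, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    files = []

    def note(path: Path) -> None:
        files.append(path.relative_to(root).as_posix())

    for run in bundle.runs:
        d = root / "cohort" / run.subject_id / run.config / f"trial{run.trial_no}"
        d.mkdir(parents=True, exist_ok=True)
        run.imu_left.roll_rate.to_csv(d / "imu_left.csv")
        run.imu_right.roll_rate.to_csv(d / "imu_right.csv")
        run.force_left.to_csv(d / "force_left.csv")
        run.force_right.to_csv(d / "force_right.csv")
        for name in ("imu_left.csv", "imu_right.csv", "force_left.csv", "force_right.csv"):
            note(d / name)
    for st in bundle.statics:
        d = root / "static" / st.truth.subject_id / st.truth.condition
        d.mkdir(parents=True, exist_ok=True)
        st.dorsal.to_files(d / "dorsal.csv", d / "dorsal.json")
        st.plantar.to_files(d / "plantar.csv", d / "plantar.json")
        (d / "meta.json").write_text(
            json.dumps({"overlap": st.truth.overlap, "config": st.truth.config})
        )
        for name in ("dorsal.csv", "dorsal.json", "plantar.csv", "plantar.json", "meta.json"):
            note(d / name)
    bundle.subjective.to_csv(root / "subjective.csv", index=False)
    note(root / "subjective.csv")
    truth = {
        "runs": [_truth_record(r.truth) for r in bundle.runs],
        "statics": [asdict(s.truth) for s in bundle.statics],
    }
    (root / "truth.json").write_text(json.dumps(truth))
    note(root / "truth.json")
    manifest = {
        p: hashlib.sha256((root / p).read_bytes()).hexdigest() for p in sorted(files)
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
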