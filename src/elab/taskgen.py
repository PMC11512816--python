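"""Synthetic cohorts for the elevator approach-avoidance task.

The generator emulates the structure the downstream analyses assume: a
4-block x 24-trial schedule with two-thirds threat trials and a 50/50
predictable/unpredictable split per block, class-conditional diffusion-model
choices (a goal-directed class whose drift toward avoidance rises under
predictability, and a stimulus-response class with uniformly high drift),
50%-stochastic outcomes in the unpredictable condition, event-locked cardiac
deceleration whose depth depends on condition x threat x class, response-
locked EMG bursts whose amplitude rises with threat only in the
stimulus-response class, and per-dyad subjective evaluations favouring
avoidance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import DDMParams, simulate_ddm

__all__ = [
    "StudyConfig",
    "ParticipantProfile",
    "SignalTrace",
    "default_profile",
    "generate_cohort_profiles",
    "generate_trial_schedule",
    "simulate_choices",
    "synthesize_ecg",
    "synthesize_emg",
    "generate_subjective_values",
    "generate_cohort",
    "write_trials_csv",
    "write_signal",
    "N_DYADS",
]

#: Threat-dyad inventory mirroring the stimulus set after exclusions
#: (16 dyads per avatar sex).
N_DYADS = 32

# Avoidance-rate calibration targets per class and condition; the default
# drift-rates below are derived from these through the closed-form unbiased
# absorption probability P(avoid) = 1/(1+exp(-a*v)).
_AVOID_TARGETS = {
    ("GD", "predictable"): 0.575,
    ("GD", "unpredictable"): 0.515,
    ("SR", "predictable"): 0.739,
    ("SR", "unpredictable"): 0.724,
}
# Boundaries sized so the 1.5 s deadline is rarely exceeded (<2% late
# responses); the SR class is slightly more cautious than the GD class.
_CLASS_BOUNDARY = {"GD": 1.05, "SR": 1.16}
_CLASS_T0 = {"GD": 0.37, "SR": 0.30}


@dataclass(frozen=True)
class StudyConfig:
    """Task schedule and cohort-level settings (defaults are the task's)."""

    n_participants: int = 60
    class_mixing: float = 29 / 90  #: probability of the SR class
    n_blocks: int = 4
    trials_per_block: int = 24
    threat_fraction: float = 2 / 3
    response_deadline: float = 1.5  # s
    jitter_mean: float = 0.9  # s
    jitter_sd: float = 0.3  # s
    jitter_bounds: tuple[float, float] = (0.3, 1.5)  # truncation range, s
    unpredictable_threat_prob: float = 0.5
    trial_spacing: float = 16.0  #: onset-to-onset spacing, s (>= 14 for epochs)
    ecg_fs: int = 1000
    emg_fs: int = 2000
    line_noise_hz: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_mixing <= 1.0:
            raise ValueError("class_mixing must be a probability")
        n_threat = self.threat_fraction * self.trials_per_block
        if abs(n_threat - round(n_threat)) > 1e-9:
            raise ValueError(
                "threat_fraction * trials_per_block must be an integer "
                f"(got {n_threat})"
            )
        if round(n_threat) % 2 or (self.trials_per_block - round(n_threat)) % 2:
            raise ValueError("threat and neutral trial counts must split 50/50 by condition")
        if self.jitter_bounds[0] >= self.jitter_bounds[1]:
            raise ValueError("jitter truncation range is empty")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def _drift_for_target(p_avoid: float, a: float) -> float:
    return math.log(p_avoid / (1.0 - p_avoid)) / a


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent class plus all generator gains for one participant.

    ``decel_kernel_gain`` maps (condition, trial_type) to the fractional
    event-locked IBI lengthening (0.08 is roughly an 5 bpm deceleration at a
    70 bpm baseline); ``emg_burst_gain`` is the extra burst amplitude (in
    units of the noise-floor SD) on threat relative to neutral trials.
    """

    participant_id: str
    latent_class: str  # "GD" or "SR"
    ddm_params_by_condition: dict  # condition -> DDMParams
    hr_baseline: float = 70.0  # beats/min
    decel_kernel_gain: dict = field(default_factory=dict)
    emg_burst_gain: float = 0.0
    sv_mean_avoid: float = 65.231
    sv_mean_approach: float = 27.704
    sv_sd: float = 20.5

    def __post_init__(self) -> None:
        if self.latent_class not in ("GD", "SR"):
            raise ValueError(f"latent_class must be 'GD' or 'SR', got {self.latent_class!r}")
        for cond, p in self.ddm_params_by_condition.items():
            if p.a <= 0 or p.t0 < 0:
                raise ValueError(f"invalid DDM parameters for {cond}")
        vp = self.ddm_params_by_condition["predictable"].v
        vu = self.ddm_params_by_condition["unpredictable"].v
        if self.latent_class == "GD" and vp <= vu:
            raise ValueError("GD profiles must have v(predictable) > v(unpredictable)")


def default_profile(
    participant_id: str,
    latent_class: str,
    rng: np.random.Generator | None = None,
    individual_sd: float = 0.12,
) -> ParticipantProfile:
    """Class-typical profile with optional individual jitter on drift-rates.

    Drift-rates are calibrated so class-level avoidance rates land on the
    target cell means (GD ~ 0.575/0.515, SR ~ 0.739/0.724
    predictable/unpredictable).
    """
    rng = np.random.default_rng() if rng is None else rng
    a = _CLASS_BOUNDARY[latent_class]
    t0 = _CLASS_T0[latent_class]
    params = {}
    if latent_class == "SR":
        # equal drift across conditions (single draw), larger than GD overall
        v_common = _drift_for_target(
            (_AVOID_TARGETS[("SR", "predictable")] + _AVOID_TARGETS[("SR", "unpredictable")]) / 2,
            a,
        )
        dv = rng.normal(0.0, individual_sd)
        for cond in ("predictable", "unpredictable"):
            params[cond] = DDMParams(v=v_common + dv, a=a, t0=t0)
    else:
        dv = rng.normal(0.0, individual_sd)
        for cond in ("predictable", "unpredictable"):
            v = _drift_for_target(_AVOID_TARGETS[("GD", cond)], a) + dv
            params[cond] = DDMParams(v=v, a=a, t0=t0)
    if latent_class == "GD":
        decel = {
            ("predictable", "threat"): 0.14,
            ("unpredictable", "threat"): 0.06,
            ("predictable", "neutral"): 0.04,
            ("unpredictable", "neutral"): 0.04,
        }
        emg_gain = 0.0
    else:
        decel = {
            ("predictable", "threat"): 0.07,
            ("unpredictable", "threat"): 0.07,
            ("predictable", "neutral"): 0.04,
            ("unpredictable", "neutral"): 0.04,
        }
        emg_gain = 3.0
    return ParticipantProfile(
        participant_id=participant_id,
        latent_class=latent_class,
        ddm_params_by_condition=params,
        hr_baseline=float(rng.normal(70.0, 6.0)),
        decel_kernel_gain=decel,
        emg_burst_gain=emg_gain,
    )


def generate_cohort_profiles(cfg: StudyConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    profiles = []
    for i in range(cfg.n_participants):
        cls = "SR" if rng.uniform() < cfg.class_mixing else "GD"
        profiles.append(default_profile(f"p{i:03d}", cls, rng=rng))
    return profiles


# ---------------------------------------------------------------------------
# Trial schedule and choices
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=32)
def _jitter_scale(mean: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation scale whose truncated-normal SD equals ``sd``.

    The default bounds are symmetric about the mean, so the truncated mean
    stays at ``mean`` while truncation shrinks the SD; solving for the scale
    keeps the realized jitter moments at the configured values.
    """
    from scipy.optimize import brentq

    def realized_sd(s: float) -> float:
        return stats.truncnorm.std((lo - mean) / s, (hi - mean) / s, loc=mean, scale=s)

    if realized_sd(sd) >= sd - 1e-9:
        return sd
    return float(brentq(lambda s: realized_sd(s) - sd, sd, 5.0 * sd))


def _truncnorm_jitter(cfg: StudyConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.jitter_bounds
    scale = _jitter_scale(cfg.jitter_mean, cfg.jitter_sd, lo, hi)
    a = (lo - cfg.jitter_mean) / scale
    b = (hi - cfg.jitter_mean) / scale
    return stats.truncnorm.rvs(
        a, b, loc=cfg.jitter_mean, scale=scale, size=size, random_state=rng
    )


def generate_trial_schedule(
    profile: ParticipantProfile, cfg: StudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Deterministically balanced trial schedule (choices unset).

    Per block the condition split is exactly 50/50 and the threat fraction is
    exact within each condition; the angry avatar's side is counterbalanced
    within condition.  Threat dyads cycle through the 32-dyad inventory.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    n_threat_block = round(cfg.threat_fraction * cfg.trials_per_block)
    n_neutral_block = cfg.trials_per_block - n_threat_block
    rows = []
    dyad_cycle = rng.permutation(N_DYADS)
    dyad_pos = 0
    for block in range(1, cfg.n_blocks + 1):
        cells = []
        for cond in ("predictable", "unpredictable"):
            nt = n_threat_block // 2
            sides = ["left"] * (nt // 2) + ["right"] * (nt - nt // 2)
            for side in sides:
                cells.append((cond, "threat", side))
            for _ in range(n_neutral_block // 2):
                cells.append((cond, "neutral", "none"))
        order = rng.permutation(len(cells))
        jitters = _truncnorm_jitter(cfg, len(cells), rng)
        for k, idx in enumerate(order):
            cond, ttype, side = cells[idx]
            if ttype == "threat":
                dyad = int(dyad_cycle[dyad_pos % N_DYADS])
                dyad_pos += 1
            else:
                dyad = -1
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "block": block,
                    "trial": (block - 1) * cfg.trials_per_block + k + 1,
                    "condition": cond,
                    "trial_type": ttype,
                    "angry_side": side,
                    "jitter_s": float(jitters[k]),
                    "choice": "none",
                    "response": "none",
                    "rt_s": np.nan,
                    "outcome": "",
                    "dyad_id": dyad,
                    "latent_class": profile.latent_class,
                }
            )
    return pd.DataFrame(rows)


def simulate_choices(
    profile: ParticipantProfile,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    cfg: StudyConfig | None = None,
) -> pd.DataFrame:
    """Complete a schedule with diffusion-model choices, RTs and outcomes.

    Threat trials use the profile's condition-specific diffusion parameters
    (upper boundary = avoid).  Neutral trials have no approach/avoid
    semantics: the side is an unbiased zero-drift diffusion choice with the
    profile's average boundary and non-decision time.  RTs beyond the
    deadline are recorded as non-responses.  Predictable outcomes follow the
    choice deterministically; unpredictable outcomes are redrawn threat with
    the configured probability.
    """
    cfg = StudyConfig() if cfg is None else cfg
    trials = schedule.copy().reset_index(drop=True)
    p_avg = profile.ddm_params_by_condition["predictable"]
    u_avg = profile.ddm_params_by_condition["unpredictable"]
    neutral_params = DDMParams(v=0.0, a=(p_avg.a + u_avg.a) / 2, t0=(p_avg.t0 + u_avg.t0) / 2)

    for cond in ("predictable", "unpredictable"):
        for ttype, params in (
            ("threat", profile.ddm_params_by_condition[cond]),
            ("neutral", neutral_params),
        ):
            mask = (trials["condition"] == cond) & (trials["trial_type"] == ttype)
            n = int(mask.sum())
            if n == 0:
                continue
            responses, rts = simulate_ddm(params, n, rng=rng)
            idx = trials.index[mask]
            trials.loc[idx, "rt_s"] = rts
            if ttype == "threat":
                angry = trials.loc[idx, "angry_side"].to_numpy()
                resp = responses.copy()
                choice = np.where(
                    resp == "avoid",
                    np.where(angry == "left", "right", "left"),
                    angry,
                )
                trials.loc[idx, "response"] = resp
                trials.loc[idx, "choice"] = choice
                if cond == "predictable":
                    outcome = np.where(resp == "avoid", "safe", "threat")
                else:
                    outcome = np.where(
                        rng.uniform(size=n) < cfg.unpredictable_threat_prob, "threat", "safe"
                    )
                trials.loc[idx, "outcome"] = outcome
            else:
                side = np.where(responses == "avoid", "left", "right")
                trials.loc[idx, "choice"] = side
                trials.loc[idx, "response"] = "none"
                trials.loc[idx, "outcome"] = "safe"

    # deadline: late responses become non-responses with missing rt
    late = trials["rt_s"] > cfg.response_deadline
    trials.loc[late, ["choice", "response"]] = "none"
    trials.loc[late, "rt_s"] = np.nan
    trials.loc[late, "outcome"] = ""
    return trials


# ---------------------------------------------------------------------------
# Physiological signal synthesis
# ---------------------------------------------------------------------------


@dataclass
class SignalTrace:
    """A continuous recording with its event-marker stream."""

    samples: np.ndarray
    fs: int
    event_markers: list  # (trial_index, onset_time_s, rt_s or nan)
    channel: str

    def __post_init__(self) -> None:
        onsets = [m[1] for m in self.event_markers]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")


def _trial_onsets(n_trials: int, cfg: StudyConfig, lead_in: float = 20.0) -> np.ndarray:
    return lead_in + cfg.trial_spacing * np.arange(n_trials)


def _decel_kernel(t: np.ndarray) -> np.ndarray:
    """Smooth deceleration bump active from ~1 s pre-onset to ~4 s post."""
    span = (t > -1.0) & (t < 4.0)
    out = np.zeros_like(t)
    out[span] = np.sin(np.pi * (t[span] + 1.0) / 5.0) ** 2
    return out


def synthesize_ecg(
    profile: ParticipantProfile,
    trials: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
    ibi_noise_sd: float = 0.02,
    r_wave_width: float = 0.012,
    noise_sd: float = 0.03,
) -> SignalTrace:
    """Continuous ECG trace with event-locked inter-beat-interval lengthening.

    Beat times follow a baseline IBI (60000/hr_baseline ms) with
    multiplicative log-normal noise, stretched around each trial onset by the
    deceleration kernel scaled with the profile's (condition, trial_type)
    gain.  The trace is a train of Gaussian R-wave templates plus white
    noise; markers align to trial onsets.
    """
    if cfg.trial_spacing < 14.0:
        raise ValueError(
            "trial_spacing must be >= 14 s so -4..10 s epochs do not overlap"
        )
    trials = trials.sort_values("trial").reset_index(drop=True)
    onsets = _trial_onsets(len(trials), cfg)
    gains = np.array(
        [
            profile.decel_kernel_gain.get((c, t), 0.0)
            for c, t in zip(trials["condition"], trials["trial_type"])
        ]
    )
    duration = onsets[-1] + cfg.trial_spacing
    base_ibi = 60.0 / profile.hr_baseline  # s

    beat_times = [0.5]
    while beat_times[-1] < duration:
        t = beat_times[-1]
        ibi = base_ibi * math.exp(rng.normal(0.0, ibi_noise_sd))
        # nearest trial determines the kernel value at this beat
        k = int(np.clip(round((t - onsets[0]) / cfg.trial_spacing), 0, len(onsets) - 1))
        rel = t - onsets[k]
        ibi *= 1.0 + gains[k] * _decel_kernel(np.array([rel]))[0]
        beat_times.append(t + ibi)
    beats = np.asarray(beat_times)

    n_samples = int(duration * cfg.ecg_fs)
    samples = noise_sd * rng.standard_normal(n_samples)
    tgrid = np.arange(n_samples) / cfg.ecg_fs
    half = int(4 * r_wave_width * cfg.ecg_fs)
    template_t = np.arange(-half, half + 1) / cfg.ecg_fs
    template = np.exp(-0.5 * (template_t / r_wave_width) ** 2)
    for b in beats:
        c = int(round(b * cfg.ecg_fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n_samples:
            continue
        samples[lo:hi] += template

    markers = [
        (int(row.trial), float(onsets[i]), float(row.rt_s) if np.isfinite(row.rt_s) else float("nan"))
        for i, row in enumerate(trials.itertuples())
    ]
    return SignalTrace(samples=samples, fs=cfg.ecg_fs, event_markers=markers, channel="ecg")


def synthesize_emg(
    profile: ParticipantProfile,
    trials: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    burst_base_amp: float = 8.0,
    burst_halfwidth: float = 0.075,
    add_line_noise: bool = True,
) -> dict[str, SignalTrace]:
    """EMG traces for both hands: band-limited noise floor plus one burst per
    responded trial, centered at onset + rt on the responding hand.

    Burst amplitude (in noise-SD units) = ``burst_base_amp`` plus the
    profile's ``emg_burst_gain`` on threat trials (nonzero only for SR
    profiles by default).  A 50 Hz line component can be mixed in to
    exercise spectral interpolation downstream.
    """
    from scipy.signal import butter, sosfiltfilt

    trials = trials.sort_values("trial").reset_index(drop=True)
    onsets = _trial_onsets(len(trials), cfg)
    duration = onsets[-1] + cfg.trial_spacing
    n_samples = int(duration * cfg.emg_fs)
    sos = butter(4, [20.0, 480.0], btype="bandpass", fs=cfg.emg_fs, output="sos")

    traces = {}
    markers = [
        (int(row.trial), float(onsets[i]), float(row.rt_s) if np.isfinite(row.rt_s) else float("nan"))
        for i, row in enumerate(trials.itertuples())
    ]
    tline = np.arange(n_samples) / cfg.emg_fs
    line = 0.8 * noise_sd * np.sin(2 * np.pi * cfg.line_noise_hz * tline) if add_line_noise else 0.0

    for hand in ("left", "right"):
        carrier = sosfiltfilt(sos, rng.standard_normal(n_samples))
        carrier /= carrier.std()
        gain = np.full(n_samples, noise_sd)
        for i, row in enumerate(trials.itertuples()):
            if row.choice != hand or not np.isfinite(row.rt_s):
                continue
            amp = burst_base_amp + (profile.emg_burst_gain if row.trial_type == "threat" else 0.0)
            center = onsets[i] + row.rt_s
            c = int(round(center * cfg.emg_fs))
            halfw = int(burst_halfwidth * cfg.emg_fs)
            lo, hi = max(c - halfw, 0), min(c + halfw + 1, n_samples)
            bump = np.hanning(2 * halfw + 1)[lo - (c - halfw) : hi - (c - halfw)]
            gain[lo:hi] += amp * noise_sd * bump
        samples = carrier * gain + line
        traces[hand] = SignalTrace(
            samples=samples, fs=cfg.emg_fs, event_markers=markers, channel=f"emg_{hand}"
        )
    return traces


# ---------------------------------------------------------------------------
# Subjective evaluations
# ---------------------------------------------------------------------------


def generate_subjective_values(
    profile: ParticipantProfile,
    dyads: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-dyad 0-100 evaluations of avoid/approach scenes and their SV score.

    ``sv = (value_avoid - value_approach) / 100`` lies in [-1, 1]; positive
    values mean the participant prefers avoiding the angry avatar of the dyad.
    """
    rng = np.random.default_rng() if rng is None else rng
    dyads = list(range(N_DYADS)) if dyads is None else list(dyads)
    if not dyads:
        raise ValueError("dyad list is empty")
    v_avoid = np.clip(rng.normal(profile.sv_mean_avoid, profile.sv_sd, len(dyads)), 0, 100)
    v_appr = np.clip(rng.normal(profile.sv_mean_approach, profile.sv_sd, len(dyads)), 0, 100)
    return pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "dyad_id": dyads,
            "value_avoid": v_avoid,
            "value_approach": v_appr,
            "sv": (v_avoid - v_appr) / 100.0,
        }
    )


# ---------------------------------------------------------------------------
# Cohort-level convenience and file interfaces
# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: StudyConfig,
    rng: np.random.Generator | None = None,
    with_signals: bool = False,
) -> dict:
    """Generate a full cohort: profiles, completed trials, SVs, signals.

    Returns a dict with keys ``profiles``, ``trials`` (one concatenated
    DataFrame), ``sv`` and, when ``with_signals``, per-participant ``ecg``
    and ``emg`` traces.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    profiles = generate_cohort_profiles(cfg, rng)
    all_trials, all_sv = [], []
    signals: dict[str, dict] = {}
    for prof in profiles:
        sched = generate_trial_schedule(prof, cfg, rng)
        trials = simulate_choices(prof, sched, rng, cfg)
        all_trials.append(trials)
        all_sv.append(generate_subjective_values(prof, rng=rng))
        if with_signals:
            signals[prof.participant_id] = {
                "ecg": synthesize_ecg(prof, trials, cfg, rng),
                "emg": synthesize_emg(prof, trials, cfg, rng),
            }
    out = {
        "profiles": profiles,
        "trials": pd.concat(all_trials, ignore_index=True),
        "sv": pd.concat(all_sv, ignore_index=True),
    }
    if with_signals:
        out["signals"] = signals
    return out


_CSV_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "condition",
    "trial_type",
    "angry_side",
    "jitter_s",
    "choice",
    "response",
    "rt_s",
    "outcome",
    "dyad_id",
    "latent_class",
]


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials[_CSV_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)


def write_signal(trace: SignalTrace, path_prefix: str | Path) -> None:
    """Write a trace as CSV samples plus a JSON sidecar with fs and markers."""
    prefix = Path(path_prefix)
    np.savetxt(prefix.with_suffix(".csv"), trace.samples, fmt="%.6g")
    sidecar = {
        "fs": trace.fs,
        "channel": trace.channel,
        "event_markers": [
            {"trial_index": t, "onset_s": o, "rt_s": None if math.isnan(r) else r}
            for t, o, r in trace.event_markers
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
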