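"""Synthetic multimodal recordings with the statistical structure the analysis assumes.

The generator emulates a cue-reactivity session: 36 alternating 25-s trials
(wash-off baseline clips vs. game stimulation clips) with six channels sampled
at a common raw rate — a fingertip photoplethysmogram (PPG), a skin-conductance
channel (GSR) and four periocular EOG electrodes — repeated over three days per
subject.

State effects are injected with the directions reported for game-craving
stimulation: reduced within-trial heart-rate variability, fewer eye blinks and
an elevated respiratory rate during stimulation trials.  Between-day
variability ("drift") and between-subject trait variability are controllable,
which makes test-retest reliability and cross-day classifier transfer tunable
quantities rather than accidents of the noise.

Signal models (deliberately simple; the feature extractors only rely on peak
times, slow modulations and event morphology):

* PPG — one Gaussian-shaped pulse per beat; instantaneous beat rate is an
  AR(1) perturbation around the subject's mean HR; pulse amplitude is
  modulated at the respiratory frequency (~10 % depth), which is how the
  respiratory rate is later recovered from the PPG.
* GSR — tonic level with slow drift plus Poisson skin-conductance responses
  (fast rise, exponential decay) and noise.
* EOG — vertical/horizontal gaze components carrying step-like saccades
  (Poisson arrivals, gaze jumps between positions drawn around straight-ahead)
  and large raised-cosine blink pulses on the vertical component; the two
  components are projected with gains +1/2 and -1/2 onto the electrode pairs
  so that the later difference-derivation reconstructs them at unit gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .core import (
    STIMULATION,
    WASH_OFF,
    SESSION_IDS,
    SessionDataset,
    SubjectStudy,
    Trial,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "StateEffects",
    "TrialTruth",
    "simulate_trial",
    "simulate_trial_with_truth",
    "simulate_study",
    "simulate_cohort",
]


@dataclass(frozen=True)
class StateEffects:
    """Additive parameter shifts applied during stimulation trials.

    Signs follow the reported physiology of craving stimulation: HR
    variability down, blink count down, respiratory rate up.
    """

    delta_stdHR: float = -1.5    # bpm, added to within-trial HR sd
    delta_NE_rate: float = -6.0  # blinks/min
    delta_mRR: float = 3.0       # breaths/min


@dataclass(frozen=True)
class SimulationConfig:
    """Process parameters of the synthetic recording.

    Rates are per minute; the state deltas of :class:`StateEffects` are added
    for stimulation trials.  ``session_drift_sd`` is the fractional sd of a
    once-per-session multiplicative perturbation of every process parameter
    (0 = exchangeable sessions); ``subject_sd`` is the analogous
    once-per-subject trait perturbation that gives features a stable
    between-subject ordering (the substrate of test-retest reliability).
    """

    hr_mean: float = 70.0          # bpm
    hr_sd: float = 3.0             # bpm, within-trial instantaneous HR sd
    rr_mean: float = 15.0          # breaths/min
    resp_mod_depth: float = 0.10   # fractional PPG amplitude modulation
    blink_rate: float = 15.0       # blinks/min
    saccade_rate: float = 40.0     # saccades/min
    scr_rate: float = 4.0          # skin-conductance responses/min
    noise_sd: float = 2.0          # a.u., EOG electrode noise at the raw rate
    blink_amplitude: float = 200.0  # a.u., vertical EOG blink pulse height
    gaze_sd_h: float = 10.0        # a.u., horizontal gaze-position spread
    gaze_sd_v: float = 5.0         # a.u., vertical gaze-position spread
    blink_fwhm: tuple[float, float] = (0.2, 0.4)  # s, half-amplitude duration range
    state_effects: StateEffects = field(default_factory=StateEffects)
    session_drift_sd: float = 0.0
    subject_sd: float = 0.10
    fs_raw: float = 2048.0         # Hz
    duration: float = 25.0         # s
    seed: int = 0

    # per-channel noise scales relative to noise_sd (EOG reference = 1)
    _PPG_NOISE = 0.025
    _GSR_NOISE = 0.01

    def validate(self) -> None:
        for name in ("blink_rate", "saccade_rate", "scr_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"SimulationConfig.{name} must be >= 0")
        if self.hr_mean <= 0 or self.rr_mean <= 0:
            raise ValidationError("SimulationConfig: hr_mean and rr_mean must be > 0")
        if self.blink_rate + self.state_effects.delta_NE_rate < 0:
            raise ValidationError(
                "SimulationConfig: blink_rate + delta_NE_rate must be >= 0"
            )
        if self.noise_sd < 0 or self.hr_sd < 0:
            raise ValidationError("SimulationConfig: noise_sd and hr_sd must be >= 0")


@dataclass
class TrialTruth:
    """Ground-truth events behind one simulated trial (for oracle tests)."""

    beat_times: np.ndarray          # s, pulse-peak times
    beat_hr: np.ndarray             # bpm, instantaneous HR per beat interval
    rr_true: float                  # breaths/min actually synthesised
    blink_intervals: list[tuple[float, float]]
    saccades: list[tuple[float, float, float]]  # (time, h_amp, v_amp)
    scr_times: np.ndarray
    params: dict


# ---------------------------------------------------------------------------
# effective per-trial parameters = config x subject factor x session factor
# ---------------------------------------------------------------------------

_FACTOR_FIELDS = ("hr_mean", "hr_sd", "rr_mean", "blink_rate", "saccade_rate",
                  "scr_rate")


def _draw_factors(rng: np.random.Generator, scale: float) -> dict[str, float]:
    # one multiplicative factor per process parameter, clipped away from zero
    return {name: max(0.05, 1.0 + scale * rng.standard_normal())
            for name in _FACTOR_FIELDS}


def _unit_factors() -> dict[str, float]:
    return {name: 1.0 for name in _FACTOR_FIELDS}


def _effective_params(config: SimulationConfig, kind: str,
                      factors: dict[str, float]) -> dict[str, float]:
    eff = {name: getattr(config, name) * factors[name] for name in _FACTOR_FIELDS}
    if kind == STIMULATION:
        se = config.state_effects
        eff["hr_sd"] = max(0.0, eff["hr_sd"] + se.delta_stdHR)
        eff["rr_mean"] = eff["rr_mean"] + se.delta_mRR
        eff["blink_rate"] = eff["blink_rate"] + se.delta_NE_rate
    for name in ("blink_rate", "saccade_rate", "scr_rate"):
        if eff[name] < 0:
            raise ValidationError(
                f"effective {name} is negative after state adjustment: {eff[name]:.3f}"
            )
    if eff["hr_mean"] <= 0 or eff["rr_mean"] <= 0:
        raise ValidationError("effective hr_mean/rr_mean must stay positive")
    return eff


# ---------------------------------------------------------------------------
# channel synthesis
# ---------------------------------------------------------------------------

def _poisson_times(rng: np.random.Generator, rate_per_min: float, duration: float,
                   *, margin: float = 0.0, min_gap: float = 0.0,
                   max_tries: int = 50) -> np.ndarray:
    """Poisson event times in [margin, duration-margin] with a minimum gap."""
    lam = rate_per_min * duration / 60.0
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0)
    lo, hi = margin, duration - margin
    for _ in range(max_tries):
        t = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(t)) >= min_gap:
            return t
    # fall back: thin events violating the gap rather than loop forever
    keep = [t[0]]
    for ti in t[1:]:
        if ti - keep[-1] >= min_gap:
            keep.append(ti)
    return np.asarray(keep)


def _synth_ppg(rng, n, fs, duration, hr_mean, hr_sd, rr_mean, mod_depth,
               noise_sd):
    """Gaussian pulse train with AR(1) beat-rate jitter and respiratory AM."""
    phi = 0.7  # AR(1) pole of instantaneous HR; gives smooth HR wander
    t_axis = np.arange(n) / fs
    beat_times, beat_hr = [], []
    x = hr_sd * rng.standard_normal() if hr_sd > 0 else 0.0
    t = rng.uniform(0.0, 60.0 / hr_mean)
    while t < duration + 1.0:
        hr = max(30.0, hr_mean + x)
        beat_times.append(t)
        beat_hr.append(hr)
        t += 60.0 / hr
        if hr_sd > 0:
            x = phi * x + np.sqrt(1.0 - phi ** 2) * hr_sd * rng.standard_normal()
    beat_times = np.asarray(beat_times)
    beat_hr = np.asarray(beat_hr)

    f_resp = rr_mean / 60.0
    resp_phase = rng.uniform(0, 2 * np.pi)
    sigma = 0.06  # s, pulse width; unambiguous peaks for HR up to ~150 bpm
    ppg = np.zeros(n)
    half = int(round(4 * sigma * fs))
    for tb in beat_times:
        amp = 1.0 + mod_depth * np.sin(2 * np.pi * f_resp * tb + resp_phase)
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        ppg[lo:hi] += amp * np.exp(-0.5 * ((t_axis[lo:hi] - tb) / sigma) ** 2)
    if noise_sd > 0:
        ppg += noise_sd * rng.standard_normal(n)
    in_trial = beat_times < duration
    return ppg, beat_times[in_trial], beat_hr[in_trial]


def _synth_gsr(rng, n, fs, duration, scr_rate, noise_sd):
    """Tonic level + slow drift + Poisson SCRs (fast rise, exponential decay)."""
    t_axis = np.arange(n) / fs
    tonic = rng.uniform(2.0, 10.0)
    slope = rng.normal(0.0, 0.02)            # µS-like units per second
    wander = 0.1 * np.sin(2 * np.pi * t_axis / 60.0 + rng.uniform(0, 2 * np.pi))
    gsr = tonic + slope * t_axis + wander
    scr_times = _poisson_times(rng, scr_rate, duration, margin=0.5, min_gap=1.0)
    tau_rise, tau_decay = 0.7, 3.0
    for ts in scr_times:
        amp = rng.lognormal(mean=np.log(0.3), sigma=0.4)
        idx0 = int(round(ts * fs))
        tail = t_axis[idx0:min(n, idx0 + int(12 * fs))] - ts
        shape = (1.0 - np.exp(-tail / tau_rise)) * np.exp(-tail / tau_decay)
        peak = shape.max() if shape.size else 1.0
        gsr[idx0:idx0 + tail.size] += amp * shape / max(peak, 1e-12)
    if noise_sd > 0:
        gsr += noise_sd * rng.standard_normal(n)
    return gsr, scr_times


def _raised_cosine(tail_t, width):
    """Blink pulse shape on [0, width]; zero outside."""
    y = 0.5 * (1.0 - np.cos(2 * np.pi * np.clip(tail_t, 0, width) / width))
    y[(tail_t < 0) | (tail_t > width)] = 0.0
    return y


def _synth_eog(rng, n, fs, duration, blink_rate, saccade_rate, blink_amplitude,
               gaze_sd_h, gaze_sd_v, blink_fwhm, noise_sd):
    """Gaze components: saccadic position steps + blink pulses (vertical only)."""
    t_axis = np.arange(n) / fs
    sacc_times = _poisson_times(rng, saccade_rate, duration, margin=0.3,
                                min_gap=0.35)
    h = np.zeros(n)
    v = np.zeros(n)
    pos_h, pos_v = 0.0, 0.0
    saccades = []
    for ts in sacc_times:
        target_h = rng.normal(0.0, gaze_sd_h)
        target_v = rng.normal(0.0, gaze_sd_v)
        idx = int(round(ts * fs))
        h[idx:] += target_h - pos_h
        v[idx:] += target_v - pos_v
        saccades.append((float(ts), float(target_h - pos_h), float(target_v - pos_v)))
        pos_h, pos_v = target_h, target_v

    blink_times = _poisson_times(rng, blink_rate, duration, margin=0.6,
                                 min_gap=1.2)
    blink_intervals = []
    for tb in blink_times:
        # raised-cosine pulse whose half-amplitude duration is blink_fwhm;
        # the full base width is twice that
        width = 2.0 * rng.uniform(*blink_fwhm)
        amp = blink_amplitude * rng.uniform(0.75, 1.25)
        idx0 = int(round(tb * fs))
        idx1 = min(n, idx0 + int(round(width * fs)))
        v[idx0:idx1] += amp * _raised_cosine(t_axis[idx0:idx1] - tb, width)
        blink_intervals.append((float(tb), float(tb + width)))

    # project components onto the electrode pairs at gains +-1/2, so that
    # (above - below) and (right - left) reconstruct v and h at unit gain
    def noisy(x):
        return x + noise_sd * rng.standard_normal(n) if noise_sd > 0 else x.copy()

    eog_above = noisy(0.5 * v)
    eog_below = noisy(-0.5 * v)
    eog_right = noisy(0.5 * h)
    eog_left = noisy(-0.5 * h)
    return (eog_above, eog_below, eog_right, eog_left), blink_intervals, saccades


def _craving_score(rng, kind: str) -> int:
    # deterministic mapping with small noise, clipped into disjoint bands so
    # the self-report manipulation check passes by construction
    if kind == STIMULATION:
        return int(np.clip(round(4.3 + rng.normal(0, 0.6)), 3, 5))
    return int(np.clip(round(1.5 + rng.normal(0, 0.6)), 1, 2))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_trial_with_truth(config: SimulationConfig, kind: str,
                              rng: np.random.Generator | int | None = None,
                              *, trial_index: int = 0, session_id: str = "day1",
                              subject_id: str = "S1",
                              factors: dict[str, float] | None = None,
                              ) -> tuple[Trial, TrialTruth]:
    """Simulate one trial and return it together with its ground truth."""
    config.validate()
    if kind not in (WASH_OFF, STIMULATION):
        raise ValidationError(f"unknown trial kind {kind!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    factors = factors if factors is not None else _unit_factors()
    eff = _effective_params(config, kind, factors)

    fs, duration = config.fs_raw, config.duration
    n = int(round(fs * duration))
    ppg, beat_times, beat_hr = _synth_ppg(
        rng, n, fs, duration, eff["hr_mean"], eff["hr_sd"], eff["rr_mean"],
        config.resp_mod_depth, config.noise_sd * config._PPG_NOISE)
    gsr, scr_times = _synth_gsr(rng, n, fs, duration, eff["scr_rate"],
                                config.noise_sd * config._GSR_NOISE)
    eog, blink_intervals, saccades = _synth_eog(
        rng, n, fs, duration, eff["blink_rate"], eff["saccade_rate"],
        config.blink_amplitude, config.gaze_sd_h, config.gaze_sd_v,
        config.blink_fwhm, config.noise_sd)
    score = _craving_score(rng, kind)

    trial = Trial(ppg=ppg, gsr=gsr, eog_above=eog[0], eog_below=eog[1],
                  eog_right=eog[2], eog_left=eog[3], kind=kind,
                  craving_score=score, trial_index=trial_index,
                  session_id=session_id, subject_id=subject_id,
                  fs_raw=fs, duration=duration)
    truth = TrialTruth(beat_times=beat_times, beat_hr=beat_hr,
                       rr_true=eff["rr_mean"], blink_intervals=blink_intervals,
                       saccades=saccades, scr_times=scr_times, params=eff)
    return trial, truth


def simulate_trial(config: SimulationConfig, kind: str,
                   rng: np.random.Generator | int | None = None,
                   **kwargs) -> Trial:
    """Simulate one trial (see :func:`simulate_trial_with_truth`)."""
    return simulate_trial_with_truth(config, kind, rng, **kwargs)[0]


def _session_kinds(n_trials: int = 36) -> list[str]:
    return [WASH_OFF if i % 2 == 0 else STIMULATION for i in range(n_trials)]


def simulate_study(config: SimulationConfig, subject_id: str = "S1",
                   seed: int | np.random.SeedSequence | None = None,
                   *, return_truth: bool = False):
    """Simulate three 36-trial sessions for one subject.

    Subject trait factors are drawn once (scale ``subject_sd``); session
    factors once per session (scale ``session_drift_sd``) and multiply the
    trait factors, so ``session_drift_sd = 0`` makes the three sessions
    exchangeable.  ``(config, seed)`` fully determines every sample.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(ss)
    subject_factors = (_draw_factors(subj_rng, config.subject_sd)
                       if config.subject_sd > 0 else _unit_factors())

    sessions: dict[str, SessionDataset] = {}
    truths: dict[str, list[TrialTruth]] = {}
    for session_id in SESSION_IDS:
        session_factors = (_draw_factors(subj_rng, config.session_drift_sd)
                           if config.session_drift_sd > 0 else _unit_factors())
        factors = {k: subject_factors[k] * session_factors[k]
                   for k in subject_factors}
        trials, session_truths = [], []
        for i, kind in enumerate(_session_kinds()):
            trial, truth = simulate_trial_with_truth(
                config, kind, subj_rng, trial_index=i, session_id=session_id,
                subject_id=subject_id, factors=factors)
            trials.append(trial)
            session_truths.append(truth)
        sessions[session_id] = SessionDataset(subject_id=subject_id,
                                              session_id=session_id,
                                              trials=trials)
        truths[session_id] = session_truths
    study = SubjectStudy(subject_id=subject_id, sessions=sessions)
    return (study, truths) if return_truth else study


def simulate_cohort(config: SimulationConfig, n_subjects: int = 9,
                    seed: int | None = None) -> list[SubjectStudy]:
    """Simulate a cohort; each subject gets an independent child seed."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_subjects)
    return [simulate_study(config, subject_id=f"S{i + 1}", seed=children[i])
            for i in range(n_subjects)]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (JSON/YAML block)."""
    d = dict(d)
    se = d.pop("state_effects", None)
    cfg = SimulationConfig(**d)
    if se is not None:
        cfg = replace(cfg, state_effects=StateEffects(**se))
    cfg.validate()
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
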