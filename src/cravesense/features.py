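"""Extraction of the 14 feature candidates from a preprocessed trial.

Per trial the features are (canonical numbering in parentheses):

* PPG cardiac/respiratory, computed on the 10–25 s window so filter start-up
  transients cannot leak in: stdHR (1), mHR (2), stdRR (3), mRR (4).
* GSR: mean normalized-skin-conductance peak amplitude mNSC (5) and trace
  minimum minNSC (6), both on the z-scored 16 Hz trace.
* EOG: blink count NE (7); saccadic-movement degrees DHSM (8), DVSM (9),
  their mean mDHV (10) and the Euclidean combination DSM (11).
* Cross-channel sample covariances on a common 16 Hz timeline: CHV (12),
  CHP (13), CVP (14).

The respiratory-rate estimator recovers the respiratory amplitude modulation
of the PPG pulse train (beat-amplitude envelope -> dominant-frequency
tracking); it is pluggable, so another RR-from-PPG algorithm with the same
contract can be substituted.  Blink detection is threshold-based on the
vertical component; saccade detection uses a Haar-family continuous wavelet
transform (a step detector) on each component.  Features that cannot be
computed for a degenerate trial are returned as NaN and treated as missing
downstream — the pipeline never aborts on a flat channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import FEATURE_NAMES, FeatureVector, ProcessedTrial, SubjectStudy
from .preprocess import PreprocessConfig, decimate_to, preprocess_trial

__all__ = [
    "FeatureConfig",
    "EventSeries",
    "estimate_hr_series",
    "estimate_rr_series",
    "hr_rr_features",
    "gsr_features",
    "detect_blinks",
    "detect_saccades",
    "covariance_features",
    "extract_features",
    "features_table",
]


@dataclass(frozen=True)
class FeatureConfig:
    hr_window: tuple[float, float] = (10.0, 25.0)  # s, HR/RR analysis window
    hr_max_bpm: float = 180.0       # bounds the minimum peak distance
    min_beats: int = 5              # fewer detected beats -> invalid HR
    rr_band: tuple[float, float] = (0.1, 0.7)  # Hz, plausible respiration
    rr_subwindow: float = 10.0      # s, sliding spectral window
    rr_step: float = 1.0            # s
    mnsc_mode: str = "peaks"        # "peaks" | "trace"
    blink_k: float = 3.0            # threshold in robust SDs of veog
    blink_min_height: float = 25.0  # a.u.; floor on the interval's peak, an
    # order of magnitude below genuine blink deflections but above saccadic
    # crosstalk on the vertical component
    blink_min_samples: int = 2      # minimum blink duration at 16 Hz
    blink_merge_gap: int = 2        # samples; shorter gaps merge intervals
    blink_pad: int = 3              # samples added per side before interpolation,
    # swallowing the sub-threshold blink flanks so no step residue remains
    saccade_scales: tuple[int, ...] = (3, 4, 6, 8)  # samples at 16 Hz
    saccade_gap: int = 3            # samples skipped around the step edge
    saccade_k: float = 5.0          # threshold in robust noise SDs
    saccade_pair_tol: int = 2       # samples; H/V events closer pair up


@dataclass
class EventSeries:
    """Detected events of one kind within a trial."""

    event_times: np.ndarray       # s, strictly increasing
    event_amplitudes: np.ndarray  # a.u.
    event_kind: str               # beat | scr_peak | blink | saccade_h | saccade_v

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("EventSeries times must be strictly increasing")

    def __len__(self) -> int:
        return self.event_times.size


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# cardiac / respiratory
# ---------------------------------------------------------------------------

def detect_ppg_peaks(ppg_f: np.ndarray, fs: float,
                     config: FeatureConfig = FeatureConfig()) -> EventSeries:
    """Pulse-peak times/amplitudes from the band-passed PPG."""
    x = np.asarray(ppg_f, dtype=float)
    min_dist = max(1, int(round(fs * 60.0 / config.hr_max_bpm)))
    prom = 0.3 * float(np.percentile(np.abs(x), 95))
    idx, _ = signal.find_peaks(x, distance=min_dist, prominence=max(prom, 1e-12))
    return EventSeries(event_times=idx / fs, event_amplitudes=x[idx],
                       event_kind="beat")


def estimate_hr_series(ppg_f: np.ndarray, fs: float,
                       config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Instantaneous heart rate (bpm) per beat inside the analysis window.

    Returns an empty array if fewer than ``min_beats`` beats are detected
    (the trial's HR features then come out NaN).
    """
    beats = detect_ppg_peaks(ppg_f, fs, config)
    t0, t1 = config.hr_window
    t = beats.event_times[(beats.event_times >= t0) & (beats.event_times <= t1)]
    if t.size < config.min_beats:
        return np.empty(0)
    return 60.0 / np.diff(t)


def estimate_rr_series(ppg_f: np.ndarray, fs: float,
                       config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Respiratory rate (breaths/min) tracked over the analysis window.

    The beat-amplitude envelope is interpolated onto a uniform 4 Hz grid and
    the dominant frequency inside ``rr_band`` is measured on sliding
    ``rr_subwindow``-second windows (Hann taper, zero-padded FFT, parabolic
    peak refinement).  Undetectable modulation yields an empty series.
    """
    x = np.asarray(ppg_f, dtype=float)
    beats = detect_ppg_peaks(x, fs, config)
    idx_all = np.round(beats.event_times * fs).astype(int)
    # baseline-corrected beat amplitude: peak height above the mean of the
    # adjacent inter-beat troughs, so slow baseline shifts (e.g. heart-rate
    # wander interacting with the high-pass) do not leak into the envelope
    amps_all = np.empty(idx_all.size)
    if idx_all.size >= 2:
        troughs = np.array([np.min(x[idx_all[i]:idx_all[i + 1] + 1])
                            for i in range(idx_all.size - 1)])
        for i, p in enumerate(idx_all):
            left = troughs[i - 1] if i > 0 else troughs[0]
            right = troughs[i] if i < troughs.size else troughs[-1]
            amps_all[i] = x[p] - 0.5 * (left + right)
    else:
        amps_all = beats.event_amplitudes.copy()
    t0, t1 = config.hr_window
    sel = (beats.event_times >= t0) & (beats.event_times <= t1)
    # the first and last beats of the trial only have a one-sided trough
    # baseline; keep them out of the envelope
    if idx_all.size >= 2:
        sel[0] = sel[-1] = False
    t, a = beats.event_times[sel], amps_all[sel]
    if t.size < config.min_beats:
        return np.empty(0)
    mean_amp = float(np.mean(np.abs(a)))
    # modulation below ~1% of the pulse amplitude is under the measurement
    # floor of the envelope and is flagged undetectable
    if mean_amp <= 0 or float(np.std(a)) < 1e-2 * mean_amp:
        return np.empty(0)

    fs_env = 4.0
    grid = np.arange(t0, t1, 1.0 / fs_env)
    env = np.interp(grid, t, a)
    env = signal.detrend(env, type="linear")

    nsub = int(round(config.rr_subwindow * fs_env))
    step = max(1, int(round(config.rr_step * fs_env)))
    nfft = 4096
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_env)
    lo, hi = config.rr_band
    band = (freqs >= lo) & (freqs <= hi)
    rr = []
    for start in range(0, env.size - nsub + 1, step):
        seg = env[start:start + nsub] * np.hanning(nsub)
        power = np.abs(np.fft.rfft(seg, nfft)) ** 2
        pband = power[band]
        if not np.any(pband > 0):
            continue
        k = int(np.argmax(pband))
        j = np.flatnonzero(band)[k]
        # parabolic refinement on log power
        if 0 < j < freqs.size - 1 and power[j] > 0:
            with np.errstate(divide="ignore"):
                y0, y1, y2 = np.log(power[j - 1:j + 2] + 1e-300)
            denom = (y0 - 2 * y1 + y2)
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f_hat = freqs[j] + delta * (freqs[1] - freqs[0])
        rr.append(60.0 * f_hat)
    return np.asarray(rr)


def hr_rr_features(hr_series: np.ndarray, rr_series: np.ndarray,
                   ) -> tuple[float, float, float, float]:
    """(stdHR, mHR, stdRR, mRR); empty series -> NaN pair."""

    def mean_std(x):
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            return np.nan, np.nan
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    mhr, stdhr = mean_std(hr_series)
    mrr, stdrr = mean_std(rr_series)
    return stdhr, mhr, stdrr, mrr


# ---------------------------------------------------------------------------
# electrodermal
# ---------------------------------------------------------------------------

def gsr_features(gsr_f: np.ndarray, config: FeatureConfig = FeatureConfig(),
                 ) -> tuple[float, float]:
    """(mNSC, minNSC) from the z-scored trace.

    Peaks are located by the zero-crossing of the first difference (rising to
    falling).  ``mnsc_mode="trace"`` averages the whole normalized trace
    instead of the peak amplitudes.
    """
    x = np.asarray(gsr_f, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        return np.nan, np.nan
    z = (x - np.mean(x)) / sd
    d = np.diff(z)
    peak_idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    if config.mnsc_mode == "trace":
        mnsc = float(np.mean(z))
    else:
        mnsc = float(np.mean(z[peak_idx])) if peak_idx.size else np.nan
    return mnsc, float(np.min(z))


# ---------------------------------------------------------------------------
# ocular
# ---------------------------------------------------------------------------

def detect_blinks(veog: np.ndarray, fs: float = 16.0,
                  config: FeatureConfig = FeatureConfig(),
                  ) -> tuple[EventSeries, int, np.ndarray]:
    """Blink detection on the vertical component.

    Samples with ``|veog|`` above ``blink_k`` robust SDs form candidate
    intervals; intervals closer than ``blink_merge_gap`` samples merge;
    intervals shorter than ``blink_min_samples`` or whose peak stays below
    ``blink_min_height`` are discarded.  Returns the
    blink events, their count NE, and a copy of ``veog`` with each blink
    interval replaced by linear interpolation between its endpoints.
    """
    x = np.asarray(veog, dtype=float)
    thr = config.blink_k * _robust_sd(x)
    mask = np.abs(x) > max(thr, 1e-12)
    # run-length encode the mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))  # inclusive [i0, i1]
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] - 1 <= config.blink_merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    blinks = [(i0, i1) for i0, i1 in merged
              if i1 - i0 + 1 >= config.blink_min_samples
              and np.max(np.abs(x[i0:i1 + 1])) >= config.blink_min_height]

    out = x.copy()
    times, amps = [], []
    for i0, i1 in blinks:
        a = max(i0 - 1 - config.blink_pad, 0)
        b = min(i1 + 1 + config.blink_pad, x.size - 1)
        out[a:b + 1] = np.linspace(x[a], x[b], b - a + 1)
        times.append(i0 / fs)
        amps.append(float(np.max(np.abs(x[i0:i1 + 1]))))
    events = EventSeries(event_times=np.asarray(times),
                         event_amplitudes=np.asarray(amps), event_kind="blink")
    return events, len(blinks), out


def _haar_cwt_response(x: np.ndarray, scale: int, gap: int) -> np.ndarray:
    """Haar-style step response: mean after minus mean before, skipping ``gap``
    samples around the candidate edge so filter-smoothed transitions do not
    bias the amplitude estimate.  Response at a clean step equals its height.
    """
    n = x.size
    c = np.concatenate(([0.0], np.cumsum(x)))
    w = np.zeros(n)
    lo = scale + gap
    i = np.arange(lo, n - lo)
    if i.size:
        after = (c[i + gap + scale] - c[i + gap]) / scale
        before = (c[i - gap] - c[i - gap - scale]) / scale
        w[i] = after - before
    return w


def _component_steps(x: np.ndarray, config: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Detected step indices and signed amplitudes on one EOG component."""
    x = np.asarray(x, dtype=float)
    scales = config.saccade_scales
    W = np.stack([_haar_cwt_response(x, s, config.saccade_gap) for s in scales])
    R = np.max(np.abs(W), axis=0)
    # noise level from the first difference (robust to sparse steps)
    noise = _robust_sd(np.diff(x)) / np.sqrt(2.0)
    thr = max(config.saccade_k * noise, 1e-9)
    min_sep = max(scales) + config.saccade_gap
    idx, _ = signal.find_peaks(R, height=thr, distance=min_sep)
    amps = np.array([W[int(np.argmax(np.abs(W[:, i]))), i] for i in idx])
    return idx, amps


def detect_saccades(heog: np.ndarray, veog_deblinked: np.ndarray,
                    fs: float = 16.0, config: FeatureConfig = FeatureConfig(),
                    ) -> dict[str, float]:
    """Saccadic-movement degrees from the two components.

    Steps are detected per component with a Haar-family continuous wavelet
    transform; the degree of movement on a component is the sum of absolute
    detected step amplitudes.  Events on the two components within
    ``saccade_pair_tol`` samples of each other count as one oblique saccade
    for DSM; an event absent on one component contributes 0 on that axis.
    Returns ``{"DHSM", "DVSM", "mDHV", "DSM"}``.
    """
    h_idx, h_amp = _component_steps(heog, config)
    v_idx, v_amp = _component_steps(veog_deblinked, config)
    dhsm = float(np.sum(np.abs(h_amp)))
    dvsm = float(np.sum(np.abs(v_amp)))

    used_v: set[int] = set()
    dsm = 0.0
    for i, ih in enumerate(h_idx):
        j_match = None
        for j, iv in enumerate(v_idx):
            if j not in used_v and abs(int(ih) - int(iv)) <= config.saccade_pair_tol:
                j_match = j
                break
        if j_match is None:
            dsm += abs(h_amp[i])
        else:
            used_v.add(j_match)
            dsm += float(np.hypot(h_amp[i], v_amp[j_match]))
    for j in range(len(v_idx)):
        if j not in used_v:
            dsm += abs(v_amp[j])

    return {"DHSM": dhsm, "DVSM": dvsm, "mDHV": (dhsm + dvsm) / 2.0, "DSM": dsm}


# ---------------------------------------------------------------------------
# cross-channel covariances
# ---------------------------------------------------------------------------

def covariance_features(heog: np.ndarray, veog: np.ndarray, ppg_f: np.ndarray,
                        fs_raw: float, fs_low: float = 16.0,
                        ) -> tuple[float, float, float]:
    """(CHV, CHP, CVP): sample covariances on a common 16 Hz timeline."""
    ppg16 = decimate_to(np.asarray(ppg_f, dtype=float), fs_raw, fs_low)
    n = min(len(heog), len(veog), len(ppg16))
    h, v, p = heog[:n], veog[:n], ppg16[:n]
    if n < 2:
        return np.nan, np.nan, np.nan
    chv = float(np.cov(h, v, ddof=1)[0, 1])
    chp = float(np.cov(h, p, ddof=1)[0, 1])
    cvp = float(np.cov(v, p, ddof=1)[0, 1])
    return chv, chp, cvp


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def extract_features(pt: ProcessedTrial,
                     config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """All 14 features for one preprocessed trial (NaN where undefined)."""
    hr = estimate_hr_series(pt.ppg_f, pt.fs_raw, config)
    rr = estimate_rr_series(pt.ppg_f, pt.fs_raw, config)
    stdhr, mhr, stdrr, mrr = hr_rr_features(hr, rr)
    mnsc, minnsc = gsr_features(pt.gsr_f, config)
    _, ne, veog_deblinked = detect_blinks(pt.veog, pt.fs_low, config)
    sacc = detect_saccades(pt.heog, veog_deblinked, pt.fs_low, config)
    chv, chp, cvp = covariance_features(pt.heog, pt.veog, pt.ppg_f,
                                        pt.fs_raw, pt.fs_low)
    return FeatureVector(stdHR=stdhr, mHR=mhr, stdRR=stdrr, mRR=mrr,
                         mNSC=mnsc, minNSC=minnsc, NE=float(ne),
                         DHSM=sacc["DHSM"], DVSM=sacc["DVSM"],
                         mDHV=sacc["mDHV"], DSM=sacc["DSM"],
                         CHV=chv, CHP=chp, CVP=cvp)


def features_table(studies: SubjectStudy | list[SubjectStudy],
                   feature_config: FeatureConfig = FeatureConfig(),
                   preprocess_config: PreprocessConfig = PreprocessConfig(),
                   ) -> pd.DataFrame:
    """Tidy feature table: one row per trial, columns stdHR..CVP plus metadata."""
    if isinstance(studies, SubjectStudy):
        studies = [studies]
    rows = []
    for study in studies:
        for sess in study:
            for trial in sess.trials:
                pt = preprocess_trial(trial, preprocess_config)
                fv = extract_features(pt, feature_config)
                row = {"subject_id": study.subject_id,
                       "session_id": sess.session_id,
                       "trial_index": trial.trial_index,
                       "kind": trial.kind,
                       "craving_score": trial.craving_score}
                row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
                rows.append(row)
    return pd.DataFrame(rows)
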