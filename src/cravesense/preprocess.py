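"""Preprocessing chain: raw six-channel trial -> filtered working signals.

* PPG: 5-sample median filter, then 4th-order Butterworth band-pass
  0.1–10 Hz (applied forward-backward, so zero phase), kept at the raw rate.
* GSR: anti-aliased decimation to 16 Hz, 0.2 Hz low-pass, linear detrend.
* EOG: vertical component = above − below, horizontal = right − left; each
  decimated to 16 Hz, median-filtered with a 7-sample window, and re-based by
  subtracting the component's median.

All parameters live in :class:`PreprocessConfig` with the conventional values
as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, signal

from .core import ProcessedTrial, Trial, ValidationError

__all__ = [
    "PreprocessConfig",
    "preprocess_ppg",
    "preprocess_gsr",
    "derive_eog_components",
    "decimate_to",
    "preprocess_trial",
]


@dataclass(frozen=True)
class PreprocessConfig:
    ppg_median_kernel: int = 5       # samples at the raw rate
    ppg_band: tuple[float, float] = (0.1, 10.0)  # Hz
    ppg_order: int = 4               # Butterworth order
    gsr_lowpass_hz: float = 0.2
    gsr_order: int = 4
    eog_median_kernel: int = 7       # samples at fs_low
    fs_low: float = 16.0             # Hz, working rate for GSR/EOG


def _check_finite(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{what}: input contains NaN/inf")
    return x


def decimate_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased decimation by the integer factor ``fs_in / fs_out``."""
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValidationError(f"decimation factor {q} is not a positive integer")
    q = int(round(q))
    if q == 1:
        return np.asarray(x, dtype=np.float64).copy()
    # line-extension padding keeps constants and slow trends artifact-free
    # at the trial edges (zero padding would bend them down)
    return signal.resample_poly(np.asarray(x, dtype=np.float64), up=1, down=q,
                                padtype="line")


def preprocess_ppg(ppg: np.ndarray, fs: float,
                   config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Median filter then zero-phase Butterworth band-pass; length preserved."""
    x = _check_finite(ppg, "preprocess_ppg")
    x = ndimage.median_filter(x, size=config.ppg_median_kernel, mode="nearest")
    sos = signal.butter(config.ppg_order, config.ppg_band, btype="bandpass",
                        fs=fs, output="sos")
    # pad to ~3 time constants of the 0.1 Hz high-pass edge; scipy's default
    # pad is far too short for so low a normalized cutoff
    padlen = min(x.size - 1, int(3 * fs / config.ppg_band[0]))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def preprocess_gsr(gsr: np.ndarray, fs: float,
                   config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Decimate to 16 Hz, low-pass at 0.2 Hz, remove the linear trend."""
    x = _check_finite(gsr, "preprocess_gsr")
    y = decimate_to(x, fs, config.fs_low)
    sos = signal.butter(config.gsr_order, config.gsr_lowpass_hz, btype="lowpass",
                        fs=config.fs_low, output="sos")
    padlen = min(y.size - 1, int(6 * config.fs_low / config.gsr_lowpass_hz))
    y = signal.sosfiltfilt(sos, y, padlen=padlen)
    return signal.detrend(y, type="linear")


def derive_eog_components(eog_above, eog_below, eog_right, eog_left, fs: float,
                          config: PreprocessConfig = PreprocessConfig(),
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vertical/horizontal EOG at 16 Hz, median-filtered, median-rebased."""
    chans = [_check_finite(c, "derive_eog_components")
             for c in (eog_above, eog_below, eog_right, eog_left)]
    n = {c.shape[0] for c in chans}
    if len(n) != 1:
        raise ValidationError("derive_eog_components: channel length mismatch")
    veog = chans[0] - chans[1]
    heog = chans[2] - chans[3]
    out = []
    for comp in (veog, heog):
        y = decimate_to(comp, fs, config.fs_low)
        y = ndimage.median_filter(y, size=config.eog_median_kernel, mode="nearest")
        out.append(y - np.median(y))
    return out[0], out[1]


def preprocess_trial(trial: Trial,
                     config: PreprocessConfig = PreprocessConfig()) -> ProcessedTrial:
    """Apply the full chain to one trial; parameters are recorded in provenance."""
    ppg_f = preprocess_ppg(trial.ppg, trial.fs_raw, config)
    gsr_f = preprocess_gsr(trial.gsr, trial.fs_raw, config)
    veog, heog = derive_eog_components(trial.eog_above, trial.eog_below,
                                       trial.eog_right, trial.eog_left,
                                       trial.fs_raw, config)
    pt = ProcessedTrial(ppg_f=ppg_f, gsr_f=gsr_f, veog=veog, heog=heog,
                        fs_raw=trial.fs_raw, fs_low=config.fs_low,
                        kind=trial.kind, craving_score=trial.craving_score,
                        trial_index=trial.trial_index,
                        session_id=trial.session_id,
                        subject_id=trial.subject_id,
                        provenance=asdict(config))
    pt.validate()
    return pt
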