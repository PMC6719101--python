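"""Domain types and the on-disk session format.

A recording session presents 36 alternating 25-s video trials (18 "wash-off"
baseline clips and 18 game "stimulation" clips) while six physiological
channels are sampled at a common rate: one photoplethysmogram (PPG), one skin
conductance channel (GSR) and four periocular electrodes (above/below the
right eye and the two outer canthi) from which vertical and horizontal EOG
components are later derived.  A subject contributes three such sessions on
different days.

Studies are stored as a directory with a JSON manifest plus one plain-text
columnar file per trial, so fixtures stay diffable and the format needs no
binary reader.  Floats are written with ``%.17g`` and therefore round-trip
bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "WASH_OFF",
    "STIMULATION",
    "TRIAL_KINDS",
    "SESSION_IDS",
    "CHANNEL_NAMES",
    "FEATURE_NAMES",
    "ValidationError",
    "Trial",
    "SessionDataset",
    "SubjectStudy",
    "ProcessedTrial",
    "FeatureVector",
    "save_study",
    "load_study",
    "load_bdf_session",
]

WASH_OFF = "wash_off"
STIMULATION = "stimulation"
TRIAL_KINDS = (WASH_OFF, STIMULATION)
SESSION_IDS = ("day1", "day2", "day3")

#: column order used in per-trial signal files
CHANNEL_NAMES = ("ppg", "gsr", "eog_above", "eog_below", "eog_right", "eog_left")

#: canonical order of the 14 feature candidates (f1..f14)
FEATURE_NAMES = (
    "stdHR", "mHR", "stdRR", "mRR", "mNSC", "minNSC", "NE",
    "DHSM", "DVSM", "mDHV", "DSM", "CHV", "CHP", "CVP",
)


class ValidationError(ValueError):
    """A domain invariant was violated; the message names the offending field."""


def _as_f64(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError("signal channels must be one-dimensional")
    return arr


@dataclass
class Trial:
    """One 25-s trial: six raw channels at ``fs_raw`` plus labels.

    Sample ``i`` of any channel lies at trial-local time ``t = i / fs_raw``
    seconds, ``t in [0, duration)``.
    """

    ppg: np.ndarray
    gsr: np.ndarray
    eog_above: np.ndarray
    eog_below: np.ndarray
    eog_right: np.ndarray
    eog_left: np.ndarray
    kind: str
    craving_score: int
    trial_index: int
    session_id: str = "day1"
    subject_id: str = "S1"
    fs_raw: float = 2048.0
    duration: float = 25.0

    def __post_init__(self) -> None:
        for name in CHANNEL_NAMES:
            setattr(self, name, _as_f64(getattr(self, name)))
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_raw * self.duration))

    def channels(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in CHANNEL_NAMES:
            yield name, getattr(self, name)

    def validate(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValidationError(f"Trial.kind must be one of {TRIAL_KINDS}, got {self.kind!r}")
        if not (1 <= int(self.craving_score) <= 5):
            raise ValidationError(
                f"Trial.craving_score must be in 1..5, got {self.craving_score}"
            )
        n = self.n_samples
        for name, ch in self.channels():
            if ch.shape[0] != n:
                raise ValidationError(
                    f"Trial.{name}: length {ch.shape[0]} != round(fs_raw*duration) = {n}"
                )
        if self.fs_raw <= 0:
            raise ValidationError("Trial.fs_raw must be positive")


@dataclass
class SessionDataset:
    """One session: 36 trials alternating wash-off / stimulation."""

    subject_id: str
    session_id: str
    trials: list[Trial] = field(default_factory=list)

    N_TRIALS = 36

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.trials) != self.N_TRIALS:
            raise ValidationError(
                f"SessionDataset {self.session_id!r}: expected {self.N_TRIALS} trials, "
                f"got {len(self.trials)}"
            )
        for i, tr in enumerate(self.trials):
            expected_kind = WASH_OFF if i % 2 == 0 else STIMULATION
            if tr.kind != expected_kind:
                raise ValidationError(
                    f"SessionDataset {self.session_id!r}: trial {i} has kind {tr.kind!r}, "
                    f"expected {expected_kind!r} (trials alternate starting with wash_off)"
                )
            if tr.trial_index != i:
                raise ValidationError(
                    f"SessionDataset {self.session_id!r}: trial at position {i} "
                    f"has trial_index {tr.trial_index}"
                )

    def trials_of_kind(self, kind: str) -> list[Trial]:
        return [t for t in self.trials if t.kind == kind]


@dataclass
class SubjectStudy:
    """Three sessions (day1, day2, day3) for one subject."""

    subject_id: str
    sessions: dict[str, SessionDataset]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if tuple(self.sessions.keys()) != SESSION_IDS:
            raise ValidationError(
                f"SubjectStudy.sessions must have keys {SESSION_IDS} in order, "
                f"got {tuple(self.sessions.keys())}"
            )
        for sid, sess in self.sessions.items():
            if sess.session_id != sid:
                raise ValidationError(
                    f"SubjectStudy: session stored under {sid!r} has session_id "
                    f"{sess.session_id!r}"
                )
            if sess.subject_id != self.subject_id:
                raise ValidationError(
                    f"SubjectStudy {self.subject_id!r}: session {sid!r} belongs to "
                    f"{sess.subject_id!r}"
                )

    def __iter__(self) -> Iterator[SessionDataset]:
        return iter(self.sessions.values())


@dataclass
class ProcessedTrial:
    """Preprocessed view of a trial.

    ``ppg_f`` stays at the raw rate; ``gsr_f`` and the derived EOG components
    live at the 16 Hz working rate.  ``provenance`` records the filter
    parameters that produced the signals.
    """

    ppg_f: np.ndarray
    gsr_f: np.ndarray
    veog: np.ndarray
    heog: np.ndarray
    fs_raw: float
    fs_low: float = 16.0
    kind: str = WASH_OFF
    craving_score: int = 1
    trial_index: int = 0
    session_id: str = "day1"
    subject_id: str = "S1"
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.veog.shape != self.heog.shape:
            raise ValidationError("ProcessedTrial: veog/heog length mismatch")
        if self.fs_low != 16.0:
            raise ValidationError("ProcessedTrial.fs_low must be 16 Hz")


@dataclass
class FeatureVector:
    """The 14 feature candidates extracted from one trial.

    Numbering follows the conventional order: 1 stdHR, 2 mHR, 3 stdRR, 4 mRR,
    5 mNSC, 6 minNSC, 7 NE, 8 DHSM, 9 DVSM, 10 mDHV, 11 DSM, 12 CHV,
    13 CHP, 14 CVP.  Features that could not be computed (no detectable
    beats, flat GSR trace, ...) are NaN; downstream stages treat NaN as
    missing.
    """

    stdHR: float
    mHR: float
    stdRR: float
    mRR: float
    mNSC: float
    minNSC: float
    NE: float
    DHSM: float
    DVSM: float
    mDHV: float
    DSM: float
    CHV: float
    CHP: float
    CVP: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (14,):
            raise ValidationError("FeatureVector.from_array expects 14 values")
        return cls(**dict(zip(FEATURE_NAMES, arr)))


# ---------------------------------------------------------------------------
# On-disk format: <dir>/manifest.json + <dir>/<session>_trial<ii>.csv
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _trial_filename(session_id: str, trial_index: int) -> str:
    return f"{session_id}_trial{trial_index:02d}.csv"


def save_study(study: SubjectStudy, path: str | Path) -> Path:
    """Write a study to ``path`` (JSON manifest + one CSV per trial).

    Returns the manifest path.  Signals are written with 17 significant
    digits, so :func:`load_study` reproduces them bitwise.
    """
    study.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "cravesense-study-v1", "subject_id": study.subject_id,
                      "sessions": []}
    for sess in study:
        rec = {"session_id": sess.session_id, "trials": []}
        for tr in sess.trials:
            fname = _trial_filename(sess.session_id, tr.trial_index)
            data = np.column_stack([ch for _, ch in tr.channels()])
            np.savetxt(root / fname, data, fmt=_FLOAT_FMT, delimiter=",",
                       header=",".join(CHANNEL_NAMES), comments="")
            rec["trials"].append({
                "trial_index": tr.trial_index,
                "kind": tr.kind,
                "craving_score": int(tr.craving_score),
                "fs_raw": tr.fs_raw,
                "duration": tr.duration,
                "file": fname,
            })
        manifest["sessions"].append(rec)
    mpath = root / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_study(path: str | Path) -> SubjectStudy:
    """Load a study saved by :func:`save_study`; validates all invariants."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    manifest = json.loads(mpath.read_text())
    subject_id = manifest["subject_id"]
    sessions: dict[str, SessionDataset] = {}
    for rec in manifest["sessions"]:
        sid = rec["session_id"]
        trials = []
        for trec in rec["trials"]:
            fpath = root / trec["file"]
            if not fpath.exists():
                raise FileNotFoundError(
                    f"missing trial: session {sid!r} trial_index {trec['trial_index']} "
                    f"({trec['file']})"
                )
            data = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
            if data.shape[1] != len(CHANNEL_NAMES):
                raise ValidationError(
                    f"{fpath.name}: expected {len(CHANNEL_NAMES)} channels, "
                    f"got {data.shape[1]}"
                )
            chans = {name: data[:, j] for j, name in enumerate(CHANNEL_NAMES)}
            trials.append(Trial(
                **chans,
                kind=trec["kind"],
                craving_score=trec["craving_score"],
                trial_index=trec["trial_index"],
                session_id=sid,
                subject_id=subject_id,
                fs_raw=trec["fs_raw"],
                duration=trec["duration"],
            ))
        sessions[sid] = SessionDataset(subject_id=subject_id, session_id=sid,
                                       trials=trials)
    return SubjectStudy(subject_id=subject_id, sessions=sessions)


def load_bdf_session(path, channel_map: dict[str, str], *, subject_id: str,
                     session_id: str, trial_onsets_s, kinds, craving_scores,
                     duration: float = 25.0) -> SessionDataset:
    """Adapter: cut a continuous EDF/BDF recording into a :class:`SessionDataset`.

    ``channel_map`` maps the six canonical channel names (see
    :data:`CHANNEL_NAMES`) to channel labels in the file.  ``trial_onsets_s``
    gives the 36 trial onsets in seconds.  Requires :mod:`mne` (optional
    dependency); raises ImportError otherwise.
    """
    import mne  # noqa: deferred optional import

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    n = int(round(fs * duration))
    trials = []
    for i, (onset, kind, score) in enumerate(zip(trial_onsets_s, kinds, craving_scores)):
        start = int(round(onset * fs))
        chans = {}
        for canon, label in channel_map.items():
            sig = raw.get_data(picks=[label])[0, start:start + n]
            chans[canon] = np.asarray(sig, dtype=np.float64)
        trials.append(Trial(**chans, kind=kind, craving_score=score, trial_index=i,
                            session_id=session_id, subject_id=subject_id,
                            fs_raw=fs, duration=duration))
    return SessionDataset(subject_id=subject_id, session_id=session_id, trials=trials)
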