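"""Session containers, validation, trimming, event masks, and TSV round trips.

Conventions
-----------
* Channels are 1-based in all public interfaces (``ch01`` .. ``ch11``);
  internally arrays are 0-based with shape ``(n_channels, n_samples)``.
* Event frame ``k`` (1 Hz) covers samples ``[k*fs, (k+1)*fs)`` — half-open.
* Floats are written with 6 significant digits, so a write -> read -> write
  round trip is bit-identical text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ROLES = ("listener", "speaker_left", "speaker_right")
EVENT_LABELS = ("verbal", "nonverbal", "none")
FLOAT_FMT = "%.6g"


class ValidationError(ValueError):
    pass


@dataclass
class ChannelTimeSeries:
    """One subject's one-channel recording for one session."""

    subject: str
    session: str
    channel: int  # 1-based
    fs: float
    values: np.ndarray


@dataclass
class EventLog:
    """1 Hz behavioral labels over the task window.

    ``labels[k]`` is the response category of second ``k`` (exhaustive and
    exclusive); ``listener_speaking[k]`` flags seconds in which the listener
    was talking.
    """

    labels: np.ndarray  # dtype '<U9', values in EVENT_LABELS
    listener_speaking: np.ndarray  # bool

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.listener_speaking = np.asarray(self.listener_speaking, dtype=bool)
        if self.labels.shape != self.listener_speaking.shape:
            raise ValidationError("labels and listener_speaking lengths differ")
        bad = set(np.unique(self.labels)) - set(EVENT_LABELS)
        if bad:
            raise ValidationError(f"unknown event labels: {bad}")

    @property
    def n_seconds(self) -> int:
        return self.labels.size

    def event_times(self, category: str) -> np.ndarray:
        """Onset seconds of events of a category (first second of each run)."""
        is_cat = self.labels == category
        onsets = np.nonzero(is_cat & ~np.r_[False, is_cat[:-1]])[0]
        return onsets


@dataclass
class GroupRecord:
    """One group's aligned recordings: rest + one task session, plus labels.

    ``task_data`` / ``rest_data`` map role -> array (n_channels, n_samples).
    """

    group_id: int
    fs: float
    task_data: dict
    rest_data: dict
    attended: str = "speaker_left"
    condition: str = "face_to_face"
    task: str = "multi_speaker"
    events: EventLog | None = None
    envelopes: dict | None = None  # role -> 10 Hz envelope of that speaker
    quality: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def unattended(self) -> str:
        return "speaker_right" if self.attended == "speaker_left" else "speaker_left"

    def role_of(self, dyad_role: str) -> str:
        """Map a dyad role (listener/attended/unattended) to a seat role."""
        if dyad_role == "listener":
            return "listener"
        if dyad_role == "attended":
            return self.attended
        if dyad_role == "unattended":
            return self.unattended
        raise ValueError(f"unknown dyad role {dyad_role!r}")

    def dyad_members(self, dyad: str) -> tuple:
        """Seat roles for a dyad label: LA, LU, or AU."""
        pairs = {
            "LA": ("listener", self.attended),
            "LU": ("listener", self.unattended),
            "AU": (self.attended, self.unattended),
        }
        if dyad not in pairs:
            raise ValueError(f"dyad must be one of {tuple(pairs)}")
        return pairs[dyad]


# --- trimming and masks --------------------------------------------------


def trim_session(values: np.ndarray, fs: float, lead_trim_s: float = 40.0,
                 tail_trim_s: float = 40.0) -> np.ndarray:
    """Remove the lead/tail buffers of a raw session, keeping the interior.

    Default trims follow the task design: a 30 s instrument-settling rest plus
    the first/last 10 s of the communication period at each end of a 360 s
    task recording, leaving 280 s.
    """
    values = np.asarray(values)
    n = values.shape[-1]
    lead = int(round(lead_trim_s * fs))
    tail = int(round(tail_trim_s * fs))
    if n - lead - tail < 1:
        raise ValidationError(
            f"series of {n} samples too short for trims {lead_trim_s}+{tail_trim_s} s"
        )
    return values[..., lead:n - tail]


def trim_to_duration(values: np.ndarray, fs: float, duration_s: float) -> np.ndarray:
    """Center-trim a session to a target duration (rest-session policy)."""
    values = np.asarray(values)
    n = values.shape[-1]
    target = int(round(duration_s * fs))
    if target > n:
        raise ValidationError(f"cannot trim {n} samples up to {target}")
    lead = (n - target) // 2
    return values[..., lead:lead + target]


def mask_from_events(log: EventLog, fs: float) -> np.ndarray:
    """Expand the 1 Hz listener-speaking flags to a listener-silent mask at fs.

    Frame ``k`` covers samples ``[k*fs, (k+1)*fs)``; the mask is True where
    the listener is *silent*.
    """
    step = int(round(fs))
    return np.repeat(~log.listener_speaking, step)


# --- validation -----------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_group(group: GroupRecord, n_channels: int = 11,
                   strict: bool = False) -> ValidationReport:
    """Check role completeness, channel count, equal lengths and fs coupling."""
    rep = ValidationReport()
    for label, data in (("task", group.task_data), ("rest", group.rest_data)):
        missing = [r for r in ROLES if r not in data]
        if missing:
            rep.errors.append(f"{label}: missing roles {missing}")
            continue
        lengths = {}
        for role, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[0] != n_channels:
                rep.errors.append(
                    f"{label}/{role}: expected {n_channels} channels, got shape {arr.shape}"
                )
                continue
            if not np.all(np.isfinite(arr)):
                rep.errors.append(f"{label}/{role}: non-finite samples")
            lengths[role] = arr.shape[1]
        if len(set(lengths.values())) > 1:
            rep.errors.append(f"{label}: unequal lengths {lengths}")
    if group.attended not in ("speaker_left", "speaker_right"):
        rep.errors.append(f"attended must be a speaker, got {group.attended!r}")
    if group.events is not None and group.task_data.get("listener") is not None:
        n_sec = int(np.asarray(group.task_data["listener"]).shape[-1] / group.fs)
        if group.events.n_seconds != n_sec:
            rep.errors.append(
                f"event log covers {group.events.n_seconds} s, task lasts {n_sec} s"
            )
    if group.events is None:
        rep.warnings.append("no event log")
    if not group.envelopes:
        rep.warnings.append("no speech envelopes")
    if group.quality is None:
        rep.warnings.append("no communication-quality score")
    if strict and not rep.ok:
        raise ValidationError("; ".join(rep.errors))
    return rep


# --- TSV / YAML round trips ----------------------------------------------


def _session_frame(values: np.ndarray, fs: float) -> pd.DataFrame:
    values = np.asarray(values)
    n_ch, n = values.shape
    cols = {"time_s": np.arange(n) / fs}
    for c in range(n_ch):
        cols[f"ch{c + 1:02d}"] = values[c]
    return pd.DataFrame(cols)


def write_session_tsv(path, values: np.ndarray, fs: float) -> None:
    _session_frame(values, fs).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_session_tsv(path) -> tuple:
    """Returns (values (n_ch, n), fs)."""
    df = pd.read_csv(path, sep="\t")
    chans = [c for c in df.columns if c.startswith("ch")]
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 10.0
    return df[chans].to_numpy().T, float(round(fs, 6))


def write_events_tsv(path, log: EventLog) -> None:
    """BIDS-events-style TSV: one row per second with its label and flag."""
    df = pd.DataFrame(
        {
            "onset": np.arange(log.n_seconds),
            "duration": np.ones(log.n_seconds, dtype=int),
            "trial_type": log.labels,
            "listener_speaking": log.listener_speaking.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventLog:
    df = pd.read_csv(path, sep="\t")
    return EventLog(
        labels=df["trial_type"].to_numpy(dtype="U9"),
        listener_speaking=df["listener_speaking"].to_numpy(dtype=bool),
    )


def write_envelope_tsv(path, env: np.ndarray, fs: float) -> None:
    df = pd.DataFrame({"time_s": np.arange(env.size) / fs, "amplitude": env})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_envelope_tsv(path) -> tuple:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 10.0
    return df["amplitude"].to_numpy(), float(round(fs, 6))


def write_matrix_tsv(path, matrix: np.ndarray) -> None:
    """Labeled n_ch x n_ch matrix (rows: first member's channel)."""
    n = matrix.shape[0]
    df = pd.DataFrame(
        matrix,
        index=[f"ch{c + 1:02d}" for c in range(n)],
        columns=[f"ch{c + 1:02d}" for c in range(n)],
    )
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="channel")


def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_group(out_dir, group: GroupRecord) -> None:
    """Persist one group: per subject-session series TSVs + events/envelopes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gid = f"group{group.group_id:02d}"
    for label, data in (("task", group.task_data), ("rest", group.rest_data)):
        for role, arr in data.items():
            write_session_tsv(out / f"{gid}_{role}_{label}.tsv", arr, group.fs)
    if group.events is not None:
        write_events_tsv(out / f"{gid}_events.tsv", group.events)
    if group.envelopes:
        for role, env in group.envelopes.items():
            write_envelope_tsv(out / f"{gid}_envelope_{role}.tsv", env, group.fs)
    info = {
        "group_id": group.group_id,
        "fs": group.fs,
        "attended": group.attended,
        "condition": group.condition,
        "task": group.task,
        "quality": None if group.quality is None else float(group.quality),
    }
    with open(out / f"{gid}_info.yaml", "w") as fh:
        yaml.safe_dump(info, fh, sort_keys=False)


def read_group(out_dir, group_id: int) -> GroupRecord:
    out = Path(out_dir)
    gid = f"group{group_id:02d}"
    with open(out / f"{gid}_info.yaml") as fh:
        info = yaml.safe_load(fh)
    task_data, rest_data = {}, {}
    fs = info["fs"]
    for role in ROLES:
        task_data[role], _ = read_session_tsv(out / f"{gid}_{role}_task.tsv")
        rest_data[role], _ = read_session_tsv(out / f"{gid}_{role}_rest.tsv")
    events = None
    ev_path = out / f"{gid}_events.tsv"
    if ev_path.exists():
        events = read_events_tsv(ev_path)
    envelopes = {}
    for role in ("speaker_left", "speaker_right"):
        p = out / f"{gid}_envelope_{role}.tsv"
        if p.exists():
            envelopes[role], _ = read_envelope_tsv(p)
    return GroupRecord(
        group_id=info["group_id"], fs=fs, task_data=task_data, rest_data=rest_data,
        attended=info["attended"], condition=info["condition"], task=info["task"],
        events=events, envelopes=envelopes or None, quality=info.get("quality"),
    )
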