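"""Reading recorded EEG, writing session logs, manifests and fixtures.

Session logs are line-delimited JSON (one event per line, preceded by a
header record) so the file can be appended to while a simulated session is
running.  A run manifest captures the config, seed, package version and
input digests needed to replay a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .preprocessing import RawSegment
from .session import SessionConfig, SessionState, TrialEvent

LOG_SCHEMA_VERSION = 1

__all__ = [
    "read_edf",
    "read_csv_signal",
    "write_csv_signal",
    "ReplaySource",
    "write_session_log",
    "read_session_log",
    "write_manifest",
    "file_digest",
]


def read_edf(path: str | Path) -> RawSegment:
    """Load a continuous EEG recording from an EDF file (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawSegment(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sample_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_csv_signal(path: str | Path) -> RawSegment:
    """Load a continuous recording from CSV: header row of channel names
    prefixed by a ``# sample_rate=<hz>`` comment line; one row per sample."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError("csv signal file must start with '# sample_rate=<hz>'")
        fs = float(first.split("=", 1)[1])
        names = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return RawSegment(data=data.T, sample_rate=fs, channel_names=names)


def write_csv_signal(path: str | Path, segment: RawSegment) -> None:
    path = Path(path)
    names = segment.channel_names or [f"CH{i:02d}" for i in range(segment.n_channels)]
    with path.open("w") as fh:
        fh.write(f"# sample_rate={segment.sample_rate}\n")
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, segment.data.T, delimiter=",", fmt="%.6f")


class ReplaySource:
    """EEG source replaying a recorded (or fixture) session.

    Built from a continuous recording plus a cue schedule
    ``[{"cue": "right", "start_s": 0.0, "duration_s": 10.0}, ...]``.  The
    source carries its own cues (``provides_cues``): the engine consumes
    trials in recorded order and uses the recorded labels, since a replay
    cannot honor a different cue schedule than the one that was run.
    """

    provides_cues = True

    def __init__(self, recording: RawSegment, schedule: list[dict]):
        self.recording = recording
        self.schedule = list(schedule)
        self._next = 0

    @classmethod
    def from_files(cls, signal_path: str | Path, schedule_path: str | Path) -> "ReplaySource":
        signal_path = Path(signal_path)
        if signal_path.suffix.lower() == ".edf":
            rec = read_edf(signal_path)
        else:
            rec = read_csv_signal(signal_path)
        sched = json.loads(Path(schedule_path).read_text())
        return cls(rec, sched["trials"] if isinstance(sched, dict) else sched)

    def __len__(self) -> int:
        return len(self.schedule) - self._next

    def next_trial(self, duration_s: float) -> tuple[RawSegment, str]:
        if self._next >= len(self.schedule):
            raise RuntimeError("replay source exhausted: no more recorded trials")
        item = self.schedule[self._next]
        self._next += 1
        fs = self.recording.sample_rate
        i0 = int(round(item["start_s"] * fs))
        n = int(round(min(duration_s, item.get("duration_s", duration_s)) * fs))
        return (
            RawSegment(
                data=self.recording.data[:, i0 : i0 + n],
                sample_rate=fs,
                channel_names=self.recording.channel_names,
            ),
            item["cue"],
        )


def _event_to_dict(e: TrialEvent) -> dict:
    d = dataclasses.asdict(e)
    return {k: v for k, v in d.items() if v is not None}


def write_session_log(path: str | Path, state: SessionState) -> None:
    """Line-delimited JSON: a header record, then one record per event,
    then a summary record."""
    path = Path(path)
    header = {
        "record": "header",
        "schema_version": LOG_SCHEMA_VERSION,
        "coadapt_version": __version__,
        "config": dataclasses.asdict(state.config),
    }
    summary = {
        "record": "summary",
        "phase": state.phase,
        "u_total": state.u_total,
        "n_resets": state.n_resets,
        "u_accuracy_history": state.u_history,
        "c_targets_reached": state.c_targets_reached,
        "c_reps_done": state.c_reps_done,
        "final_thresholds": {
            "right": state.thresholds.threshold("right"),
            "left": state.thresholds.threshold("left"),
        },
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for e in state.events:
            fh.write(json.dumps({"record": "event", **_event_to_dict(e)}) + "\n")
        fh.write(json.dumps(summary) + "\n")


def read_session_log(path: str | Path) -> tuple[dict, list[TrialEvent], dict]:
    """Parse a session log back into (header, events, summary)."""
    header: dict = {}
    summary: dict = {}
    events: list[TrialEvent] = []
    fields = {f.name for f in dataclasses.fields(TrialEvent)}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            kind = rec.pop("record", "event")
            if kind == "header":
                header = rec
            elif kind == "summary":
                summary = rec
            else:
                events.append(TrialEvent(**{k: v for k, v in rec.items() if k in fields}))
    if not events:
        raise ValueError(f"no events found in session log {path}")
    return header, events, summary


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config: SessionConfig,
    seed: int,
    outputs: list[str],
    inputs: dict[str, str] | None = None,
    extra: dict | None = None,
) -> None:
    """Everything needed to replay a run bit-identically."""
    manifest = {
        "coadapt_version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "inputs": inputs or {},
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
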