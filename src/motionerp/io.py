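"""Continuous recordings, event lists, and BrainVision-dialect file I/O.

A :class:`Recording` holds a channels x samples matrix at 1000 Hz together
with an event stream (stimulus-onset markers carrying the motion-velocity
condition, and button-press markers).  On disk, recordings use the
BrainVision triplet dialect: a text header (``.vhdr``), multiplexed IEEE
float32 binary data (``.eeg``), and a text marker file (``.vmrk``).  EEG and
EOG channels are stored in microvolts; the EMG channel is on an arbitrary
millivolt-like scale.

Conventions: sample indexing is 0-based internally (BrainVision marker
positions are 1-based on disk and converted on read/write); event time zero
is the marker sample; analysis windows in ms map to half-open
``[start, stop)`` sample ranges at 1 ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import MotionErpError, ParseError

#: Marker labels used on disk for the two motion-velocity conditions.
STIM_CODES = {"slow": "S  1", "fast": "S  2"}
RESPONSE_CODE = "R  1"

CHANNEL_KINDS = ("eeg", "eog", "emg")


@dataclass(frozen=True)
class Event:
    """A single marker: 0-based sample index, label, optional condition."""

    sample: int
    label: str                      # "stimulus" or "response"
    condition: str | None = None    # "slow" | "fast" for stimulus events


@dataclass
class EventList:
    """Sorted list of events with strictly in-recording sample indices."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.sample)

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def stimuli(self, condition: str | None = None) -> list[Event]:
        out = [e for e in self.events if e.label == "stimulus"]
        if condition is not None:
            out = [e for e in out if e.condition == condition]
        return out

    def responses(self) -> list[Event]:
        return [e for e in self.events if e.label == "response"]

    def validate(self, n_samples: int):
        for e in self.events:
            if not (0 <= e.sample < n_samples):
                raise MotionErpError(
                    f"event at sample {e.sample} outside recording "
                    f"of {n_samples} samples"
                )

    def to_tsv(self) -> str:
        lines = ["sample\tlabel\tcondition"]
        for e in self.events:
            lines.append(f"{e.sample}\t{e.label}\t{e.condition or ''}")
        return "\n".join(lines) + "\n"


@dataclass
class Recording:
    """Continuous multi-channel recording with markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix; EEG/EOG in uV, EMG in arbitrary mV-scale units.
    srate : float
        Sampling rate in Hz (1000 for this protocol).
    channel_labels : tuple of str
        Unique channel names; 10:10 electrode names plus "EOG" and "EMG".
    channel_kinds : tuple of str
        One of "eeg", "eog", "emg" per channel.
    events : EventList
    """

    data: np.ndarray
    srate: float
    channel_labels: tuple
    channel_kinds: tuple
    events: EventList = field(default_factory=EventList)

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.channel_kinds = tuple(self.channel_kinds)
        if self.srate <= 0:
            raise MotionErpError("sampling rate must be > 0")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise MotionErpError("channel labels must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise MotionErpError(
                "data must be (n_channels, n_samples) matching channel_labels"
            )
        if len(self.channel_kinds) != len(self.channel_labels):
            raise MotionErpError("channel_kinds must match channel_labels")
        for k in self.channel_kinds:
            if k not in CHANNEL_KINDS:
                raise MotionErpError(f"unknown channel kind {k!r}")
        self.events.validate(self.data.shape[1])

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MotionErpError(f"channel {label!r} not in recording") from None

    def picks(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self.channel_kinds) if k == kind]

    @property
    def eeg_labels(self) -> tuple:
        return tuple(self.channel_labels[i] for i in self.picks("eeg"))

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw and "events" not in kw:
            kw["events"] = self.events
        return replace(self, **kw)


# --------------------------------------------------------------------------
# BrainVision triplet dialect
# --------------------------------------------------------------------------

def _marker_string(event: Event) -> str:
    if event.label == "stimulus":
        if event.condition not in STIM_CODES:
            raise MotionErpError(f"stimulus event without valid condition: {event}")
        return "Stimulus", STIM_CODES[event.condition]
    if event.label == "response":
        return "Response", RESPONSE_CODE
    raise MotionErpError(f"cannot serialize event label {event.label!r}")


def write_brainvision(recording: Recording, path) -> Path:
    """Write ``recording`` as a BrainVision triplet; returns the .vhdr path.

    ``path`` may omit the extension.  Data are stored as multiplexed
    little-endian IEEE float32 with resolution 1, so a write/read round trip
    reproduces samples to float32 precision and markers exactly.
    """
    path = Path(path)
    stem = path.with_suffix("")
    vhdr, eeg, vmrk = (stem.with_suffix(s) for s in (".vhdr", ".eeg", ".vmrk"))

    n_ch = len(recording.channel_labels)
    sampling_interval_us = 1e6 / recording.srate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by motionerp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, (label, kind) in enumerate(
        zip(recording.channel_labels, recording.channel_kinds), start=1
    ):
        unit = "mV" if kind == "emg" else "µV"
        lines.append(f"Ch{i}={label},,1,{unit}")
    lines += ["", "[Channel Kinds]"]
    for i, kind in enumerate(recording.channel_kinds, start=1):
        lines.append(f"Kind{i}={kind}")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    recording.data.astype("<f4").T.tofile(eeg)

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        f"Mk1=New Segment,,1,1,0,0",
    ]
    for j, ev in enumerate(recording.events, start=2):
        mtype, mdesc = _marker_string(ev)
        # marker positions are 1-based on disk
        mlines.append(f"Mk{j}={mtype},{mdesc},{ev.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def _parse_ini(text: str, filename: str):
    """Minimal INI parse preserving line numbers: {section: [(line, k, v)]}."""
    sections: dict[str, list] = {}
    current = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections.setdefault(current, [])
            continue
        if "=" in line and current is not None:
            k, v = line.split("=", 1)
            sections[current].append((ln, k.strip(), v.strip()))
    return sections


def read_brainvision(path) -> Recording:
    """Read a BrainVision triplet written by this package (or compatible).

    Raises :class:`ParseError` (with a line number where applicable) on
    malformed headers, unsupported binary formats, or a data file whose size
    disagrees with the declared channel count.
    """
    vhdr = Path(path)
    if not vhdr.exists():
        raise ParseError(f"header file not found: {vhdr}")
    text = vhdr.read_text(encoding="utf-8")
    if "Brain Vision Data Exchange Header File" not in text.splitlines()[0]:
        raise ParseError("not a BrainVision header", line=1)
    sec = _parse_ini(text, vhdr.name)

    common = {k: (ln, v) for ln, k, v in sec.get("Common Infos", [])}

    def need(key):
        if key not in common:
            raise ParseError(f"missing {key} in [Common Infos] of {vhdr.name}")
        return common[key][1]

    data_file = vhdr.parent / need("DataFile")
    marker_file = vhdr.parent / need("MarkerFile")
    n_ch = int(need("NumberOfChannels"))
    srate = 1e6 / float(need("SamplingInterval"))
    if need("DataOrientation").upper() != "MULTIPLEXED":
        ln = common["DataOrientation"][0]
        raise ParseError("only MULTIPLEXED orientation supported", line=ln)

    binfo = {k: (ln, v) for ln, k, v in sec.get("Binary Infos", [])}
    if "BinaryFormat" not in binfo or binfo["BinaryFormat"][1] != "IEEE_FLOAT_32":
        raise ParseError("only IEEE_FLOAT_32 binary format supported")

    labels, units = [], []
    for ln, k, v in sec.get("Channel Infos", []):
        parts = v.split(",")
        if len(parts) < 4:
            raise ParseError(f"malformed channel entry {k}", line=ln)
        labels.append(parts[0])
        units.append(parts[3])
    if len(labels) != n_ch:
        raise ParseError(
            f"header declares {n_ch} channels but lists {len(labels)} entries"
        )
    kinds = [None] * n_ch
    for ln, k, v in sec.get("Channel Kinds", []):
        idx = int(k.replace("Kind", "")) - 1
        if v not in CHANNEL_KINDS:
            raise ParseError(f"unknown channel kind {v!r}", line=ln)
        kinds[idx] = v
    for i in range(n_ch):
        if kinds[i] is None:  # infer from label/unit for foreign files
            lb = labels[i].upper()
            kinds[i] = "eog" if "EOG" in lb else ("emg" if "EMG" in lb else "eeg")

    if not data_file.exists():
        raise ParseError(f"data file not found: {data_file}")
    raw = np.fromfile(data_file, dtype="<f4")
    if raw.size % n_ch != 0:
        raise ParseError(
            f"data file {data_file.name} holds {raw.size} samples, not a "
            f"multiple of the declared {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64)

    events = []
    if not marker_file.exists():
        raise ParseError(f"marker file not found: {marker_file}")
    mtext = marker_file.read_text(encoding="utf-8")
    msec = _parse_ini(mtext, marker_file.name)
    code_to_cond = {v: k for k, v in STIM_CODES.items()}
    for ln, k, v in msec.get("Marker Infos", []):
        parts = v.split(",")
        if len(parts) < 3:
            raise ParseError(f"malformed marker {k}", line=ln)
        mtype, mdesc, mpos = parts[0], parts[1], parts[2]
        if mtype == "New Segment":
            continue
        sample = int(mpos) - 1
        if mtype == "Stimulus":
            cond = code_to_cond.get(mdesc)
            if cond is None:
                raise ParseError(f"unknown stimulus code {mdesc!r}", line=ln)
            events.append(Event(sample, "stimulus", cond))
        elif mtype == "Response":
            events.append(Event(sample, "response"))
        # other marker types are ignored

    return Recording(
        data=data,
        srate=srate,
        channel_labels=tuple(labels),
        channel_kinds=tuple(kinds),
        events=EventList(events),
    )
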