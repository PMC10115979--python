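"""Recording data model, montage, file formats, and pipeline configuration.

The central container is :class:`EEGRecording`: a channels x samples matrix in
microvolts with a sampling rate, ordered channel labels, 2-D scalp positions
(unit disk, nose toward +y), and condition event markers.  Recordings move
between disk and memory in three dialects:

* delimited text — one header row of channel labels, then one row per sample
  (tab or comma; sniffed on read), with an optional ``<stem>.events`` sidecar
  of ``sample<TAB>tag`` lines;
* EDF — read through mne; a minimal 16-bit EDF writer is provided because no
  installed library exports EDF;
* native ``.npz`` — a lossless round-trip format for intermediate results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("eegmicrostates")

#: condition tags used by the two experimental arms
AI_CONDITIONS = ("rest", "imagery_left", "imagery_right")
RA_CONDITIONS = ("rest", "real_needle")


class FormatError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

# 31 standard 10-20/10-10 labels with schematic unit-disk positions
# (x: left -> right, y: posterior -> anterior/nose).  Left-right symmetric.
MONTAGE_31: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.35, 0.50), "Fz": (0.0, 0.50),
    "F4": (0.35, 0.50), "F8": (0.81, 0.59),
    "FT9": (-0.95, 0.31), "FC5": (-0.68, 0.28), "FC1": (-0.25, 0.25),
    "FC2": (0.25, 0.25), "FC6": (0.68, 0.28), "FT10": (0.95, 0.31),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "TP9": (-0.95, -0.31), "CP5": (-0.68, -0.28), "CP1": (-0.25, -0.25),
    "CP2": (0.25, -0.25), "CP6": (0.68, -0.28), "TP10": (0.95, -0.31),
    "P7": (-0.81, -0.59), "P3": (-0.35, -0.50), "Pz": (0.0, -0.50),
    "P4": (0.35, -0.50), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def default_montage() -> tuple[list[str], np.ndarray]:
    """Built-in 31-position montage: (labels, positions[n, 2])."""
    labels = list(MONTAGE_31)
    pos = np.array([MONTAGE_31[c] for c in labels], dtype=float)
    return labels, pos


def load_montage(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a user montage file: ``label x y`` per line (whitespace/comma)."""
    labels, rows = [], []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise FormatError(f"montage line {i + 1}: expected 'label x y', got {line!r}")
        labels.append(parts[0])
        rows.append((float(parts[1]), float(parts[2])))
    return labels, np.asarray(rows, dtype=float)


def montage_positions(ch_names: list[str]) -> np.ndarray:
    """Positions for the given labels from the built-in template."""
    missing = [c for c in ch_names if c not in MONTAGE_31]
    if missing:
        raise KeyError(f"channels not in built-in montage: {missing}")
    return np.array([MONTAGE_31[c] for c in ch_names], dtype=float)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG: ``data[n_channels, n_samples]`` in microvolts."""

    data: np.ndarray
    srate: float
    ch_names: list[str]
    ch_pos: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = ""
    group_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ch_pos = np.asarray(self.ch_pos, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.ch_names) != n_ch or self.ch_pos.shape != (n_ch, 2):
            raise ValueError(
                f"inconsistent dimensions: {n_ch} data rows, "
                f"{len(self.ch_names)} labels, ch_pos {self.ch_pos.shape}"
            )
        if len(set(self.ch_names)) != n_ch:
            dupes = sorted({c for c in self.ch_names if self.ch_names.count(c) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        self.events = [(int(s), str(t)) for s, t in self.events]
        for s, _t in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event sample {s} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def copy_with(self, **kw) -> "EEGRecording":
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d["data"] = d["data"].copy()
        d.update(kw)
        return EEGRecording(**d)


@dataclass
class ConditionEpoch:
    """A condition-labelled slice of a recording."""

    condition_tag: str
    data: np.ndarray
    srate: float

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PipelineConfig:
    """Tunable knobs for the full analysis chain."""

    band: tuple[float, float] = (1.0, 45.0)
    resample_hz: float = 200.0
    cluster_range: tuple[int, int] = (4, 8)
    n_restarts: int = 50
    max_iter: int = 500
    tol: float = 1e-7
    seed: int = 0
    smoothing_min_samples: int = 0
    artifact_mode: str = "passthrough"
    max_peak_maps: int | None = 4000

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if high >= self.resample_hz / 2:
            raise ValueError("band upper edge must be below resample Nyquist")
        k0, k1 = self.cluster_range
        if not (2 <= k0 <= k1 <= 12):
            raise ValueError("cluster_range must lie within [2, 12]")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.artifact_mode not in ("bss", "passthrough"):
            raise ValueError("artifact_mode must be 'bss' or 'passthrough'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("band", "cluster_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["cluster_range"] = list(self.cluster_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events")


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_text(path: Path, srate: float | None) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.strip():
            raise FormatError(f"{path}: empty header line 1")
        delim = _sniff_delimiter(header)
        ch_names = [c.strip() for c in header.split(delim)]
        if any(not c for c in ch_names):
            raise FormatError(f"{path}: malformed header line 1: empty label")
        n_ch = len(ch_names)
        rows = []
        for i, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            vals = line.split(delim)
            if len(vals) != n_ch:
                raise FormatError(
                    f"{path}: row {i} has {len(vals)} fields, expected {n_ch}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from None
    data = np.asarray(rows, dtype=float).T if rows else np.empty((n_ch, 0))
    events: list[tuple[int, str]] = []
    ev_path = _events_path(path)
    if ev_path.exists():
        for i, line in enumerate(ev_path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{ev_path}: line {i}: expected 'sample<TAB>tag'")
            events.append((int(parts[0]), parts[1].strip()))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if srate is None:
        srate = float(meta.get("srate", 0.0))
        if srate <= 0:
            raise FormatError(
                f"{path}: sampling rate unknown; pass srate= or provide a "
                ".meta.json sidecar"
            )
    try:
        pos = montage_positions(ch_names)
    except KeyError:
        pos = _disk_positions(n_ch)
    return EEGRecording(
        data=data, srate=srate, ch_names=ch_names, ch_pos=pos, events=events,
        subject_id=str(meta.get("subject_id", "")),
        group_tag=str(meta.get("group_tag", "")),
    )


def _disk_positions(n: int) -> np.ndarray:
    """Fallback positions: n points evenly spread on the unit disk."""
    golden = np.pi * (3 - np.sqrt(5))
    idx = np.arange(n)
    r = np.sqrt((idx + 0.5) / n)
    th = idx * golden
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _write_text(path: Path, rec: EEGRecording, delim: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delim.join(rec.ch_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=delim)
    if rec.events:
        with open(_events_path(path), "w") as fh:
            for s, t in rec.events:
                fh.write(f"{s}\t{t}\n")
    meta = {"srate": rec.srate, "subject_id": rec.subject_id, "group_tag": rec.group_tag}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    ch_names = list(raw.ch_names)
    try:
        pos = montage_positions(ch_names)
    except KeyError:
        pos = _disk_positions(len(ch_names))
    events: list[tuple[int, str]] = []
    for onset, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        events.append((int(round(onset * raw.info["sfreq"])), str(desc)))
    return EEGRecording(
        data=data, srate=float(raw.info["sfreq"]), ch_names=ch_names,
        ch_pos=pos, events=events,
    )


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a minimal EDF file (16-bit, one data record per second).

    The sampling rate must be an integer; the final partial second is
    zero-padded.  Quantisation error is bounded by the per-channel physical
    range divided by 2^16.
    """
    path = Path(path)
    srate = int(round(rec.srate))
    if abs(srate - rec.srate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / srate)) if rec.n_samples else 0
    padded = np.zeros((n_ch, n_rec * srate))
    padded[:, : rec.n_samples] = rec.data

    def fx(text: str, width: int) -> bytes:
        return f"{text:<{width}}"[:width].encode("ascii")

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(fx("0", 8))
        fh.write(fx(rec.subject_id or "X", 80))
        fh.write(fx("recording", 80))
        fh.write(fx("01.01.00", 8))
        fh.write(fx("00.00.00", 8))
        fh.write(fx(str(256 * (1 + n_ch)), 8))
        fh.write(fx("", 44))
        fh.write(fx(str(n_rec), 8))
        fh.write(fx("1", 8))
        fh.write(fx(str(n_ch), 4))
        for c in rec.ch_names:
            fh.write(fx(c, 16))
        for _ in range(n_ch):
            fh.write(fx("EEG", 80))
        for _ in range(n_ch):
            fh.write(fx("uV", 8))
        for v in pmin:
            fh.write(fx(f"{v:.6g}", 8))
        for v in pmax:
            fh.write(fx(f"{v:.6g}", 8))
        for _ in range(n_ch):
            fh.write(fx(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(fx(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(fx("", 80))
        for _ in range(n_ch):
            fh.write(fx(str(srate), 8))
        for _ in range(n_ch):
            fh.write(fx("", 32))
        scale = (dmax - dmin) / (pmax - pmin)
        for r in range(n_rec):
            block = padded[:, r * srate : (r + 1) * srate]
            dig = np.round((block - pmin[:, None]) * scale[:, None] + dmin)
            fh.write(dig.astype("<i2").tobytes())
    if rec.events:
        # EDF proper has no annotation stream; keep the sidecar convention.
        with open(_events_path(path), "w") as fh:
            for s, t in rec.events:
                fh.write(f"{s}\t{t}\n")


# ---------------------------------------------------------------------------
# Native format + public read/write
# ---------------------------------------------------------------------------

def _read_native(path: Path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        events = [(int(s), t) for s, t in zip(z["event_samples"], meta["event_tags"])]
        return EEGRecording(
            data=z["data"], srate=meta["srate"], ch_names=meta["ch_names"],
            ch_pos=z["ch_pos"], events=events,
            subject_id=meta["subject_id"], group_tag=meta["group_tag"],
        )


def _write_native(path: Path, rec: EEGRecording) -> None:
    meta = {
        "srate": rec.srate, "ch_names": rec.ch_names,
        "subject_id": rec.subject_id, "group_tag": rec.group_tag,
        "event_tags": [t for _s, t in rec.events],
    }
    np.savez(
        path, data=rec.data, ch_pos=rec.ch_pos,
        event_samples=np.array([s for s, _t in rec.events], dtype=int),
        meta=np.array(json.dumps(meta)),
    )


def read_recording(
    path: str | Path, format_hint: str | None = None, srate: float | None = None
) -> EEGRecording:
    """Read an EEG recording from EDF, delimited text, or native ``.npz``.

    ``format_hint`` is one of ``edf``, ``text``, ``native``; when omitted it
    is inferred from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        format_hint = {
            ".edf": "edf", ".npz": "native",
        }.get(path.suffix.lower(), "text")
    if format_hint == "edf":
        return _read_edf(path)
    if format_hint == "native":
        return _read_native(path)
    if format_hint == "text":
        return _read_text(path, srate)
    raise ValueError(f"unknown format hint {format_hint!r}")


def write_recording(
    path: str | Path, rec: EEGRecording, format_hint: str | None = None
) -> None:
    """Write a recording in the text, EDF, or native dialect."""
    path = Path(path)
    if format_hint is None:
        format_hint = {
            ".edf": "edf", ".npz": "native",
        }.get(path.suffix.lower(), "text")
    if format_hint == "edf":
        write_edf(path, rec)
    elif format_hint == "native":
        _write_native(path, rec)
    elif format_hint == "text":
        _write_text(path, rec)
    else:
        raise ValueError(f"unknown format hint {format_hint!r}")


# ---------------------------------------------------------------------------
# Condition epochs
# ---------------------------------------------------------------------------

def extract_condition_epochs(
    rec: EEGRecording, plan: str, block_s: float | None = None
) -> list[ConditionEpoch]:
    """Cut a marked recording into per-condition epochs.

    Each event marks the start of a block; a block runs to the next event (or
    to ``block_s`` seconds, if given, whichever is shorter; the last block
    runs to the end of the recording).  Under the ``AI`` plan the repeated
    one-minute blocks of each imagery/rest condition are concatenated into a
    single epoch per condition; under ``RA`` the rest and needling segments
    are returned.  Blocks are non-overlapping slices, so no sample lands in
    two epochs.
    """
    if plan not in ("AI", "RA"):
        raise ValueError("plan must be 'AI' or 'RA'")
    if not rec.events:
        raise ValueError("recording has no event markers")
    expected = AI_CONDITIONS if plan == "AI" else RA_CONDITIONS
    events = sorted(rec.events)
    starts = [s for s, _ in events]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("event markers must be strictly increasing")
    ends = starts[1:] + [rec.n_samples]
    if block_s is not None:
        blen = int(round(block_s * rec.srate))
        ends = [min(e, s + blen) for s, e in zip(starts, ends)]
    blocks: dict[str, list[np.ndarray]] = {}
    for (s, tag), e in zip(events, ends):
        blocks.setdefault(tag, []).append(rec.data[:, s:e])
    missing = [t for t in expected if t not in blocks]
    if missing:
        raise ValueError(f"missing condition markers: {missing}")
    return [
        ConditionEpoch(tag, np.concatenate(blocks[tag], axis=1), rec.srate)
        for tag in expected
    ]
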