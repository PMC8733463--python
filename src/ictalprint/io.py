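"""Recording / annotation containers and EDF + CSV input-output.

Signals travel as EDF (European Data Format, 16-bit integer encoding,
one data record per second) because EDF natively supports a different
sampling rate per signal — the EEG channels run at 207 Hz while the
accelerometer axes run at 10 or 20 Hz. Seizure labels deliberately do
NOT use EDF+ annotations; they live in a sidecar CSV so they stay
human-editable and diffable.

Channel naming convention: ``EEG_prox`` / ``EEG_dist`` are the two
bipolar subcutaneous EEG derivations (proximal / distal contact with
respect to the implant housing, microvolts), ``ACC_x`` / ``ACC_y`` /
``ACC_z`` are the trunk accelerometer axes in units of g. An alias map
lets files with other labels be read.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChannelSignal", "Recording", "SeizureAnnotation",
    "EDFFormatError", "PhysicalRangeError", "AnnotationError",
    "read_recording", "write_recording", "read_annotations", "write_annotations",
    "EEG_LABELS", "ACC_LABELS", "REQUIRED_LABELS", "DEFAULT_PHYSICAL_RANGE",
]

EEG_LABELS = ("EEG_prox", "EEG_dist")
ACC_LABELS = ("ACC_x", "ACC_y", "ACC_z")
REQUIRED_LABELS = EEG_LABELS + ACC_LABELS

#: default physical (full-scale) ranges per role; EDF encodes each sample
#: as a 16-bit integer across this range, so it also sets quantization.
DEFAULT_PHYSICAL_RANGE = {"eeg": 1000.0, "acc": 4.0}  # ±µV, ±g

DEFAULT_UNITS = {"eeg": "uV", "acc": "g"}

VALID_SEIZURE_LABELS = ("electrographic", "FBTCS")


class EDFFormatError(ValueError):
    """The file is not an EDF we can interpret (bad header, missing labels)."""


class PhysicalRangeError(ValueError):
    """A sample exceeds the configured physical range; refusing to clip."""


class AnnotationError(ValueError):
    """A seizure annotation violates the schema."""


@dataclass
class ChannelSignal:
    """One uniformly sampled signal of a recording."""

    label: str
    role: str               # "eeg" | "acc"
    fs: float               # samples / second
    samples: np.ndarray     # 1-D float array, physical units
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("eeg", "acc"):
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if not self.units:
            self.units = DEFAULT_UNITS[self.role]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Recording:
    """Multirate multichannel container for one person.

    Exactly two EEG channels (``EEG_prox``, ``EEG_dist``) and three
    accelerometer axes (``ACC_x``, ``ACC_y``, ``ACC_z``); all channels
    start together, durations may differ by less than one sample period
    of the slowest channel.
    """

    person_id: str
    channels: list[ChannelSignal]
    start_time: float = 0.0   # seconds; the analysis only uses relative time

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise EDFFormatError(f"duplicate channel labels: {labels}")
        eeg = [c for c in self.channels if c.role == "eeg"]
        acc = [c for c in self.channels if c.role == "acc"]
        if sorted(c.label for c in eeg) != sorted(EEG_LABELS) or len(eeg) != 2:
            raise EDFFormatError(
                f"need exactly EEG channels {EEG_LABELS}, got {[c.label for c in eeg]}"
            )
        if sorted(c.label for c in acc) != sorted(ACC_LABELS) or len(acc) != 3:
            raise EDFFormatError(
                f"need exactly acc channels {ACC_LABELS}, got {[c.label for c in acc]}"
            )
        slowest = min(c.fs for c in self.channels)
        durs = [c.duration_s for c in self.channels]
        if max(durs) - min(durs) >= 1.0 / slowest:
            raise EDFFormatError(
                f"channel durations differ by more than one slow-channel sample: {durs}"
            )

    def channel(self, label: str) -> ChannelSignal:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(f"no channel {label!r} in recording {self.person_id!r}")

    @property
    def duration_s(self) -> float:
        return min(c.duration_s for c in self.channels)


@dataclass(frozen=True)
class SeizureAnnotation:
    """A labeled seizure event on a recording's relative timeline."""

    person_id: str
    seizure_id: str
    onset_s: float
    duration_s: float
    label: str  # "electrographic" | "FBTCS"

    def __post_init__(self) -> None:
        if self.label not in VALID_SEIZURE_LABELS:
            raise AnnotationError(
                f"label {self.label!r} not in {VALID_SEIZURE_LABELS} "
                f"(seizure {self.seizure_id!r})"
            )
        if self.onset_s < 0:
            raise AnnotationError(f"negative onset {self.onset_s} for {self.seizure_id!r}")
        if self.duration_s <= 0:
            raise AnnotationError(f"non-positive duration {self.duration_s} for {self.seizure_id!r}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


# ---------------------------------------------------------------------------
# EDF codec. 16-bit EDF with a 1-second data record: every signal must have
# an integer number of samples per second (207, 20 and 10 Hz all qualify).
# ---------------------------------------------------------------------------

_ROLE_BY_PREFIX = {"EEG": "eeg", "ACC": "acc"}


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raise EDFFormatError(f"header field too long: {text!r} > {width} bytes")
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{value:g}", f"{value:.{max(0, width - 8)}g}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise EDFFormatError(f"cannot encode {value} in {width} ascii bytes")


def write_recording(
    rec: Recording,
    path: str | Path,
    physical_range: Mapping[str, float] | None = None,
) -> Path:
    """Write a :class:`Recording` as a 16-bit EDF file with 1-s records.

    ``physical_range`` maps role -> symmetric full-scale amplitude
    (defaults: EEG ±1000 µV, acc ±4 g). A sample outside the range
    raises :class:`PhysicalRangeError` rather than clipping silently.
    """
    rec.validate()
    ranges = dict(DEFAULT_PHYSICAL_RANGE)
    if physical_range:
        ranges.update(physical_range)
    path = Path(path)

    n_records = int(np.ceil(rec.duration_s - 1e-9))
    if n_records < 1:
        raise EDFFormatError("recording shorter than one 1-s data record")
    sig_meta = []
    for ch in rec.channels:
        spr = ch.fs
        if abs(spr - round(spr)) > 1e-9:
            raise EDFFormatError(
                f"channel {ch.label}: fs={ch.fs} has a non-integer number "
                "of samples per 1-s record"
            )
        spr = int(round(spr))
        pmax = ranges[ch.role]
        amax = float(np.max(np.abs(ch.samples))) if len(ch.samples) else 0.0
        if amax > pmax:
            raise PhysicalRangeError(
                f"channel {ch.label}: |sample| {amax:g} exceeds physical range ±{pmax:g}"
            )
        sig_meta.append((ch, spr, pmax))

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.person_id, 80)
    header += _pad(f"start_s={rec.start_time:g}", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    n_sig = len(rec.channels)
    header += _pad(str(256 * (1 + n_sig)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(n_sig), 4)

    fields: list[list[bytes]] = []
    fields.append([_pad(ch.label, 16) for ch, _, _ in sig_meta])
    fields.append([_pad("", 80)] * n_sig)
    fields.append([_pad(ch.units, 8) for ch, _, _ in sig_meta])
    fields.append([_num(-pmax, 8) for _, _, pmax in sig_meta])
    fields.append([_num(pmax, 8) for _, _, pmax in sig_meta])
    fields.append([_pad("-32768", 8)] * n_sig)
    fields.append([_pad("32767", 8)] * n_sig)
    fields.append([_pad("", 80)] * n_sig)
    fields.append([_pad(str(spr), 8) for _, spr, _ in sig_meta])
    fields.append([_pad("", 32)] * n_sig)
    for group in fields:
        for item in group:
            header += item

    # digital value d -> physical p = pmin + (d - dmin) * (pmax - pmin) / (dmax - dmin)
    digital: list[np.ndarray] = []
    for ch, spr, pmax in sig_meta:
        gain = 65535.0 / (2.0 * pmax)
        full = np.full(n_records * spr, 0, dtype=np.int16)
        d = np.rint((ch.samples + pmax) * gain - 32768.0)
        full[: len(d)] = np.clip(d, -32768, 32767).astype(np.int16)
        digital.append(full)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for (ch, spr, _), dig in zip(sig_meta, digital):
                fh.write(dig[r * spr : (r + 1) * spr].astype("<i2").tobytes())
    return path


def _read_exact(fh, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise EDFFormatError("truncated EDF header or record")
    return buf


def read_recording(
    path: str | Path,
    label_aliases: Mapping[str, str] | None = None,
) -> Recording:
    """Read an EDF file written by :func:`write_recording` (or compatible).

    ``label_aliases`` maps labels found in the file to the canonical
    channel names when a foreign file uses its own convention.
    """
    path = Path(path)
    aliases = dict(label_aliases or {})
    try:
        fh = open(path, "rb")
    except OSError as exc:
        raise IOError(f"cannot open EDF file {path}: {exc}") from exc
    with fh:
        _read_exact(fh, 8)                                   # version
        person_id = _read_exact(fh, 80).decode("ascii").strip()
        rec_field = _read_exact(fh, 80).decode("ascii").strip()
        _read_exact(fh, 16)                                  # date + time
        _read_exact(fh, 8)                                   # header bytes
        _read_exact(fh, 44)
        n_records = int(_read_exact(fh, 8).decode("ascii").strip())
        record_dur = float(_read_exact(fh, 8).decode("ascii").strip())
        n_sig = int(_read_exact(fh, 4).decode("ascii").strip())
        if n_records < 0 or record_dur <= 0 or n_sig <= 0:
            raise EDFFormatError(f"implausible EDF header in {path}")

        def grab(width: int, conv=str):
            return [conv(_read_exact(fh, width).decode("ascii").strip()) for _ in range(n_sig)]

        labels = grab(16)
        grab(80)                                             # transducer
        units = grab(8)
        pmins = grab(8, float)
        pmaxs = grab(8, float)
        dmins = grab(8, float)
        dmaxs = grab(8, float)
        grab(80)                                             # prefiltering
        sprs = grab(8, int)
        grab(32)

        labels = [aliases.get(lab, lab) for lab in labels]
        missing = [lab for lab in REQUIRED_LABELS if lab not in labels]
        if missing:
            raise EDFFormatError(
                f"{path}: missing required channel labels {missing}; "
                f"required: {list(REQUIRED_LABELS)}, found: {labels}"
            )

        raw = [np.empty(n_records * spr, dtype=np.int16) for spr in sprs]
        for r in range(n_records):
            for i, spr in enumerate(sprs):
                chunk = np.frombuffer(_read_exact(fh, 2 * spr), dtype="<i2")
                raw[i][r * spr : (r + 1) * spr] = chunk

    start_time = 0.0
    if rec_field.startswith("start_s="):
        try:
            start_time = float(rec_field.split("=", 1)[1])
        except ValueError:
            pass

    channels = []
    for i, lab in enumerate(labels):
        if lab not in REQUIRED_LABELS:
            continue
        role = _ROLE_BY_PREFIX[lab.split("_")[0]]
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        samples = pmins[i] + (raw[i].astype(float) - dmins[i]) * scale
        channels.append(
            ChannelSignal(label=lab, role=role, fs=sprs[i] / record_dur,
                          samples=samples, units=units[i])
        )
    order = {lab: k for k, lab in enumerate(REQUIRED_LABELS)}
    channels.sort(key=lambda c: order[c.label])
    return Recording(person_id=person_id, channels=channels, start_time=start_time)


# ---------------------------------------------------------------------------
# Annotation CSV (sidecar to the EDF)
# ---------------------------------------------------------------------------

_ANNOT_HEADER = ["person_id", "seizure_id", "onset_s", "duration_s", "label"]


def write_annotations(annos: Iterable[SeizureAnnotation], path: str | Path) -> Path:
    """Write annotations as CSV, rows sorted by (person_id, onset_s)."""
    path = Path(path)
    rows = sorted(annos, key=lambda a: (a.person_id, a.onset_s, a.seizure_id))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ANNOT_HEADER)
        for a in rows:
            w.writerow([a.person_id, a.seizure_id, f"{a.onset_s:g}", f"{a.duration_s:g}", a.label])
    return path


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read a seizure-annotation CSV; validates labels and numeric fields."""
    path = Path(path)
    out: list[SeizureAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _ANNOT_HEADER:
            raise AnnotationError(
                f"{path}: expected header {_ANNOT_HEADER}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                anno = SeizureAnnotation(
                    person_id=row["person_id"],
                    seizure_id=row["seizure_id"],
                    onset_s=float(row["onset_s"]),
                    duration_s=float(row["duration_s"]),
                    label=row["label"],
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, AnnotationError):
                    raise
                raise AnnotationError(f"{path}:{lineno}: bad numeric field ({exc})") from exc
            key = (anno.person_id, anno.seizure_id)
            if key in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate seizure id {key}")
            seen.add(key)
            out.append(anno)
    return out
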