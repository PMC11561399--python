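"""Reading and writing a well-defined subset of the FCS listmode format.

The at-line cytometer drops one FCS file per sample; the controller consumes
them and the simulator produces them through the same interface.  The dialect
written is FCS 3.1, one dataset per file, ``$DATATYPE F`` (single-precision
float), little-endian.  Reading additionally accepts ``$DATATYPE I`` with
linear amplification (``$PnE`` = 0,0) and either byte order.

Time is carried internally as decimal hours since feed start.  Acquisition
time is resolved with the precedence

    ``CYTOLOOP$THOURS`` custom keyword  >  ``$BTIM`` + ``$DATE``  >  file mtime

and the source actually used is recorded on the returned table so the audit
log can report it.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ChannelError, FormatError, IntegrityError, ValidationError

REQUIRED_CHANNELS = ("FSC-H", "SSC-H", "FL1-H", "FL3-H")

#: custom keywords carried in the TEXT segment
KW_DILUTION = "CYTOLOOP$DILUTION"
KW_SAMPLEID = "CYTOLOOP$SAMPLEID"
KW_THOURS = "CYTOLOOP$THOURS"

_DELIM = "/"
_HEADER_LEN = 58  # "FCS3.1    " + 8 offset fields of 8 chars


@dataclass
class EventTable:
    """Per-event channel intensities plus acquisition metadata for one sample.

    Attributes
    ----------
    sample_id : str
        Free-text identifier of the sample.
    acquired_at : float
        Acquisition time, decimal hours since feed start.
    dilution_factor : float
        Dilution applied before acquisition (e.g. 100 for 100x in PBS).
    channels : tuple of str
        Ordered channel names after mapping.
    events : ndarray, shape (n_events, n_channels)
        Non-negative finite intensities, one row per event.
    time_source : str
        Which clock supplied ``acquired_at``: ``keyword``, ``btim`` or
        ``mtime`` (``set`` when constructed in memory).
    """

    sample_id: str
    acquired_at: float
    dilution_factor: float
    channels: tuple
    events: np.ndarray
    time_source: str = "set"
    keywords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size == 0:
            self.events = self.events.reshape(0, len(self.channels))
        if self.events.ndim != 2 or self.events.shape[1] != len(self.channels):
            raise ValidationError(
                f"events matrix shape {self.events.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if self.dilution_factor <= 0:
            raise ValidationError("dilution_factor must be positive")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def column(self, channel: str) -> np.ndarray:
        """Return the intensity column for ``channel``.

        Raises
        ------
        ChannelError
            If the channel is not present.
        """
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise ChannelError(f"channel {channel!r} not present in sample "
                               f"{self.sample_id!r}") from None
        return self.events[:, idx]

    def require_channels(self, names: Sequence[str]) -> None:
        missing = [c for c in names if c not in self.channels]
        if missing:
            raise ChannelError(
                f"sample {self.sample_id!r} lacks required channel(s): "
                + ", ".join(missing)
            )


def _validate_finite(events: np.ndarray) -> None:
    if events.size and not np.all(np.isfinite(events)):
        raise ValidationError("event matrix contains non-finite intensities")
    if events.size and events.min() < 0:
        raise ValidationError("event matrix contains negative intensities")


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_fcs(table: EventTable, path: os.PathLike | str) -> Path:
    """Write ``table`` as a single-dataset FCS 3.1 listmode file.

    Data are stored as little-endian single-precision floats.  ``$BTIM`` and
    ``$DATE`` are derived from ``acquired_at`` (hours since feed start,
    folded onto a nominal clock), and the exact decimal-hour timestamp plus
    dilution factor travel in custom keywords so a round trip is lossless.

    Raises
    ------
    ValidationError
        If any intensity is non-finite or negative; nothing is written.
    """
    path = Path(path)
    _validate_finite(table.events)
    if len(table.channels) < 1:
        raise ValidationError("at least one channel is required")

    n_events, n_par = table.events.shape
    data = np.ascontiguousarray(table.events, dtype="<f4").tobytes()

    # nominal wall clock: fold decimal hours onto a 24 h dial for $BTIM
    hours = float(table.acquired_at)
    day = int(hours // 24)
    rem = hours - 24 * day
    hh = int(rem)
    mm = int((rem - hh) * 60)
    ss = ((rem - hh) * 60 - mm) * 60
    btim = f"{hh:02d}:{mm:02d}:{ss:06.3f}"
    date = f"{1 + day:02d}-JAN-2024"

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
        "$BTIM": btim,
        "$DATE": date,
        KW_DILUTION: repr(float(table.dilution_factor)),
        KW_SAMPLEID: table.sample_id,
        KW_THOURS: repr(float(table.acquired_at)),
    }
    for i, name in enumerate(table.channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = table.events[:, i - 1].max() if n_events else 0.0
        kw[f"$P{i}R"] = str(int(max(rng, 1)) + 1)

    # two-pass: compute TEXT length with placeholder offsets, then fill in
    def render(begin_data: int, end_data: int) -> bytes:
        full = dict(kw)
        full["$BEGINDATA"] = str(begin_data)
        full["$ENDDATA"] = str(end_data)
        parts = [_DELIM]
        for k, v in full.items():
            if _DELIM in k or _DELIM in str(v):
                raise ValidationError(
                    f"keyword {k!r}={v!r} contains the TEXT delimiter")
            parts.append(f"{k}{_DELIM}{v if str(v) else ' '}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(0, 0)
    text_start = _HEADER_LEN
    # offsets may grow the TEXT segment itself; iterate to a fixed point
    for _ in range(4):
        data_start = text_start + len(text)
        data_end = data_start + len(data) - 1 if data else 0
        new_text = render(data_start if data else 0, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:  # pragma: no cover - lengths stabilise in <=2 iterations
        raise IntegrityError("TEXT offset fixed point not reached")

    data_start = text_start + len(text)
    data_end = data_start + len(data) - 1 if data else 0
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_start + len(text) - 1:8d}".encode()
        + (f"{data_start:8d}".encode() if data else b"       0")
        + (f"{data_end:8d}".encode() if data else b"       0")
        + b"       0" + b"       0"
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

def _parse_text(raw: bytes) -> dict:
    if not raw:
        raise IntegrityError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    # NOTE: escaped (doubled) delimiters inside values are not supported —
    # the writer refuses to emit them and instrument exports do not use them.
    tokens = body.split(delim)
    if len(tokens) % 2:
        raise IntegrityError("TEXT segment has an odd number of tokens")
    return {tokens[i].strip().upper(): tokens[i + 1]
            for i in range(0, len(tokens), 2)}


def _read_segments(path: Path) -> tuple[dict, bytes]:
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_LEN)
        if len(header) < _HEADER_LEN or not header.startswith(b"FCS"):
            raise FormatError(f"{path} is not an FCS file")
        version = header[3:10].decode("latin-1").strip()
        if version not in ("3.0", "3.1", "2.0"):
            raise FormatError(f"unsupported FCS version {version!r}")

        def off(i: int) -> int:
            s = header[10 + 8 * i:18 + 8 * i].decode("latin-1").strip()
            return int(s) if s else 0

        text_start, text_end = off(0), off(1)
        data_start, data_end = off(2), off(3)
        fh.seek(text_start)
        text = fh.read(text_end - text_start + 1)
        kw = _parse_text(text)
        if data_start == 0:
            data_start = int(kw.get("$BEGINDATA", "0"))
            data_end = int(kw.get("$ENDDATA", "0"))
        if int(kw.get("$NEXTDATA", "0")) != 0:
            raise FormatError("multi-dataset FCS files are not supported")
        if data_end >= data_start > 0:
            fh.seek(data_start)
            data = fh.read(data_end - data_start + 1)
            if len(data) != data_end - data_start + 1:
                raise IntegrityError(f"{path}: truncated DATA segment")
        else:
            data = b""
    return kw, data


def _decode_events(kw: Mapping[str, str], data: bytes, path: Path) -> np.ndarray:
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")

    if datatype == "F":
        widths = [32] * n_par
        for i in range(1, n_par + 1):
            b = int(kw.get(f"$P{i}B", "32"))
            if b != 32:
                raise FormatError(f"$P{i}B={b} unsupported for $DATATYPE F")
        dtype = np.dtype(f"{endian}f4")
        expected = 4 * n_par * n_tot
        if len(data) < expected:
            raise IntegrityError(
                f"{path}: DATA holds {len(data)} bytes, need {expected}")
        arr = np.frombuffer(data[:expected], dtype=dtype)
    elif datatype == "I":
        widths = [int(kw.get(f"$P{i}B", "16")) for i in range(1, n_par + 1)]
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32):
            raise FormatError(f"unsupported $PnB widths {widths} for $DATATYPE I")
        for i in range(1, n_par + 1):
            amp = kw.get(f"$P{i}E", "0,0").replace(" ", "")
            if amp not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
                raise FormatError(
                    f"log-amplified integer data ($P{i}E={amp}) unsupported")
        dtype = np.dtype(f"{endian}u{widths[0] // 8}")
        expected = widths[0] // 8 * n_par * n_tot
        if len(data) < expected:
            raise IntegrityError(
                f"{path}: DATA holds {len(data)} bytes, need {expected}")
        arr = np.frombuffer(data[:expected], dtype=dtype)
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    return arr.astype(float).reshape(n_tot, n_par)


def _acquisition_hours(kw: Mapping[str, str], path: Path,
                       time_origin: float | None) -> tuple[float, str]:
    if KW_THOURS in kw:
        return float(kw[KW_THOURS]), "keyword"
    btim, date = kw.get("$BTIM"), kw.get("$DATE")
    if btim:
        parts = btim.split(":")
        h = int(parts[0]); m = int(parts[1]) if len(parts) > 1 else 0
        s = float(parts[2]) if len(parts) > 2 else 0.0
        hours = h + m / 60 + s / 3600
        if date:
            try:
                day = datetime.strptime(date.strip().upper(), "%d-%b-%Y").day
            except ValueError:
                try:
                    day = datetime.strptime(date.strip().upper(), "%d-%b-%y").day
                except ValueError:
                    day = 1
            hours += 24 * (day - 1)
        if time_origin is not None:
            hours -= time_origin
        return hours, "btim"
    mtime = os.path.getmtime(path)
    origin = time_origin if time_origin is not None else 0.0
    return (mtime - origin) / 3600.0, "mtime"


def read_fcs(path: os.PathLike | str,
             channel_map: Mapping[str, str] | None = None,
             time_origin: float | None = None) -> EventTable:
    """Read one FCS file into an :class:`EventTable`.

    Parameters
    ----------
    path : path-like
        FCS file to read.
    channel_map : mapping, optional
        Detector label -> canonical name (e.g. ``{"FL1-A": "FL1-H"}``);
        unmapped names pass through unchanged.
    time_origin : float, optional
        Clock origin used when the acquisition time must be derived from
        ``$BTIM``/``$DATE`` (origin in decimal hours on the same nominal
        dial) or from file mtime (origin as a POSIX timestamp).  Ignored
        when the lossless decimal-hour keyword is present.

    Raises
    ------
    ChannelError
        If any of FSC-H, SSC-H, FL1-H, FL3-H is absent after mapping.
    FormatError, IntegrityError
        Unsupported dialect / truncated data segment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kw, data = _read_segments(path)
    events = _decode_events(kw, data, path)

    n_par = int(kw["$PAR"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if channel_map:
        names = [channel_map.get(n, n) for n in names]

    acquired_at, source = _acquisition_hours(kw, path, time_origin)
    dilution = float(kw.get(KW_DILUTION, "1.0"))
    sample_id = kw.get(KW_SAMPLEID, path.stem)

    table = EventTable(
        sample_id=sample_id,
        acquired_at=acquired_at,
        dilution_factor=dilution,
        channels=tuple(names),
        events=events,
        time_source=source,
        keywords=dict(kw),
    )
    table.require_channels(REQUIRED_CHANNELS)
    return table


def read_fcs_metadata(path: os.PathLike | str,
                      time_origin: float | None = None) -> tuple[dict, float, str]:
    """Parse only the TEXT segment; returns (keywords, acquired_at, source)."""
    kw, _ = _read_segments(Path(path))
    hours, source = _acquisition_hours(kw, Path(path), time_origin)
    return kw, hours, source


def discover_new_samples(directory: os.PathLike | str,
                         already_seen: set | frozenset = frozenset(),
                         pattern: str = "*.fcs") -> list[Path]:
    """List unseen FCS files in ``directory``, oldest acquisition first.

    Files whose TEXT segment cannot be parsed still appear (sorted by mtime)
    so the caller can quarantine them; ties on acquisition time break on the
    file name, so repeated calls over a growing directory yield each file
    exactly once and in a stable order.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a readable directory: {directory}")
    seen = {Path(p).resolve() for p in already_seen}
    fresh = []
    for p in sorted(directory.glob(pattern)):
        if p.resolve() in seen:
            continue
        try:
            _, hours, _ = read_fcs_metadata(p)
        except Exception:
            hours = os.path.getmtime(p) / 3600.0
        fresh.append((hours, p.name, p))
    fresh.sort(key=lambda t: (t[0], t[1]))
    return [p for _, _, p in fresh]
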