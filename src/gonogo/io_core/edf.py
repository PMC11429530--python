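"""Minimal EDF+C writer/reader for continuous recordings.

Covers exactly what the pipeline needs: integer sampling rates, one data
record per second, 16-bit samples scaled to microvolts, and one
"EDF Annotations" signal carrying stimulus/response markers.

Annotation label convention (documented in the README):

* ``stim:<condition>:<block>`` — stimulus onset (condition "Go"/"NoGo")
* ``resp`` — button press

Onsets are written in seconds and mapped back to the nearest sample.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import FormatError, InvalidInputError
from ..montage import EOG_CHANNELS
from .containers import Recording

_ANNOT_LABEL = "EDF Annotations"
_ANNOT_SAMPLES = 512  # 1024 bytes of TAL capacity per 1 s record

_STIM_RE = re.compile(r"^stim:(?P<condition>[^:]+)(?::(?P<block>\d+))?$")


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise InvalidInputError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as EDF+C.

    Signal data are quantised to 16 bits over a per-channel symmetric
    physical range; events and responses become annotations.
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise InvalidInputError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_signals = len(recording.channel_names) + 1  # + annotations
    spr = [fs] * len(recording.channel_names) + [_ANNOT_SAMPLES]
    n_records = math.ceil(recording.n_samples / fs)

    data = recording.data
    if recording.n_samples < n_records * fs:  # zero-pad the final record
        pad = n_records * fs - recording.n_samples
        data = np.pad(data, ((0, 0), (0, pad)))

    # per-channel symmetric physical range, at least +/-1 uV
    pmax = np.maximum(np.ceil(np.max(np.abs(data), axis=1)), 1.0)
    pmin = -pmax
    scale = (pmax - pmin) / (32767.0 - (-32768.0))
    digital = np.clip(np.round((data - pmin[:, None]) / scale[:, None]) - 32768,
                      -32768, 32767).astype("<i2")

    # ---- annotations per record ----------------------------------------
    tals: list[list[bytes]] = [[] for _ in range(n_records)]
    for _, ev in recording.events.iterrows():
        t = ev["onset_sample"] / fs
        label = f"stim:{ev['condition']}:{int(ev.get('block', 0))}"
        tals[min(int(t), n_records - 1)].append(
            f"+{t:.6f}\x14{label}\x14\x00".encode("ascii"))
    for _, rp in recording.responses.iterrows():
        t = rp["press_sample"] / fs
        tals[min(int(t), n_records - 1)].append(
            f"+{t:.6f}\x14resp\x14\x00".encode("ascii"))

    # ---- header ---------------------------------------------------------
    header = bytearray()
    header += _pad_field("0", 8)
    header += _pad_field("X X X X", 80)                      # patient id
    header += _pad_field("Startdate X X X X", 80)            # recording id
    header += _pad_field("01.01.00", 8)
    header += _pad_field("00.00.00", 8)
    header += _pad_field(256 * (1 + n_signals), 8)
    header += _pad_field("EDF+C", 44)
    header += _pad_field(n_records, 8)
    header += _pad_field(1, 8)                               # record duration s
    header += _pad_field(n_signals, 4)

    labels = list(recording.channel_names) + [_ANNOT_LABEL]
    for lab in labels:
        header += _pad_field(lab, 16)
    for _ in labels:
        header += _pad_field("", 80)                         # transducer
    for i in range(n_signals):
        header += _pad_field("uV" if i < n_signals - 1 else "", 8)
    for i in range(n_signals):
        header += _pad_field(f"{pmin[i]:.1f}" if i < n_signals - 1 else -1, 8)
    for i in range(n_signals):
        header += _pad_field(f"{pmax[i]:.1f}" if i < n_signals - 1 else 1, 8)
    for i in range(n_signals):
        header += _pad_field(-32768, 8)
    for i in range(n_signals):
        header += _pad_field(32767, 8)
    for _ in labels:
        header += _pad_field("", 80)                         # prefiltering
    for n in spr:
        header += _pad_field(n, 8)
    for _ in labels:
        header += _pad_field("", 32)                         # reserved

    # ---- data records ---------------------------------------------------
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for ch in range(len(recording.channel_names)):
                fh.write(digital[ch, r * fs:(r + 1) * fs].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii") + b"".join(tals[r])
            if len(tal) > 2 * _ANNOT_SAMPLES:
                raise InvalidInputError(f"too many annotations in record {r}")
            fh.write(tal.ljust(2 * _ANNOT_SAMPLES, b"\x00"))
    return path


def _read_fields(raw: bytes, offset: int, width: int, n: int) -> list[str]:
    return [raw[offset + i * width: offset + (i + 1) * width].decode("ascii").strip()
            for i in range(n)]


def read_edf(path: str | Path, require_eog: bool = True) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (data in microvolts).

    Raises :class:`FormatError` when the file declares fewer than 20
    channels or (with ``require_eog``) lacks the four EOG labels.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_dur = float(raw[244:252].decode("ascii").strip())
        n_signals = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header ({exc})") from None

    off = 256
    labels = _read_fields(raw, off, 16, n_signals); off += 16 * n_signals
    off += 80 * n_signals  # transducer
    off += 8 * n_signals   # physical dimension
    pmin = [float(x) for x in _read_fields(raw, off, 8, n_signals)]; off += 8 * n_signals
    pmax = [float(x) for x in _read_fields(raw, off, 8, n_signals)]; off += 8 * n_signals
    dmin = [float(x) for x in _read_fields(raw, off, 8, n_signals)]; off += 8 * n_signals
    dmax = [float(x) for x in _read_fields(raw, off, 8, n_signals)]; off += 8 * n_signals
    off += 80 * n_signals  # prefiltering
    spr = [int(x) for x in _read_fields(raw, off, 8, n_signals)]; off += 8 * n_signals
    off += 32 * n_signals  # reserved
    header_bytes = 256 * (1 + n_signals)

    annot_idx = [i for i, lab in enumerate(labels) if lab == _ANNOT_LABEL]
    sig_idx = [i for i in range(n_signals) if i not in annot_idx]

    if len(sig_idx) < 20:
        raise FormatError(f"{path}: expected >= 20 data channels, found {len(sig_idx)}")
    channel_names = [labels[i] for i in sig_idx]
    if require_eog:
        absent = [c for c in EOG_CHANNELS if c not in channel_names]
        if absent:
            raise FormatError(f"{path}: missing EOG channels {absent}")

    rec_len = sum(spr)
    body = np.frombuffer(raw[header_bytes:], dtype="<i2")
    if len(body) < n_records * rec_len:
        raise FormatError(f"{path}: truncated data records")
    body = body[: n_records * rec_len].reshape(n_records, rec_len)
    starts = np.concatenate([[0], np.cumsum(spr)])

    fs_candidates = {spr[i] / record_dur for i in sig_idx}
    if len(fs_candidates) != 1:
        raise FormatError(f"{path}: mixed sampling rates are not supported")
    fs = fs_candidates.pop()

    data = np.empty((len(sig_idx), n_records * spr[sig_idx[0]]))
    for row, i in enumerate(sig_idx):
        dig = body[:, starts[i]: starts[i + 1]].reshape(-1).astype(float)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[row] = (dig - dmin[i]) * scale + pmin[i]

    events, responses = [], []
    for i in annot_idx:
        stream = body[:, starts[i]: starts[i + 1]].astype("<i2").tobytes()
        for tal in stream.split(b"\x00"):
            if not tal:
                continue
            parts = tal.split(b"\x14")
            try:
                onset = float(parts[0].replace(b"\x15", b"."))
            except ValueError:
                continue
            for label in parts[1:]:
                text = label.decode("ascii", "ignore")
                m = _STIM_RE.match(text)
                if m:
                    events.append((int(round(onset * fs)), m["condition"],
                                   int(m["block"] or 0)))
                elif text == "resp":
                    responses.append(int(round(onset * fs)))

    events_df = pd.DataFrame(sorted(events), columns=["onset_sample", "condition", "block"])
    responses_df = pd.DataFrame({"press_sample": sorted(responses)})
    return Recording(data=data, fs=fs, channel_names=channel_names,
                     events=events_df, responses=responses_df)
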