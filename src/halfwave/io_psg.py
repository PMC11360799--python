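"""Loader for MIT-BIH Polysomnographic ("slpdb") records and stage labels.

Implements the minimal subset of the WFDB physiological-signal layout that
the slpdb records use: a text header (``.hea``), a 16-bit two's-complement
little-endian interleaved signal file (``.dat``, format 16) and a binary MIT
annotation file (``.st``) carrying one sleep-stage symbol per 30-s epoch in
the annotation's aux string.  A fixture writer emits the same layout so
round-trip fidelity is testable offline; nothing here downloads data.

This module is a leaf: no other module in the package imports it.  Everything
else works from in-memory epochs and labels.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import Epoch
from .reduction import Signal

__all__ = [
    "STAGE_SYMBOLS",
    "PsgRecord",
    "load_record",
    "write_record",
    "epochs_with_labels",
]

logger = logging.getLogger(__name__)

#: annotation aux symbol -> class label
STAGE_SYMBOLS = {
    "1": "S1",
    "2": "S2",
    "3": "S3",
    "4": "S4",
    "W": "W",
    "R": "R",
    "M": "M",
    "MT": "M",
}

#: class label -> canonical annotation aux symbol written to .st files
LABEL_TO_SYMBOL = {
    "S1": "1", "S2": "2", "S3": "3", "S4": "4", "W": "W", "R": "R", "M": "MT",
}

_NOTE = 22  # annotation type code used for stage comments
_SKIP = 59  # long-interval escape
_AUX = 63  # aux-string escape


@dataclass(frozen=True)
class PsgRecord:
    """A single-EEG-channel polysomnographic record with stage annotations.

    ``stage_annotations`` is an ordered sequence of
    ``(epoch_start_sample, label)`` pairs with labels from
    {S1, S2, S3, S4, W, R, M}.
    """

    record_id: str
    eeg: Signal
    stage_annotations: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        anns = tuple((int(t), str(s)) for t, s in self.stage_annotations)
        times = [t for t, _ in anns]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stage annotations must be strictly ordered in time")
        object.__setattr__(self, "stage_annotations", anns)


# --------------------------------------------------------------------------
# header


def _parse_header(path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_id = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    channels = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fmt = tok[1]
        if "x" in fmt:
            base, factor = fmt.split("x")
            if int(factor) != 1:
                raise ValueError(
                    f"channel {tok[-1]!r} declares {factor} samples per frame; "
                    "rate mismatches are an error, not silently resampled"
                )
            fmt = base
        gain_spec = tok[2] if len(tok) > 2 else "200"
        units = ""
        if "/" in gain_spec:
            gain_spec, units = gain_spec.split("/", 1)
        baseline = 0
        if "(" in gain_spec:
            gain_spec, rest = gain_spec.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_spec) if gain_spec else 200.0
        channels.append(
            {
                "file": tok[0],
                "fmt": int(fmt),
                "gain": gain if gain != 0 else 200.0,
                "baseline": baseline,
                "units": units,
                "description": " ".join(tok[8:]) if len(tok) > 8 else "",
            }
        )
    return record_id, nsig, fs, nsamp, channels


# --------------------------------------------------------------------------
# annotations (MIT format)


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    pending_time: int | None = None
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            (long_iv,) = struct.unpack("<i", data[i : i + 4])
            i += 4
            t += long_iv
            pending_time = None
            continue
        if code == _AUX:
            aux = data[i : i + interval].decode("ascii", errors="replace")
            i += interval + (interval & 1)  # pad byte on odd length
            if pending_time is not None:
                symbol = aux.split()[0] if aux.split() else ""
                label = STAGE_SYMBOLS.get(symbol)
                if label is None:
                    warnings.warn(
                        f"unrecognized stage symbol {symbol!r} at sample "
                        f"{pending_time}; annotation skipped"
                    )
                else:
                    out.append((pending_time, label))
                pending_time = None
            continue
        t += interval
        pending_time = t
    return out


def _write_annotations(path: Path, anns: list[tuple[int, str]]) -> None:
    buf = bytearray()
    prev = 0
    for t, label in anns:
        delta = t - prev
        prev = t
        if delta > 0x3FF:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<i", delta)
            delta = 0
        buf += struct.pack("<H", (_NOTE << 10) | delta)
        aux = LABEL_TO_SYMBOL.get(label, label).encode("ascii")
        buf += struct.pack("<H", (_AUX << 10) | len(aux))
        buf += aux
        if len(aux) & 1:
            buf += b"\x00"
    buf += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(buf))


# --------------------------------------------------------------------------
# public API


def load_record(path_or_id: str | Path) -> PsgRecord:
    """Read a WFDB-layout record (``<base>.hea/.dat/.st``) from disk.

    The single EEG channel is selected by header description; a record
    without one is a format error.  No downloading: missing files raise
    FileNotFoundError naming the missing extension.
    """
    base = Path(path_or_id)
    for ext in (".hea", ".dat", ".st"):
        if not base.with_suffix(ext).exists():
            raise FileNotFoundError(
                f"record {base.name!r}: missing {ext} file at {base.with_suffix(ext)}"
            )
    record_id, nsig, fs, nsamp, channels = _parse_header(base.with_suffix(".hea"))

    eeg_idx = next(
        (i for i, ch in enumerate(channels) if "EEG" in ch["description"].upper()),
        None,
    )
    if eeg_idx is None:
        raise ValueError(
            f"record {base.name!r}: no channel with an EEG description in header"
        )
    ch = channels[eeg_idx]
    if ch["fmt"] != 16:
        raise ValueError(f"unsupported WFDB signal format {ch['fmt']} (only 16)")

    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    if nsig > 1:
        raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)[:, eeg_idx]
    samples = (raw.astype(float) - ch["baseline"]) / ch["gain"]
    if nsamp and samples.size != nsamp:
        raise ValueError(
            f"record {base.name!r}: header declares {nsamp} samples but "
            f"{samples.size} were read"
        )
    anns = _read_annotations(base.with_suffix(".st"))
    return PsgRecord(
        record_id=record_id,
        eeg=Signal(samples, fs=fs),
        stage_annotations=tuple(anns),
    )


def write_record(base: str | Path, record: PsgRecord, gain: float = 200.0) -> None:
    """Fixture writer: emit ``<base>.hea/.dat/.st`` in the layout load_record reads.

    Samples are quantized at the given ADC gain (units per physical unit), so
    round-trips are lossless for samples that are integer multiples of 1/gain
    within the int16 range.
    """
    base = Path(base)
    sig = record.eeg
    adc = np.round(sig.samples * gain).astype("<i2")
    fs = sig.fs
    fs_txt = f"{fs:g}"
    header = (
        f"{base.name} 1 {fs_txt} {adc.size}\n"
        f"{base.name}.dat 16 {gain:g}(0)/uV 16 0 {int(adc[0])} 0 0 EEG\n"
    )
    base.with_suffix(".hea").write_text(header)
    adc.tofile(base.with_suffix(".dat"))
    _write_annotations(base.with_suffix(".st"), list(record.stage_annotations))


def epochs_with_labels(
    rec: PsgRecord, epoch_seconds: float = 30.0
) -> list[Epoch]:
    """Labelled 30-s epochs aligned to the record's annotation boundaries.

    Annotations whose window runs past the end of the signal are dropped
    (count logged).  Records annotated at a faster cadence than
    ``epoch_seconds`` (e.g. 20-s scoring) are rejected.
    """
    width_f = rec.eeg.fs * epoch_seconds
    width = int(round(width_f))
    if width <= 0 or abs(width_f - width) > 1e-9:
        raise ValueError("fs * epoch_seconds must be a positive integer")
    starts = [t for t, _ in rec.stage_annotations]
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    if gaps and min(gaps) < width:
        raise ValueError(
            f"record {rec.record_id!r} is annotated every {min(gaps)} samples "
            f"(< {width}); the pipeline is wired for {epoch_seconds:g}-s epochs"
        )
    epochs: list[Epoch] = []
    dropped = 0
    n = len(rec.eeg)
    for start, label in rec.stage_annotations:
        if start + width <= n:
            epochs.append(
                Epoch(
                    Signal(rec.eeg.samples[start : start + width],
                           fs=rec.eeg.fs, t0=start),
                    label=label,
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.info(
            "record %s: dropped %d annotation(s) whose epoch runs past the signal",
            rec.record_id, dropped,
        )
    return epochs
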