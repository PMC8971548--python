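"""Compact WFDB codec: text headers, format 16/212 signals, MIT annotations.

Covers the subset of the WFDB specification needed to read MIT-BIH style
records (multi-lead, format 212, gain/baseline in the header) and to write
records that standard WFDB tooling can read back: one ``.hea`` text header,
one ``.dat`` signal file shared by all leads, and one ``.atr`` annotation
file in the MIT binary annotation format.

Amplitudes cross this boundary in ADC units; conversion to physical units
(mV) happens in :mod:`beatbox.io_formats` using the per-lead gain/baseline
returned here.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SignalSpec",
    "RecordHeader",
    "read_header",
    "read_signal",
    "write_record",
    "read_annotations",
    "write_annotations",
    "SYMBOL_TO_CODE",
    "CODE_TO_SYMBOL",
    "BEAT_CODES",
]


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float  # ADC units per mV
    baseline: int  # ADC value corresponding to 0 mV
    adc_res: int
    adc_zero: int
    init_value: int
    checksum: int
    block_size: int
    description: str  # lead name, e.g. "MLII"


@dataclass
class RecordHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalSpec] = field(default_factory=list)


# -- header ------------------------------------------------------------

def read_header(path: str | Path) -> RecordHeader:
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0

    signals: list[SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        file_name = toks[0]
        fmt = int(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(toks) > 2:
            g = toks[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_res = int(toks[3]) if len(toks) > 3 else 12
        adc_zero = int(toks[4]) if len(toks) > 4 else 0
        init_value = int(toks[5]) if len(toks) > 5 else adc_zero
        checksum = int(toks[6]) if len(toks) > 6 else 0
        block_size = int(toks[7]) if len(toks) > 7 else 0
        description = " ".join(toks[8:]) if len(toks) > 8 else f"sig{len(signals)}"
        if baseline is None:
            baseline = adc_zero
        signals.append(
            SignalSpec(
                file_name, fmt, gain, baseline, adc_res, adc_zero,
                init_value, checksum, block_size, description,
            )
        )
    return RecordHeader(record_name, n_sig, fs, n_samples, signals)


# -- signal data -------------------------------------------------------

def _read_fmt16(raw: bytes, n_sig: int) -> np.ndarray:
    flat = np.frombuffer(raw, dtype="<i2")
    usable = (len(flat) // n_sig) * n_sig
    return flat[:usable].reshape(-1, n_sig).astype(np.int32)


def _read_fmt212(raw: bytes, n_sig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    usable = (len(b) // 3) * 3
    b = b[:usable].reshape(-1, 3).astype(np.int32)
    # two 12-bit samples packed in 3 bytes
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(2 * len(b), dtype=np.int32)
    flat[0::2] = s0
    flat[1::2] = s1
    usable = (len(flat) // n_sig) * n_sig
    return flat[:usable].reshape(-1, n_sig)


def read_signal(header: RecordHeader, directory: str | Path) -> np.ndarray:
    """Return raw ADC samples with shape (n_samples, n_sig)."""
    directory = Path(directory)
    file_names = {s.file_name for s in header.signals}
    if len(file_names) != 1:
        raise NotImplementedError("multi-file WFDB records are not supported")
    fmt = header.signals[0].fmt
    raw = (directory / header.signals[0].file_name).read_bytes()
    if fmt == 16:
        adc = _read_fmt16(raw, header.n_sig)
    elif fmt == 212:
        adc = _read_fmt212(raw, header.n_sig)
    else:
        raise NotImplementedError(f"signal format {fmt} not supported")
    if header.n_samples:
        adc = adc[: header.n_samples]
    return adc


def write_record(
    directory: str | Path,
    record_name: str,
    adc: np.ndarray,
    fs: float,
    lead_names: list[str],
    gain: float = 200.0,
    baseline: int = 0,
    fmt: int = 16,
) -> Path:
    """Write ``record_name.hea`` + ``record_name.dat`` (format 16).

    ``adc`` is integer ADC samples, shape (n_samples, n_sig).
    Returns the header path.
    """
    if fmt != 16:
        raise NotImplementedError("writing supports format 16 only")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.asarray(adc)
    if adc.ndim == 1:
        adc = adc[:, None]
    if adc.shape[1] != len(lead_names):
        raise ValueError("lead_names length must match signal columns")
    adc16 = adc.astype("<i2")
    dat = directory / f"{record_name}.dat"
    dat.write_bytes(adc16.tobytes())

    n_samples, n_sig = adc.shape
    lines = [f"{record_name} {n_sig} {fs:g} {n_samples}"]
    for j, name in enumerate(lead_names):
        checksum = int(np.sum(adc[:, j], dtype=np.int64) & 0xFFFF)
        if checksum >= 0x8000:
            checksum -= 0x10000
        init = int(adc[0, j]) if n_samples else 0
        lines.append(
            f"{record_name}.dat 16 {gain:g}({baseline})/mV 16 "
            f"{baseline} {init} {checksum} 0 {name}"
        )
    hea = directory / f"{record_name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


# -- annotations -------------------------------------------------------

# WFDB annotation codes (the subset relevant to beat typing).
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}

#: codes that denote a heartbeat (as opposed to rhythm/quality marks)
BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41}
)

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class AnnotationParseError(ValueError):
    pass


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file → ordered (sample, symbol) pairs."""
    raw = Path(path).read_bytes()
    if len(raw) % 2:
        raw = raw[:-1]
    words = np.frombuffer(raw, dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(words)
    while i < n:
        w = int(words[i])
        code = w >> 10
        delta = w & 0x3FF
        i += 1
        if code == 0 and delta == 0:  # end of file
            break
        if code == _SKIP:
            if i + 1 >= n:
                raise AnnotationParseError(f"truncated SKIP at word {i}")
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 2
        elif code == _AUX:
            i += (delta + 1) // 2  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifier bytes: irrelevant to beat typing
        else:
            t += delta
            out.append((t, CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_annotations(path: str | Path, anns: list[tuple[int, str]]) -> None:
    """Write (sample, symbol) pairs as an MIT-format annotation file."""
    buf = bytearray()
    prev = 0
    for sample, symbol in anns:
        code = SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no WFDB annotation code for symbol {symbol!r}")
        dt = sample - prev
        if dt < 0:
            raise ValueError("annotations must be in ascending sample order")
        if dt > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        buf += struct.pack("<H", (code << 10) | dt)
        prev = sample
    buf += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(buf))
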