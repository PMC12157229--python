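"""Trace and event I/O: CSV (canonical interchange) and 16-bit EDF.

Unit convention throughout: time in seconds, amplitudes in mV, currents in
mA.  CSV round trips are bit-exact (floats serialised with %.17g).  EDF
stores 16-bit digital samples scaled over a symmetric physical range, so a
round trip is lossless only up to ``physical_range / 2**16`` — the standard
clinical-container trade-off.  Stimulation-event annotations travel in a
separate events CSV; the EDF container carries samples only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import MesTrace, StimEvent
from .stim_engine import PulseSchedule

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "read_events_csv",
    "write_trace_edf",
    "read_trace_edf",
]

_FLOAT_FMT = "%.17g"


def write_trace_csv(path: str | Path, trace: MesTrace) -> None:
    """Columns ``time_s, ch1_mV, ch2_mV, ...``; floats round-trip exactly."""
    cols = {"time_s": trace.times}
    for ch in range(trace.n_channels):
        cols[f"ch{ch + 1}_mV"] = trace.samples[ch]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(path: str | Path) -> MesTrace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"cannot parse trace CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    ch_cols = [c for c in df.columns if c.startswith("ch") and c.endswith("_mV")]
    if not ch_cols:
        raise ValueError(f"{path}: no channel columns (chN_mV) found")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs")
    fs = 1.0 / float(np.median(np.diff(t)))
    # snap to an integer rate when the time column quantisation suggests one
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    samples = np.vstack([df[c].to_numpy() for c in sorted(ch_cols)])
    return MesTrace(samples, fs=fs, t0=float(t[0]))


def write_events_csv(path: str | Path, events) -> None:
    """Events CSV: ``time_s, channel, current_mA`` (accepts a PulseSchedule
    or a list of StimEvent)."""
    if isinstance(events, PulseSchedule):
        rows = [(e.time_s, e.channel, e.amplitude_ma) for e in events.events]
    else:
        rows = [(e.time_s, e.channel, e.current_ma) for e in events]
    pd.DataFrame(rows, columns=["time_s", "channel", "current_mA"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path: str | Path) -> list[StimEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "channel", "current_mA"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return [StimEvent(float(r.time_s), int(r.channel), float(r.current_mA))
            for r in df.itertuples()]


# --- minimal EDF (European Data Format) container ---------------------------
# Fixed 256-byte main header + 256 bytes per signal, then data records of
# little-endian int16.  Written with mV as the physical dimension.

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int) -> str:
    for prec in range(width, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s
    return f"{x:.0f}"[:width]


def write_trace_edf(path: str | Path, trace: MesTrace,
                    patient_id: str = "X", recording_id: str = "mecfes") -> None:
    """Write samples as plain EDF, one signal per channel, dimension mV.

    If ``fs`` is integer and the length divides into whole seconds the file
    uses 1 s records; otherwise a single record spanning the whole trace.
    Quantisation: 16-bit over a symmetric physical range just above the
    per-file absolute maximum.
    """
    x = trace.samples
    n_ch, n = x.shape
    fs_int = int(round(trace.fs))
    if abs(trace.fs - fs_int) < 1e-9 and n % fs_int == 0:
        n_records, samp_per_rec, rec_dur = n // fs_int, fs_int, 1.0
    else:
        n_records, samp_per_rec, rec_dur = 1, n, n / trace.fs
    pmax = max(float(np.abs(x).max()), 1e-6) * (1 + 1e-9)
    dmin, dmax = -32768, 32767
    scale = (2 * pmax) / (dmax - dmin)
    digital = np.clip(np.round((x + pmax) / scale) + dmin, dmin, dmax).astype("<i2")

    hdr = b""
    hdr += _ascii("0", 8)
    hdr += _ascii(patient_id, 80)
    hdr += _ascii(recording_id, 80)
    hdr += _ascii("01.01.00", 8)   # start date (synthetic data: epoch placeholder)
    hdr += _ascii("00.00.00", 8)
    hdr += _ascii(256 + n_ch * 256, 8)
    hdr += _ascii("", 44)
    hdr += _ascii(n_records, 8)
    hdr += _ascii(_fmt_float(rec_dur, 8), 8)
    hdr += _ascii(n_ch, 4)
    for ch in range(n_ch):
        hdr += _ascii(f"ch{ch + 1}", 16)
    hdr += b"".join(_ascii("synthetic MES", 80) for _ in range(n_ch))
    hdr += b"".join(_ascii("mV", 8) for _ in range(n_ch))
    hdr += b"".join(_ascii(_fmt_float(-pmax, 8), 8) for _ in range(n_ch))
    hdr += b"".join(_ascii(_fmt_float(pmax, 8), 8) for _ in range(n_ch))
    hdr += b"".join(_ascii(dmin, 8) for _ in range(n_ch))
    hdr += b"".join(_ascii(dmax, 8) for _ in range(n_ch))
    hdr += b"".join(_ascii("", 80) for _ in range(n_ch))
    hdr += b"".join(_ascii(samp_per_rec, 8) for _ in range(n_ch))
    hdr += b"".join(_ascii("", 32) for _ in range(n_ch))
    assert len(hdr) == 256 + n_ch * 256

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            sl = slice(rec * samp_per_rec, (rec + 1) * samp_per_rec)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())


def read_trace_edf(path: str | Path) -> MesTrace:
    """Read a plain EDF file written by :func:`write_trace_edf` (or any
    single-rate, annotation-free EDF)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii"))
        rec_dur = float(head[244:252].decode("ascii"))
        n_ch = int(head[252:256].decode("ascii"))
        sig = fh.read(n_ch * 256)
        if len(sig) < n_ch * 256:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(n_ch)]

        pmin = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmax = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmin = [int(v) for v in fields(16 + 80 + 8 + 8 + 8, 8)]
        dmax = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
        spr = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: mixed per-signal rates not supported")
        data = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * n_ch * spr[0]
    if data.size < expected:
        raise ValueError(f"{path}: expected {expected} samples, found {data.size}")
    data = data[:expected].reshape(n_records, n_ch, spr[0])
    samples = np.concatenate([data[:, ch, :].reshape(-1)[None, :] for ch in range(n_ch)], axis=0).astype(float)
    for ch in range(n_ch):
        scale = (pmax[ch] - pmin[ch]) / (dmax[ch] - dmin[ch])
        samples[ch] = (samples[ch] - dmin[ch]) * scale + pmin[ch]
    fs = spr[0] / rec_dur
    return MesTrace(samples, fs=fs, t0=0.0)
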