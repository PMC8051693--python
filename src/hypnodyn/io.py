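"""Readers/writers and epoch/sample alignment.

Hypnograms are stored as plain text, one state label per line, with
'#'-prefixed header lines carrying metadata (``epoch_s``, ``t0``).
Signals are read from CSV (columns frontal, occipital[, emg]) or from
.npy/.npz arrays; the sampling rate comes from an ``fs`` header/field or
an explicit argument. EDF is not supported in this build (no EDF library
available); requesting it raises with a clear message.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import EEGSession, Hypnogram, State, parse_state

__all__ = [
    "read_hypnogram",
    "write_hypnogram",
    "read_signals",
    "write_signals",
    "downsample",
    "epoch_windows",
    "read_config",
    "write_config",
]


def read_hypnogram(path, epoch_s: Optional[float] = None) -> Hypnogram:
    """Read a one-label-per-line hypnogram file.

    ``#``-prefixed lines are header/comments; a header of the form
    ``# epoch_s = 5`` (or ``# t0 = 0``) sets metadata. An explicit
    ``epoch_s`` argument overrides the header. Unrecognised state tokens
    are an error naming the offending line.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"hypnogram file not found: {path}")
    labels = []
    header = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip().lower()] = v.strip()
                continue
            try:
                labels.append(parse_state(line))
            except ValueError:
                raise ValueError(
                    f"{path}: unrecognized state token {line!r} on line {lineno}"
                ) from None
    if not labels:
        raise ValueError(f"{path}: empty hypnogram file")
    if epoch_s is None:
        epoch_s = float(header.get("epoch_s", 5.0))
    t0 = float(header.get("t0", 0.0))
    return Hypnogram(labels=tuple(labels), epoch_s=epoch_s, t0=t0)


def write_hypnogram(h: Hypnogram, path) -> None:
    """Write a hypnogram as text, one label per line plus metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# epoch_s = {h.epoch_s:g}\n")
        fh.write(f"# t0 = {h.t0:g}\n")
        for lab in h.labels:
            fh.write(f"{lab.value}\n")


_CHANNEL_ORDER = ("frontal", "occipital", "emg")


def read_signals(path, format: Optional[str] = None, fs: Optional[float] = None,
                 subject_id: str = "", condition: str = "") -> EEGSession:
    """Read an EEG session from CSV or .npy/.npz.

    CSV: a ``# fs = <Hz>`` header line or an ``fs`` argument supplies the
    sampling rate; columns are frontal, occipital[, emg] (named header row
    optional). ``.npz``: arrays ``frontal``, ``occipital``[, ``emg``] and a
    scalar ``fs``. ``.npy``: (n_channels, n_samples) array, channel order as
    above, ``fs`` argument required.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = {".csv": "csv", ".npy": "npy", ".npz": "npz", ".edf": "edf"}.get(
            ext, "csv")
    format = format.lower()
    if format == "edf":
        raise NotImplementedError(
            "EDF input is not supported in this build (no EDF reader library "
            "available); export channels to CSV or .npz instead"
        )
    if format == "npz":
        dat = np.load(path)
        if "frontal" not in dat or "occipital" not in dat:
            raise ValueError(f"{path}: need at least 'frontal' and 'occipital' arrays")
        fs_val = float(dat["fs"]) if "fs" in dat else fs
        if fs_val is None:
            raise ValueError(f"{path}: sampling rate missing (no 'fs' field)")
        return EEGSession(
            frontal=dat["frontal"], occipital=dat["occipital"],
            emg=dat["emg"] if "emg" in dat else None,
            fs=fs_val, subject_id=subject_id, condition=condition,
        )
    if format == "npy":
        arr = np.atleast_2d(np.load(path))
        if arr.shape[0] < 2:
            raise ValueError(f"{path}: need >= 2 channels (frontal, occipital)")
        if fs is None:
            raise ValueError("fs argument required for .npy input")
        return EEGSession(
            frontal=arr[0], occipital=arr[1],
            emg=arr[2] if arr.shape[0] > 2 else None,
            fs=fs, subject_id=subject_id, condition=condition,
        )
    if format == "csv":
        header_fs = None
        rows = []
        colnames = None
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if "=" in body:
                        k, v = body.split("=", 1)
                        if k.strip().lower() == "fs":
                            header_fs = float(v)
                    continue
                parts = [p.strip() for p in line.split(",")]
                if colnames is None and any(
                        p.lower() in _CHANNEL_ORDER for p in parts):
                    colnames = [p.lower() for p in parts]
                    continue
                rows.append([float(p) for p in parts])
        if not rows:
            raise ValueError(f"{path}: no samples found")
        arr = np.asarray(rows, dtype=float)
        if arr.shape[1] < 2:
            raise ValueError(f"{path}: need >= 2 channels (frontal, occipital)")
        if colnames is not None:
            order = [colnames.index(c) for c in _CHANNEL_ORDER if c in colnames]
            arr = arr[:, order]
        fs_val = fs if fs is not None else header_fs
        if fs_val is None:
            raise ValueError(f"{path}: sampling rate missing (no '# fs =' header)")
        return EEGSession(
            frontal=arr[:, 0], occipital=arr[:, 1],
            emg=arr[:, 2] if arr.shape[1] > 2 else None,
            fs=fs_val, subject_id=subject_id, condition=condition,
        )
    raise ValueError(f"unknown signal format: {format!r}")


def write_signals(session: EEGSession, path) -> None:
    """Write a session to .npz (arrays + fs); the lossless inverse of read."""
    payload = {
        "frontal": session.frontal, "occipital": session.occipital,
        "fs": session.fs,
    }
    if session.emg is not None:
        payload["emg"] = session.emg
    np.savez(path, **payload)


def downsample(session: EEGSession, fs_out: float) -> EEGSession:
    """Resample all channels to ``fs_out`` with anti-aliased polyphase filtering.

    ``fs_out`` must be positive and no greater than the current rate;
    ``fs_out == fs`` is the identity.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out > session.fs:
        raise ValueError(
            f"cannot upsample: fs_out={fs_out} > fs={session.fs}")
    if fs_out == session.fs:
        return session
    from fractions import Fraction

    frac = Fraction(fs_out / session.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator

    def _res(x):
        return sps.resample_poly(x, up, down)

    return EEGSession(
        frontal=_res(session.frontal),
        occipital=_res(session.occipital),
        emg=_res(session.emg) if session.emg is not None else None,
        fs=fs_out,
        subject_id=session.subject_id,
        condition=session.condition,
    )


def epoch_windows(session: EEGSession, h: Hypnogram,
                  mask: Optional[Sequence[bool]] = None):
    """Cut the session into non-overlapping per-epoch windows.

    Epoch k covers samples [k*epoch_s*fs, (k+1)*epoch_s*fs) — a 0-based
    half-open partition. Yields ``(epoch_index, state, {channel: segment})``
    for every retained epoch (mask True, default all) that fits entirely
    within the signal.

    Raises if session and hypnogram are misaligned by >= 1 epoch, or if the
    mask is longer than the hypnogram.
    """
    session.check_alignment(h)
    if mask is None:
        mask = np.ones(len(h), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(h):
        raise ValueError(
            f"mask length {len(mask)} != hypnogram length {len(h)}")
    spe = int(round(h.epoch_s * session.fs))  # samples per epoch
    out = []
    chans = session.channels()
    for k in range(len(h)):
        if not mask[k]:
            continue
        lo, hi = k * spe, (k + 1) * spe
        if hi > session.n_samples:
            break  # last partial epoch dropped
        out.append((k, h.labels[k], {name: x[lo:hi] for name, x in chans.items()}))
    return out


def read_config(path) -> dict:
    """Read a flat ``key = value`` text config; '#' comments allowed."""
    cfg = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line or "=" not in line:
                continue
            k, v = line.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
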