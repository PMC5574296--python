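"""Minimal RIFF/AVI reader and writer for uncompressed 24-bit video.

Frames are stored as bottom-up BGR device-independent bitmaps (the classic
``DIB`` fourcc, ``biCompression = 0``), which makes the container lossless:
a written frame reads back bit-identically.  Only this one pixel format is
supported; compressed AVI streams raise :class:`~polypscan.exceptions.DecodeError`.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .exceptions import DecodeError, EmptyInputError

__all__ = ["read_avi", "write_avi"]


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    if len(payload) % 2:
        payload += b"\x00"  # RIFF chunks are word-aligned
    return fourcc + struct.pack("<I", len(payload)) + payload


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def _encode_frame(frame: np.ndarray, row_size: int) -> bytes:
    h, w, _ = frame.shape
    bgr = frame[::-1, :, ::-1]  # bottom-up rows, BGR order
    rows = np.zeros((h, row_size), dtype=np.uint8)
    rows[:, : 3 * w] = bgr.reshape(h, 3 * w)
    return rows.tobytes()


def write_avi(path, frames, fps: int = 25) -> None:
    """Write ``frames`` (uniform H×W×3 uint8 arrays) as an uncompressed AVI."""
    frames = [np.asarray(f, dtype=np.uint8) for f in frames]
    if not frames:
        raise EmptyInputError("cannot write an AVI with zero frames")
    h, w, c = frames[0].shape
    if c != 3 or any(f.shape != (h, w, 3) for f in frames):
        raise ValueError("all frames must share one H x W x 3 shape")

    row_size = (3 * w + 3) // 4 * 4
    frame_bytes = row_size * h
    n = len(frames)

    avih = struct.pack(
        "<14I",
        1_000_000 // fps,  # microseconds per frame
        frame_bytes * fps,  # max bytes per second
        0,
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2HI5I2I4h",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, n,
        frame_bytes, 0, 0, 0, 0, w, h,
    )
    strf = struct.pack("<I2i2H6I", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

    movi_items = [_chunk(b"00db", _encode_frame(f, row_size)) for f in frames]
    movi = _list(b"movi", b"".join(movi_items))

    # idx1: one entry per frame, offsets relative to the start of 'movi'
    idx_entries = []
    offset = 4
    for item in movi_items:
        idx_entries.append(struct.pack("<4s3I", b"00db", 0x10, offset, len(item) - 8))
        offset += len(item)
    idx1 = _chunk(b"idx1", b"".join(idx_entries))

    hdrl = _list(b"hdrl", _chunk(b"avih", avih) + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)))
    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> list[np.ndarray]:
    """Read an uncompressed 24-bit AVI into a list of H×W×3 uint8 arrays."""
    path = Path(path)
    try:
        buf = path.read_bytes()
    except OSError as exc:
        raise DecodeError(f"cannot read AVI file {path}: {exc}") from exc
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise DecodeError(f"{path} is not a RIFF/AVI container")

    width = height = bitcount = compression = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"strf" and size >= 40:
                _, width, height, _, bitcount, compression = struct.unpack_from("<I2i2HI", buf, data_pos)
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(buf[data_pos : data_pos + size])

    walk(12, len(buf))

    if width is None:
        raise DecodeError(f"{path}: no video stream format (strf) found")
    if compression != 0 or bitcount != 24:
        raise DecodeError(f"{path}: only uncompressed 24-bit AVI is supported (biCompression={compression}, biBitCount={bitcount})")
    if not frames:
        raise EmptyInputError(f"{path}: AVI contains no frames")

    row_size = (3 * width + 3) // 4 * 4
    out = []
    for raw in frames:
        if len(raw) < row_size * abs(height):
            raise DecodeError(f"{path}: truncated frame chunk")
        rows = np.frombuffer(raw, dtype=np.uint8, count=row_size * abs(height)).reshape(abs(height), row_size)
        bgr = rows[:, : 3 * width].reshape(abs(height), width, 3)
        rgb = bgr[::-1, :, ::-1] if height > 0 else bgr[:, :, ::-1]
        out.append(np.ascontiguousarray(rgb))
    return out
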