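"""Minimal uncompressed AVI (RIFF) reader and writer.

Only raw DIB video streams are supported: 8-bit palettized frames (written
with a grayscale palette) and 24-bit BGR frames. Anything with a non-zero
``biCompression`` is rejected -- compressed codecs are out of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, FormatError

_AVIF_HASINDEX = 0x10
_AVIIF_KEYFRAME = 0x10


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (n, h, w) uint8 as an uncompressed 8-bit AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, h, w) array")
    if frames.shape[0] == 0:
        raise EmptyInputError("refusing to write an AVI with zero frames")
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = frames.astype(np.uint8, copy=False)
    n, h, w = frames.shape
    row_bytes = (w + 3) & ~3
    frame_bytes = row_bytes * h

    scale = 1000
    rate = int(round(fps * scale))
    usec_per_frame = int(round(1_000_000 / fps))

    avih = struct.pack(
        "<14I",
        usec_per_frame,
        frame_bytes * int(round(fps)),
        0,
        _AVIF_HASINDEX,
        n,
        0,
        1,
        frame_bytes,
        w,
        h,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIII4h",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        scale, rate,
        0, n,
        frame_bytes, 0, 0,
        0, 0, w, h,
    )
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 0)
    palette = bytes(b for v in range(256) for b in (v, v, v, 0))
    strl = _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", bmih + palette))
    hdrl = _list(b"hdrl", _chunk(b"avih", avih) + strl)

    pad_cols = row_bytes - w
    movi_payload = bytearray()
    index = bytearray()
    for frame in frames:
        rows = frame[::-1]  # DIB scanlines are bottom-up
        if pad_cols:
            rows = np.pad(rows, ((0, 0), (0, pad_cols)))
        data = rows.tobytes()
        # idx1 offsets are relative to the 'movi' fourcc
        index += struct.pack(
            "<4sIII", b"00db", _AVIIF_KEYFRAME, 4 + len(movi_payload), len(data)
        )
        movi_payload += _chunk(b"00db", data)
    movi = _list(b"movi", bytes(movi_payload))
    idx1 = _chunk(b"idx1", bytes(index))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        body = pos + 8
        yield fourcc, body, min(body + size, end)
        pos = body + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns ``(frames (n, h, w) uint8, fps)``.

    8-bit palettized streams are mapped through their palette (luma for
    colour palettes); 24-bit BGR streams are converted to grayscale by the
    caller if requested -- here they are returned as (n, h, w, 3) RGB.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise FormatError(f"not a RIFF/AVI file: {path}")

    fps = None
    width = height = None
    bitcount = None
    palette = None
    stream_index = -1
    vids_stream = None
    frame_blobs: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal fps, width, height, bitcount, palette, stream_index, vids_stream
        for fourcc, body, body_end in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(body + 4, body_end)
            elif fourcc == b"strh":
                stream_index += 1
                fcc_type = buf[body:body + 4]
                if fcc_type == b"vids" and vids_stream is None:
                    vids_stream = stream_index
                    scale, rate = struct.unpack_from("<II", buf, body + 20)
                    if scale > 0 and rate > 0:
                        fps = rate / scale
            elif fourcc == b"strf" and stream_index == vids_stream and bitcount is None:
                (_, w, h, _, bc, compression) = struct.unpack_from(
                    "<IiiHHI", buf, body
                )
                if compression != 0:
                    raise FormatError(
                        f"compressed AVI stream (biCompression={compression}) "
                        f"is not supported: {path}"
                    )
                width, height, bitcount = w, h, bc
                if bc == 8:
                    n_colors = max((body_end - body - 40) // 4, 0)
                    pal = np.frombuffer(
                        buf, np.uint8, count=n_colors * 4, offset=body + 40
                    ).reshape(-1, 4)
                    palette = pal[:, :3][:, ::-1]  # stored BGR0
            elif vids_stream is not None and fourcc in (
                f"{vids_stream:02d}db".encode(),
                f"{vids_stream:02d}dc".encode(),
            ):
                frame_blobs.append(buf[body:body_end])

    walk(12, len(buf))

    if bitcount is None or width is None:
        raise FormatError(f"no uncompressed video stream found in {path}")
    if not frame_blobs:
        raise EmptyInputError(f"AVI contains zero frames: {path}")
    if fps is None:
        raise FormatError(f"AVI stream missing frame-rate metadata: {path}")

    h = abs(height)
    bottom_up = height > 0
    if bitcount == 8:
        row_bytes = (width + 3) & ~3
        frames = np.empty((len(frame_blobs), h, width), np.uint8)
        for i, blob in enumerate(frame_blobs):
            rows = np.frombuffer(blob, np.uint8, count=row_bytes * h)
            rows = rows.reshape(h, row_bytes)[:, :width]
            frames[i] = rows[::-1] if bottom_up else rows
        if palette is not None and len(palette) >= 256:
            if np.all(palette[:, 0] == palette[:, 1]) and np.all(
                palette[:, 1] == palette[:, 2]
            ):
                lut = palette[:, 0]
            else:
                lut = np.round(
                    0.299 * palette[:, 0]
                    + 0.587 * palette[:, 1]
                    + 0.114 * palette[:, 2]
                ).astype(np.uint8)
            frames = lut[frames]
        return frames, float(fps)
    if bitcount == 24:
        row_bytes = (width * 3 + 3) & ~3
        frames = np.empty((len(frame_blobs), h, width, 3), np.uint8)
        for i, blob in enumerate(frame_blobs):
            rows = np.frombuffer(blob, np.uint8, count=row_bytes * h)
            rows = rows.reshape(h, row_bytes)[:, : width * 3].reshape(h, width, 3)
            rows = rows[:, :, ::-1]  # BGR -> RGB
            frames[i] = rows[::-1] if bottom_up else rows
        return frames, float(fps)
    raise FormatError(f"unsupported AVI bit depth {bitcount}: {path}")
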