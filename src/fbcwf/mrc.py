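"""Minimal MRC2014 reader/writer for particle stacks (mode 2, float32).

Implements the subset of the MRC2014 specification needed for square image
stacks: a 1024-byte header with the 'MAP ' format tag and little-endian
machine stamp, followed by the raw frame data.  The pixel size is stored
in and recovered from the CELLA fields.
"""

from __future__ import annotations

import numpy as np

HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


class MRCFormatError(IOError):
    pass


def write_mrc(path, data: np.ndarray, pixel_size_A: float = 1.0) -> None:
    """Write an (N, L, L) or (L, L) float stack as an MRC2014 file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[-1] != data.shape[-2]:
        raise ValueError("expected an (N, L, L) stack of square frames")
    nz, ny, nx = data.shape

    hdr_i = np.zeros(256, dtype="<i4")
    hdr_f = hdr_i.view("<f4")
    hdr_i[0:3] = (nx, ny, nz)
    hdr_i[3] = _MODE_FLOAT32
    hdr_i[7:10] = (nx, ny, nz)                     # mx, my, mz
    hdr_f[10:13] = (nx * pixel_size_A, ny * pixel_size_A, nz * pixel_size_A)
    hdr_f[13:16] = (90.0, 90.0, 90.0)              # cell angles
    hdr_i[16:19] = (1, 2, 3)                       # axis order
    hdr_f[19] = float(data.min())
    hdr_f[20] = float(data.max())
    hdr_f[21] = float(data.mean())
    hdr_i[22] = 0                                  # ispg: image stack
    hdr_i[52] = int.from_bytes(b"MAP ", "little")
    hdr_i[53] = int.from_bytes(bytes([0x44, 0x44, 0x00, 0x00]), "little")
    hdr_f[54] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(hdr_i.tobytes())
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path):
    """Read an MRC2014 stack; returns (data (N, L, L) float32, pixel_size)."""
    with open(path, "rb") as fh:
        raw = fh.read(HEADER_BYTES)
        if len(raw) < HEADER_BYTES:
            raise MRCFormatError(f"{path}: truncated header "
                                 f"({len(raw)} of {HEADER_BYTES} bytes)")
        hdr_i = np.frombuffer(raw, dtype="<i4")
        hdr_f = hdr_i.view("<f4")
        if hdr_i[52].tobytes() != b"MAP ":
            raise MRCFormatError(f"{path}: missing MRC2014 'MAP ' tag")
        nx, ny, nz = (int(v) for v in hdr_i[0:3])
        mode = int(hdr_i[3])
        if mode != _MODE_FLOAT32:
            raise MRCFormatError(f"{path}: unsupported MRC mode {mode} "
                                 "(only float32 mode 2 is handled)")
        if nx != ny:
            raise MRCFormatError(f"{path}: frames are {ny} x {nx}, not square")
        nsymbt = int(hdr_i[23])
        fh.seek(HEADER_BYTES + nsymbt)
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * 4), dtype="<f4")
        if data.size != count:
            raise MRCFormatError(
                f"{path}: truncated data ({data.size} of {count} values)")
    pixel = float(hdr_f[10]) / nx if nx else 1.0
    return data.reshape(nz, ny, nx).copy(), pixel
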