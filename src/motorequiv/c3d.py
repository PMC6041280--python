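"""Minimal C3D reader/writer for 3D point data.

C3D is the binary interchange format of optoelectronic motion-capture
systems.  This module implements the subset needed to exchange labelled
marker trajectories: Intel (little-endian) byte order, 3D points stored as
float or scaled integer, the POINT parameter group (USED, FRAMES, RATE,
SCALE, DATA_START, LABELS, UNITS).  Analog channels and multi-section
parameter exotica are out of scope; files that need them are rejected
rather than misread.

Layout (512-byte blocks):
  block 1      -- binary header; words hold point count, frame range,
                  scale factor, data start block and frame rate
  block 2..    -- parameter section: group/parameter records
  DATA_START.. -- frames x points x (x, y, z, residual); a negative
                  residual marks an invalid (occluded) sample
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np

from .exceptions import DataError, FormatError
from .io import Recording

__all__ = ["read_c3d", "write_c3d"]

_BLOCK = 512
_PROC_INTEL = 84  # 83 + 1


def _pad_block(buf: bytearray) -> None:
    if len(buf) % _BLOCK:
        buf.extend(b"\x00" * (_BLOCK - len(buf) % _BLOCK))


def _param_record(name: str, group_id: int, dtype: int,
                  dims: list[int], payload: bytes) -> bytes:
    body = struct.pack("<bB", dtype, len(dims))
    body += bytes(dims)
    body += payload
    body += struct.pack("<B", 0)  # empty description
    rec = struct.pack("<bb", len(name), group_id) + name.encode("ascii")
    rec += struct.pack("<h", 2 + len(body))  # offset to next record
    rec += body
    return rec


def _group_record(name: str, group_id: int) -> bytes:
    rec = struct.pack("<bb", len(name), -group_id) + name.encode("ascii")
    rec += struct.pack("<h", 3)  # offset: desc-len byte + empty desc
    rec += struct.pack("<B", 0)
    return rec


def write_c3d(recording: Recording, path: str | Path, units: str = "mm") -> Path:
    """Write a recording as a float-storage C3D file.

    ``units`` controls the POINT:UNITS metadata *and* the stored numbers:
    with ``units='m'`` positions are written in meters so that the file is
    unit-consistent.
    """
    if not recording.markers:
        raise FormatError("refusing to write a recording with no markers")
    if units not in ("mm", "m", "cm"):
        raise FormatError(f"unsupported units {units!r}")
    factor = {"mm": 1.0, "cm": 0.1, "m": 0.001}[units]
    names = list(recording.markers)
    npts = len(names)
    nframes = recording.n_samples

    # --- parameter section (block 2..) ---
    params = bytearray()
    params += struct.pack("<BBBB", 1, 80, 0, _PROC_INTEL)  # block count patched below
    params += _group_record("POINT", 1)
    params += _param_record("USED", 1, 2, [], struct.pack("<h", npts))
    params += _param_record("FRAMES", 1, 2, [], struct.pack("<h", nframes))
    params += _param_record("SCALE", 1, 4, [], struct.pack("<f", -1.0))
    params += _param_record("RATE", 1, 4, [], struct.pack("<f", recording.sample_rate))
    maxlen = max(len(n) for n in names)
    label_block = b"".join(n.ljust(maxlen).encode("ascii") for n in names)
    params += _param_record("LABELS", 1, -1, [maxlen, npts], label_block)
    params += _param_record("UNITS", 1, -1, [len(units)], units.encode("ascii"))
    # still to append: the DATA_START record (19 bytes) and terminator (4 bytes)
    n_param_blocks = (len(params) + 19 + 4 + _BLOCK - 1) // _BLOCK
    data_start_block = 2 + n_param_blocks
    params += _param_record("DATA_START", 1, 2, [], struct.pack("<h", data_start_block))
    # terminator: zero name length, zero group, zero offset
    params += struct.pack("<bbh", 0, 0, 0)
    params[2] = n_param_blocks
    _pad_block(params)
    assert len(params) == n_param_blocks * _BLOCK

    # --- header (block 1) ---
    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 80)  # parameter block pointer, magic
    struct.pack_into("<h", header, 2, npts)
    struct.pack_into("<h", header, 4, 0)  # analog per frame
    struct.pack_into("<h", header, 6, 1)  # first frame
    struct.pack_into("<h", header, 8, nframes)
    struct.pack_into("<h", header, 10, 0)  # max gap
    struct.pack_into("<f", header, 12, -1.0)  # scale (negative: float data)
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, recording.sample_rate)

    # --- data section ---
    frames = np.empty((nframes, npts, 4), dtype="<f4")
    for j, name in enumerate(names):
        frames[:, j, :3] = recording.markers[name] * factor
        frames[:, j, 3] = 0.0
    data = bytearray(frames.tobytes())
    _pad_block(data)

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(params)
        fh.write(data)
    return path


def _read_params(raw: bytes, start: int) -> dict[str, object]:
    """Parse POINT group parameters from the parameter section."""
    proc = raw[start + 3]
    if proc != _PROC_INTEL:
        raise FormatError(f"unsupported C3D processor type {proc} (Intel only)")
    pos = start + 4
    group_ids: dict[int, str] = {}
    entries: list[tuple[int, str, int, list[int], bytes]] = []
    while pos < len(raw):
        nchar = struct.unpack_from("<b", raw, pos)[0]
        gid = struct.unpack_from("<b", raw, pos + 1)[0]
        if nchar == 0:
            break
        name = raw[pos + 2: pos + 2 + abs(nchar)].decode("ascii", "replace")
        offset_pos = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", raw, offset_pos)[0]
        body = offset_pos + 2
        if gid < 0:  # group definition
            group_ids[-gid] = name.upper()
        else:  # parameter
            dtype = struct.unpack_from("<b", raw, body)[0]
            ndims = raw[body + 1]
            dims = list(raw[body + 2: body + 2 + ndims])
            size = {-1: 1, 1: 1, 2: 2, 4: 4}[dtype]
            count = int(np.prod(dims)) if dims else 1
            payload = raw[body + 2 + ndims: body + 2 + ndims + size * count]
            entries.append((gid, name.upper(), dtype, dims, payload))
        if offset <= 0:
            break
        pos = offset_pos + offset
    point: dict[str, object] = {}
    for gid, name, dtype, dims, payload in entries:
        if group_ids.get(gid) != "POINT":
            continue
        if dtype == 4:
            vals = np.frombuffer(payload, dtype="<f4").astype(float)
            point[name] = vals if len(vals) > 1 else float(vals[0])
        elif dtype == 2:
            vals = np.frombuffer(payload, dtype="<i2").astype(int)
            point[name] = vals if len(vals) > 1 else int(vals[0])
        elif dtype == -1:
            if len(dims) == 2:
                ml, cnt = dims
                point[name] = [
                    payload[i * ml:(i + 1) * ml].decode("ascii", "replace").strip()
                    for i in range(cnt)
                ]
            else:
                point[name] = payload.decode("ascii", "replace").strip()
    return point


def read_c3d(
    path: str | Path,
    participant_id: str = "unknown",
    tool: str | None = None,
    effector: str | None = None,
    endpoint_marker: str | None = None,
) -> Recording:
    """Read 3D point data from a C3D file into a :class:`Recording`.

    Positions are converted to mm regardless of the file's POINT:UNITS.
    Samples with a negative residual (occluded / invalid) raise
    :class:`DataError` listing the affected frames.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 2 * _BLOCK:
        raise FormatError(f"{path}: truncated C3D file")
    param_block, magic = raw[0], raw[1]
    if magic != 80:
        raise FormatError(f"{path}: not a C3D file (magic byte {magic})")
    npts = struct.unpack_from("<h", raw, 2)[0]
    first_frame = struct.unpack_from("<h", raw, 6)[0]
    last_frame = struct.unpack_from("<h", raw, 8)[0]
    hdr_scale = struct.unpack_from("<f", raw, 12)[0]
    hdr_data_start = struct.unpack_from("<h", raw, 16)[0]
    hdr_rate = struct.unpack_from("<f", raw, 20)[0]

    point = _read_params(raw, (param_block - 1) * _BLOCK)
    n_used = int(point.get("USED", npts))
    rate = float(point.get("RATE", hdr_rate))
    scale = float(point.get("SCALE", hdr_scale))
    data_start = int(point.get("DATA_START", hdr_data_start))
    nframes = int(point.get("FRAMES", last_frame - first_frame + 1))
    units = point.get("UNITS", "mm")
    if isinstance(units, list):
        units = units[0] if units else "mm"
    labels = point.get("LABELS")
    if not isinstance(labels, list) or len(labels) < n_used or not all(
        lab for lab in labels[:n_used]
    ):
        warnings.warn(
            f"{path}: markers unlabeled; using synthetic names marker_1..{n_used}",
            stacklevel=2,
        )
        labels = [f"marker_{i + 1}" for i in range(n_used)]

    offset = (data_start - 1) * _BLOCK
    if scale < 0:  # float storage
        need = nframes * n_used * 4 * 4
        vals = np.frombuffer(raw, dtype="<f4", count=nframes * n_used * 4,
                             offset=offset).reshape(nframes, n_used, 4)
        coords = vals[:, :, :3].astype(float)
        residuals = vals[:, :, 3].astype(float)
    else:  # integer storage, coordinates scaled
        need = nframes * n_used * 4 * 2
        vals = np.frombuffer(raw, dtype="<i2", count=nframes * n_used * 4,
                             offset=offset).reshape(nframes, n_used, 4)
        coords = vals[:, :, :3].astype(float) * scale
        residuals = vals[:, :, 3].astype(float)
    if len(raw) < offset + need:
        raise FormatError(f"{path}: data section shorter than declared")

    bad = np.argwhere(residuals < 0)
    if bad.size:
        frames_bad = sorted({int(f) + first_frame for f, _ in bad})
        raise DataError(
            f"{path}: {len(frames_bad)} frame(s) with occluded/invalid samples: "
            f"{frames_bad[:20]}{'...' if len(frames_bad) > 20 else ''}"
        )

    unit_factor = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(str(units).lower())
    if unit_factor is None:
        raise FormatError(f"{path}: unsupported POINT:UNITS {units!r}")
    markers = {
        labels[j]: coords[:, j, :] * unit_factor for j in range(n_used)
    }
    return Recording(
        participant_id=participant_id,
        tool=tool,
        effector=effector,
        sample_rate=rate,
        markers=markers,
        endpoint_marker=endpoint_marker,
    )
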