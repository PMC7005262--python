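"""Minimal MRC2014 volume I/O (mode 2, little-endian float32).

Self-contained on purpose: the pipeline only ever needs mode-2 cubic/cuboid
scalar grids with a voxel size and an origin, and keeping the reader in-repo
avoids an external format dependency. Axis convention: arrays are indexed
``[z, y, x]``; the header's NX/NY/NZ are the fastest-to-slowest axes (x, y,
z), matching the MRC2014 column/row/section layout.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_BYTES = 1024
_MAP_ID = b"MAP "


class MrcFormatError(ValueError):
    """Malformed or unsupported MRC file; the message names the bad field."""


def write_mrc(path, grid: np.ndarray, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D array as MRC2014 mode 2.

    ``grid`` is indexed [z, y, x]; ``voxel_size`` in Angstrom; ``origin`` is
    the (x, y, z) position of the first voxel's centre in Angstrom.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise MrcFormatError(f"grid must be 3D, got shape {grid.shape}")
    if voxel_size <= 0:
        raise MrcFormatError(f"voxel_size must be > 0, got {voxel_size}")
    data = np.ascontiguousarray(grid, dtype="<f4")
    nz, ny, nx = data.shape
    ox, oy, oz = (float(v) for v in origin)

    header = bytearray(HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)        # NX NY NZ
    struct.pack_into("<i", header, 12, 2)                 # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)          # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)       # MX MY MZ
    cella = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", header, 40, *cella)           # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)          # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76,
        float(data.min()), float(data.max()), float(data.mean()),
    )
    struct.pack_into("<i", header, 92, 0)                 # ISPG
    struct.pack_into("<i", header, 96, 0)                 # NSYMBT
    struct.pack_into("<3f", header, 196, ox, oy, oz)      # ORIGIN
    header[208:212] = _MAP_ID
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])     # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)                # NLABL

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path):
    """Read an MRC2014 mode-2 file -> (grid [z,y,x] float32, voxel_size, origin).

    Raises :class:`MrcFormatError` naming the offending header field for
    anything malformed, truncated or not mode 2.
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MrcFormatError("header: file shorter than the 1024-byte MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode = struct.unpack_from("<i", header, 12)[0]
        if min(nx, ny, nz) <= 0:
            raise MrcFormatError(f"NX/NY/NZ: non-positive dimensions ({nx}, {ny}, {nz})")
        if mode != 2:
            raise MrcFormatError(f"MODE: only mode 2 (float32) supported, got {mode}")
        if header[208:212] != _MAP_ID:
            raise MrcFormatError("MAP: missing 'MAP ' format identifier at word 53")
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        if mx <= 0:
            raise MrcFormatError(f"MX: non-positive grid sampling ({mx})")
        voxel_size = cella_x / mx
        if voxel_size <= 0:
            raise MrcFormatError(f"CELLA: non-positive voxel size ({voxel_size})")
        nsymbt = struct.unpack_from("<i", header, 96)[0]
        origin = struct.unpack_from("<3f", header, 196)
        if nsymbt:
            fh.read(nsymbt)
        count = nx * ny * nz
        raw = fh.read(count * 4)
        if len(raw) < count * 4:
            raise MrcFormatError(
                f"data: expected {count} float32 voxels, file truncated at {len(raw) // 4}"
            )
        grid = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx).copy()
    return grid, float(voxel_size), tuple(float(v) for v in origin)
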