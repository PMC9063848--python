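"""Independent minimal MRC2014 writer used as an oracle for core_io.

Deliberately written from the byte layout of the format (struct packing,
not gemmi), so tests of axis-order normalization and origin precedence do
not share code with the implementation under test.
"""

from __future__ import annotations

import struct

import numpy as np

_MODE_DTYPE = {0: "<i1", 1: "<i2", 2: "<f4"}


def write_mrc(
    path,
    data_zyx: np.ndarray,
    voxel=(1.0, 1.0, 1.0),
    mapcrs=(1, 2, 3),
    nstart=(0, 0, 0),
    origin=(0.0, 0.0, 0.0),
    mode=2,
) -> None:
    """Write ``data_zyx`` (logical z,y,x order) with arbitrary storage axes.

    ``mapcrs`` gives the crystal axis (1=x, 2=y, 3=z) stored as columns,
    rows and sections; ``nstart``/``origin`` are in x,y,z order.
    """
    nz, ny, nx = data_zyx.shape
    n_xyz = (nx, ny, nz)
    vx, vy, vz = voxel
    ax = [mapcrs[0] - 1, mapcrs[1] - 1, mapcrs[2] - 1]  # xyz index of col/row/sec
    a_xyz = np.transpose(data_zyx, (2, 1, 0))
    store = np.transpose(a_xyz, (ax[2], ax[1], ax[0]))  # (sections, rows, cols)
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, n_xyz[ax[0]], n_xyz[ax[1]], n_xyz[ax[2]])
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, nstart[ax[0]], nstart[ax[1]], nstart[ax[2]])
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vx, ny * vy, nz * vz)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, *mapcrs)
    struct.pack_into(
        "<3f", header, 76, float(data_zyx.min()), float(data_zyx.max()), float(data_zyx.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ISPG = P1
    struct.pack_into("<3f", header, 196, *origin)
    header[208:212] = b"MAP "
    struct.pack_into("<4B", header, 212, 0x44, 0x44, 0, 0)  # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(store.astype(_MODE_DTYPE[mode]).tobytes())
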