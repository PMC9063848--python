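"""Shared Fourier-shell machinery for RAPS and FSC.

Both metrics bin the 3D DFT of a cubic volume into spherical shells one
Fourier voxel wide: Fourier voxel (kz, ky, kx) with integer frequency
indices belongs to shell ``k`` when its radius lies in [k - 1/2, k + 1/2).
Shells up to ``n // 2`` (Nyquist) are reported; the corner voxels beyond
Nyquist are still indexed so noise-shaping code can cover the whole lattice.
"""

from __future__ import annotations

import numpy as np

from .core_io import ValidationError, VoxelGrid

#: tolerance on voxel anisotropy for Fourier-domain metrics (max/min - 1)
CUBIC_VOXEL_TOL = 0.01


def require_cubic_voxels(grid: VoxelGrid) -> float:
    """Return the scalar voxel size, or raise if voxels are too anisotropic."""
    if not grid.is_cubic_voxel(CUBIC_VOXEL_TOL):
        raise ValidationError(
            f"Fourier-domain metrics need ~cubic voxels "
            f"(max/min ≤ {1 + CUBIC_VOXEL_TOL}); got voxel_size={grid.voxel_size}"
        )
    return float(np.mean(grid.voxel_size))


def pad_to_cube(data: np.ndarray) -> np.ndarray:
    """Zero-pad a 3D array to a cube (no-op when already cubic)."""
    n = max(data.shape)
    if data.shape == (n, n, n):
        return data
    out = np.zeros((n, n, n), dtype=data.dtype)
    out[: data.shape[0], : data.shape[1], : data.shape[2]] = data
    return out


def shell_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Shell index per Fourier voxel of an n³ DFT, and per-shell voxel counts.

    Covers the full lattice (indices run to ceil(√3·n/2)); the caller decides
    how many shells to report.
    """
    k = np.fft.fftfreq(n) * n  # integer frequency indices, fftn layout
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij", sparse=True)
    radius = np.sqrt(kz**2 + ky**2 + kx**2)
    idx = np.floor(radius + 0.5).astype(np.int64)  # [k-1/2, k+1/2) binning
    counts = np.bincount(idx.ravel())
    return idx, counts


def shell_sum(values: np.ndarray, idx: np.ndarray, n_shells: int) -> np.ndarray:
    """Sum ``values`` over each shell; returns an array of length ``n_shells``."""
    return np.bincount(idx.ravel(), weights=values.ravel(), minlength=n_shells)[:n_shells]
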