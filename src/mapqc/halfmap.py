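"""Half-map analyses: raw-map construction, contour matching, and FSC.

When the two independently refined half-maps of a reconstruction are
deposited, three things become possible:

* a *raw map* — the unfiltered, unsharpened average of the half-maps,
  rescaled to the primary map's mean and standard deviation so images of
  the two are comparable;
* a contour level for that raw map, chosen so its isosurface encloses the
  same volume as the primary map at its recommended level;
* the Fourier shell correlation (FSC) between the half-maps, the standard
  internal estimate of reconstruction resolution.

The FSC curve is reported together with the community resolution criteria
(0.5, 0.143, the half-bit information curve, and 3σ) and the resolution at
which the curve first falls below each, linearly interpolated between
shells.  A curve that rises back above a criterion after crossing it is
flagged — such oscillations typically betray masking or interpolation
artefacts rather than genuine signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _fourier
from .core_io import ValidationError, VoxelGrid

__all__ = [
    "FSCCurve",
    "ContourMatch",
    "RawMap",
    "average_half_maps",
    "scale_to_reference",
    "match_contour_by_volume",
    "make_raw_map",
    "fsc",
    "criterion_curves",
    "resolution_at_threshold",
    "read_author_fsc",
]

CRITERION_NAMES = ("fsc_0.5", "fsc_0.143", "half_bit", "three_sigma")


@dataclass
class FSCCurve:
    """Per-shell Fourier shell correlation with criterion curves and crossings."""

    frequencies: np.ndarray  # shell centers, Å⁻¹
    fsc: np.ndarray  # correlation per shell, in [-1, 1]
    n_voxels_per_shell: np.ndarray
    criteria: dict[str, np.ndarray] = field(default_factory=dict)
    crossings: dict[str, Optional[float]] = field(default_factory=dict)  # resolution, Å
    oscillation: dict[str, bool] = field(default_factory=dict)

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])


@dataclass
class ContourMatch:
    """Result of volume-matched contour estimation."""

    level: float
    achieved_count: int
    target_count: int
    warning: Optional[str] = None


@dataclass
class RawMap:
    grid: VoxelGrid
    matched_level: Optional[float] = None


def average_half_maps(h1: VoxelGrid, h2: VoxelGrid) -> VoxelGrid:
    """Voxel-wise mean of the two half-maps; metadata from the first."""
    h1.same_geometry(h2, check=True)
    return h1.with_data((h1.data + h2.data) / 2, label="raw map (half-map average)")


def scale_to_reference(grid: VoxelGrid, ref: VoxelGrid) -> VoxelGrid:
    """Affinely rescale ``grid`` to the mean and std of ``ref``.

    out = (grid − mean)/std × std_ref + mean_ref.  Computed as a single
    multiply-add so a map that already has the reference moments passes
    through bit-identically.
    """
    mean = float(np.mean(grid.data, dtype=np.float64))
    std = float(np.std(grid.data, dtype=np.float64))
    if std == 0.0:
        raise ValidationError("cannot scale a zero-variance map")
    ref_mean = float(np.mean(ref.data, dtype=np.float64))
    ref_std = float(np.std(ref.data, dtype=np.float64))
    scale = ref_std / std
    offset = ref_mean - mean * scale
    return grid.with_data(grid.data * scale + offset, label=grid.label)


def match_contour_by_volume(grid: VoxelGrid, ref: VoxelGrid, ref_level: float) -> ContourMatch:
    """Contour level of ``grid`` enclosing the same volume as ``ref`` at ``ref_level``.

    Returns the level L (drawn from the map's own voxel values) whose
    enclosed voxel count is closest to the reference count; among levels
    achieving the same count the largest is returned.
    """
    target = int(np.count_nonzero(ref.data >= ref_level))
    values = np.sort(np.unique(grid.data.ravel()))
    if target == 0:
        level = float(values[-1]) + abs(float(values[-1])) * 1e-6 + 1e-6
        return ContourMatch(
            level=level, achieved_count=0, target_count=0,
            warning="reference level encloses no voxels; returning level above map maximum",
        )
    n = grid.data.size
    sorted_all = np.sort(grid.data.ravel())
    # count(grid >= v) for each candidate unique value v
    counts = n - np.searchsorted(sorted_all, values, side="left")
    diffs = np.abs(counts - target)
    best = diffs.min()
    candidates = np.nonzero(diffs == best)[0]
    idx = int(candidates[-1])  # largest level among equal-count candidates
    return ContourMatch(
        level=float(values[idx]),
        achieved_count=int(counts[idx]),
        target_count=target,
    )


def make_raw_map(
    h1: VoxelGrid,
    h2: VoxelGrid,
    primary: VoxelGrid,
    recommended_level: Optional[float] = None,
) -> RawMap:
    """Average the half-maps, scale to the primary map, and match its contour."""
    averaged = average_half_maps(h1, h2)
    scaled = scale_to_reference(averaged, primary)
    matched = None
    if recommended_level is not None:
        matched = match_contour_by_volume(scaled, primary, recommended_level).level
    return RawMap(grid=scaled, matched_level=matched)


def fsc(a: VoxelGrid, b: VoxelGrid) -> FSCCurve:
    """Fourier shell correlation between two volumes on the same lattice.

    Per shell k (one Fourier voxel wide):
    FSC(k) = Re Σ F_a·F_b* / sqrt(Σ|F_a|² · Σ|F_b|²).
    """
    a.same_geometry(b, check=True)
    voxel = _fourier.require_cubic_voxels(a)
    da = _fourier.pad_to_cube(a.data.astype(np.float64))
    db = _fourier.pad_to_cube(b.data.astype(np.float64))
    n = da.shape[0]
    fa = np.fft.fftn(da)
    fb = np.fft.fftn(db)
    idx, counts = _fourier.shell_indices(n)
    n_shells = n // 2 + 1
    num = _fourier.shell_sum((fa * np.conj(fb)).real, idx, n_shells)
    pa = _fourier.shell_sum(np.abs(fa) ** 2, idx, n_shells)
    pb = _fourier.shell_sum(np.abs(fb) ** 2, idx, n_shells)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    shell_counts = counts[:n_shells]
    curve = FSCCurve(
        frequencies=np.arange(n_shells) / (n * voxel),
        fsc=values,
        n_voxels_per_shell=shell_counts,
        criteria=criterion_curves(shell_counts),
    )
    for name in CRITERION_NAMES:
        res, osc = _first_crossing(curve, curve.criteria[name])
        curve.crossings[name] = res
        curve.oscillation[name] = osc
    return curve


def criterion_curves(n_voxels_per_shell: np.ndarray) -> dict[str, np.ndarray]:
    """The four community resolution-criterion curves.

    ``n_eff`` is the raw per-shell Fourier voxel count (no symmetry
    correction).  half-bit: (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n);
    3σ: 3/√(n/2).
    """
    n_eff = np.maximum(np.asarray(n_voxels_per_shell, dtype=np.float64), 1.0)
    sqrt_n = np.sqrt(n_eff)
    ones = np.ones_like(n_eff)
    return {
        "fsc_0.5": 0.5 * ones,
        "fsc_0.143": 0.143 * ones,
        "half_bit": (0.2071 + 1.9102 / sqrt_n) / (1.2071 + 0.9102 / sqrt_n),
        "three_sigma": 3.0 / np.sqrt(n_eff / 2.0),
    }


def _as_threshold(curve: FSCCurve, criterion: Union[str, float, np.ndarray]) -> np.ndarray:
    if isinstance(criterion, str):
        if criterion not in curve.criteria:
            curve.criteria.update(criterion_curves(curve.n_voxels_per_shell))
        return curve.criteria[criterion]
    if np.isscalar(criterion):
        return np.full_like(curve.fsc, float(criterion))  # type: ignore[arg-type]
    return np.asarray(criterion, dtype=float)


def _first_crossing(
    curve: FSCCurve, threshold: np.ndarray
) -> tuple[Optional[float], bool]:
    """First shell where FSC drops below the threshold; later re-crossings flag oscillation.

    Returns (resolution in Å via linear interpolation, oscillation flag).
    Shell 0 (DC) is excluded.  No crossing → (None, False).
    """
    f = curve.frequencies
    diff = curve.fsc - threshold
    cross_idx = None
    for i in range(1, len(diff)):
        if diff[i] < 0 and diff[i - 1] >= 0:
            cross_idx = i
            break
    if cross_idx is None:
        return None, False
    i = cross_idx
    denom = diff[i - 1] - diff[i]
    t = diff[i - 1] / denom if denom > 0 else 0.5
    freq = f[i - 1] + t * (f[i] - f[i - 1])
    oscillation = bool(np.any(diff[i:] >= 0))
    resolution = 1.0 / freq if freq > 0 else None
    return resolution, oscillation


def resolution_at_threshold(
    curve: FSCCurve, criterion: Union[str, float, np.ndarray]
) -> Optional[float]:
    """Resolution (Å) where the FSC first falls below ``criterion``.

    ``criterion`` may be one of the named curves, a constant, or an explicit
    per-shell array.  Returns None when the curve never crosses (resolution
    beyond Nyquist).
    """
    threshold = _as_threshold(curve, criterion)
    resolution, _ = _first_crossing(curve, threshold)
    return resolution


def read_author_fsc(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an author-provided FSC curve: two-column text or simple XML.

    Returns (frequencies in Å⁻¹, fsc values).  These curves are overlaid in
    the report, never recomputed.
    """
    from pathlib import Path

    text = Path(path).read_text()
    if text.lstrip().startswith("<"):
        import xml.etree.ElementTree as ET

        root = ET.fromstring(text)
        freqs, values = [], []
        for point in root.iter():
            x = point.get("x") or point.findtext("x")
            y = point.get("y") or point.findtext("y")
            if x is not None and y is not None:
                freqs.append(float(x))
                values.append(float(y))
        if not freqs:
            raise ValidationError(f"{path}: no (x, y) FSC points found in XML")
        return np.array(freqs), np.array(values)
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ";")):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) >= 2:
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValidationError(f"{path}: no two-column FSC data found")
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1]
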