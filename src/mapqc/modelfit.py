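"""Map/model-fit metrics: atom and residue inclusion, simulated maps,
map-model FSC, and the Q-score.

Inclusion metrics ask a contour-dependent question — does the density at
each atom position reach the chosen level? — and are therefore only as
trustworthy as the recommended contour level.  The Q-score instead
correlates the local density profile around each atom with an ideal
Gaussian, making it invariant to any positive affine rescaling of the map
and independent of the contour level entirely; a well-resolved atom in
good density scores near 1, an atom in noise scores near 0, and a
misplaced atom can score negative.

The simulated map used for map-model FSC is a Gaussian-atom approximation:
every heavy atom contributes an isotropic Gaussian whose integral is
proportional to occupancy × atomic number and whose variance combines the
atom's B-factor with a resolution-dependent width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core_io import AtomicModel, ValidationError, VoxelGrid
from .halfmap import FSCCurve, fsc, resolution_at_threshold

__all__ = [
    "OUTSIDE",
    "InclusionResult",
    "ResidueScore",
    "QScoreResult",
    "SimulatedMap",
    "interpolate_at",
    "atom_inclusion_sweep",
    "residue_inclusion",
    "inclusion_colour",
    "simulate_map",
    "map_model_fsc",
    "q_score",
]

#: sentinel for sample points outside the map box; compares below any level
OUTSIDE = -np.inf

#: width factor converting a nominal resolution (Å) to a Gaussian σ such
#: that the Fourier amplitude falls to ~50% at spatial frequency 1/resolution
RESOLUTION_SIGMA_FACTOR = 0.225

#: Gaussian truncation radius for map simulation, in units of σ
TRUNCATION_SIGMAS = 4.5

#: presentation chunk size for per-residue panels
RESIDUE_CHUNK = 200


@dataclass
class ResidueScore:
    chain_id: str
    seq_num: int
    insertion_code: str
    name: str
    score: float
    n_atoms: int


@dataclass
class InclusionResult:
    levels: Optional[np.ndarray] = None
    fraction_all: Optional[np.ndarray] = None
    fraction_backbone: Optional[np.ndarray] = None
    level: Optional[float] = None
    average: Optional[float] = None
    per_residue: list[ResidueScore] = field(default_factory=list)
    chunks: list[tuple[str, int, int]] = field(default_factory=list)  # (chain, start, stop)


@dataclass
class QScoreResult:
    sigma: float
    per_atom: list[float] = field(default_factory=list)  # NaN where unreliable
    per_residue: list[ResidueScore] = field(default_factory=list)
    per_chain: dict[str, float] = field(default_factory=dict)
    overall: float = float("nan")
    n_unreliable: int = 0


@dataclass
class SimulatedMap:
    grid: VoxelGrid
    resolution_used: float


def interpolate_at(grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the map at physical Å points (N, 3 as x,y,z).

    Points outside the box (outside the convex hull of voxel centers)
    return :data:`OUTSIDE`, which compares below any contour level.
    """
    idx = grid.index_coords(points)  # (N, 3) fractional (z, y, x)
    nz, ny, nx = grid.shape
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] <= nz - 1)
        & (idx[:, 1] >= 0) & (idx[:, 1] <= ny - 1)
        & (idx[:, 2] >= 0) & (idx[:, 2] <= nx - 1)
    )
    values = np.full(idx.shape[0], OUTSIDE)
    if inside.any():
        coords = idx[inside].T
        values[inside] = map_coordinates(
            grid.data.astype(np.float64), coords, order=1, mode="nearest"
        )
    return values


def _model_sample_values(grid: VoxelGrid, model: AtomicModel) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated density at every heavy atom; returns (values, backbone mask)."""
    atoms = model.heavy_atoms()
    if not atoms:
        raise ValidationError("model has no non-hydrogen atoms")
    coords = np.array([a.coords for a in atoms])
    values = interpolate_at(grid, coords)
    backbone = np.array([a.is_backbone for a in atoms], dtype=bool)
    return values, backbone


def atom_inclusion_sweep(
    grid: VoxelGrid, model: AtomicModel, n_levels: int = 128
) -> InclusionResult:
    """Fraction of atoms inside the map as a function of contour level.

    An atom is inside at level L when the interpolated density at its
    center is ≥ L.  Hydrogens are excluded; the fraction is reported for
    all heavy atoms and for backbone atoms separately.  Levels span the
    map's full value range.
    """
    values, backbone = _model_sample_values(grid, model)
    lo, hi = float(grid.data.min()), float(grid.data.max())
    levels = np.linspace(lo, hi, n_levels) if hi > lo else np.array([lo])
    frac_all = (values[None, :] >= levels[:, None]).mean(axis=1)
    if backbone.any():
        frac_bb = (values[None, backbone] >= levels[:, None]).mean(axis=1)
    else:
        frac_bb = np.full_like(frac_all, np.nan)
    return InclusionResult(levels=levels, fraction_all=frac_all, fraction_backbone=frac_bb)


def inclusion_colour(score: float) -> tuple[float, float, float]:
    """Linear red (0) → cyan (1) colour for an inclusion score."""
    s = min(max(score, 0.0), 1.0)
    return (1.0 - s, s, s)


def residue_inclusion(grid: VoxelGrid, model: AtomicModel, level: float) -> InclusionResult:
    """Per-residue inclusion fraction at one contour level (normally the
    recommended one), with presentation chunks of ≤ 200 residues per chain."""
    per_residue: list[ResidueScore] = []
    chunks: list[tuple[str, int, int]] = []
    total_in = 0
    total_atoms = 0
    for chain in model.chains:
        n_res = len(chain.residues)
        for start in range(0, n_res, RESIDUE_CHUNK):
            chunks.append((chain.chain_id, start, min(start + RESIDUE_CHUNK, n_res)))
        for res in chain.residues:
            atoms = res.heavy_atoms()
            if not atoms:
                continue
            coords = np.array([a.coords for a in atoms])
            values = interpolate_at(grid, coords)
            n_in = int(np.count_nonzero(values >= level))
            total_in += n_in
            total_atoms += len(atoms)
            per_residue.append(
                ResidueScore(
                    chain_id=chain.chain_id,
                    seq_num=res.seq_num,
                    insertion_code=res.insertion_code,
                    name=res.name,
                    score=n_in / len(atoms),
                    n_atoms=len(atoms),
                )
            )
    if total_atoms == 0:
        raise ValidationError("model has no non-hydrogen atoms")
    return InclusionResult(
        level=float(level),
        average=total_in / total_atoms,
        per_residue=per_residue,
        chunks=chunks,
    )


def simulate_map(model: AtomicModel, like: VoxelGrid, resolution: float) -> SimulatedMap:
    """Gaussian-atom density simulated from the model on the target lattice.

    Each heavy atom contributes an isotropic 3D Gaussian of integral
    occupancy × Z and variance σ² = B/(8π²) + (0.225·resolution)²,
    truncated at 4.5σ.  The resolution must be representable on the
    lattice (resolution > 2 × max voxel size).
    """
    if resolution <= 2.0 * max(like.voxel_size):
        raise ValidationError(
            f"resolution {resolution} Å is below Nyquist for voxel size {like.voxel_size}"
        )
    nz, ny, nx = like.shape
    sx, sy, sz = like.voxel_size
    ox, oy, oz = like.origin
    out = np.zeros((nz, ny, nx), dtype=np.float64)
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    zs = oz + sz * np.arange(nz)
    sigma_res = RESOLUTION_SIGMA_FACTOR * resolution
    for atom in model.heavy_atoms():
        z_number = gemmi.Element(atom.element).atomic_number
        if z_number == 0:
            z_number = 6  # unknown element: treat as carbon
        sigma2 = atom.b_factor / (8.0 * math.pi**2) + sigma_res**2
        sigma = math.sqrt(sigma2)
        amplitude = atom.occupancy * z_number / ((2.0 * math.pi) ** 1.5 * sigma**3)
        r = TRUNCATION_SIGMAS * sigma
        ax, ay, az = atom.coords
        i0, i1 = np.searchsorted(xs, [ax - r, ax + r])
        j0, j1 = np.searchsorted(ys, [ay - r, ay + r])
        k0, k1 = np.searchsorted(zs, [az - r, az + r])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx2 = (xs[i0:i1] - ax) ** 2
        dy2 = (ys[j0:j1] - ay) ** 2
        dz2 = (zs[k0:k1] - az) ** 2
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        out[k0:k1, j0:j1, i0:i1] += amplitude * np.exp(-r2 / (2.0 * sigma2))
    grid = like.with_data(out, label=f"simulated map at {resolution} Å")
    return SimulatedMap(grid=grid, resolution_used=float(resolution))


def map_model_fsc(
    grid: VoxelGrid, model: AtomicModel, resolution: float
) -> tuple[FSCCurve, Optional[float]]:
    """FSC between the map and a model-simulated map; headline estimate at 0.5.

    The 0.5 cutoff (rather than 0.143) is used because the model is not
    independent of the map.
    """
    simulated = simulate_map(model, grid, resolution)
    curve = fsc(grid, simulated.grid)
    return curve, resolution_at_threshold(curve, "fsc_0.5")


# --------------------------------------------------------------------------
# Q-score

_QSCORE_RADII = np.round(np.arange(1, 21) * 0.1, 10)  # 0.1 … 2.0 Å
_POINTS_PER_SHELL = 8
_MIN_SAMPLE_POINTS = 10


def _shell_directions() -> np.ndarray:
    """(20, 8, 3) unit vectors: golden-spiral directions, 8 per shell.

    One global Fibonacci-sphere sequence of 160 points is split into
    consecutive groups of 8, so consecutive shells sample different
    directions.  Deterministic — no RNG involved.
    """
    n = len(_QSCORE_RADII) * _POINTS_PER_SHELL
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)  # golden angle
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    dirs = np.stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta], axis=1
    )
    return dirs.reshape(len(_QSCORE_RADII), _POINTS_PER_SHELL, 3)


_DIRECTIONS = _shell_directions()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(xc @ yc) / denom


def q_score(grid: VoxelGrid, model: AtomicModel, sigma: float = 0.6) -> QScoreResult:
    """Per-atom resolvability: correlation with an ideal Gaussian profile.

    For each heavy atom the map is sampled at the atom center and on 20
    spherical shells of radius 0.1–2.0 Å (8 deterministic golden-spiral
    points per shell).  Sample points that fall outside the box or are
    closer to another atom than to this one are discarded.  The atom's Q
    is the Pearson correlation between the sampled values and the
    reference profile exp(−r²/(2σ²)); correlation is affine-invariant, so
    neither the reference amplitude nor any rescaling of the map matters.
    Atoms with fewer than 10 usable points are flagged unreliable (NaN)
    and excluded from the aggregates.
    """
    atoms = model.heavy_atoms()
    if not atoms:
        raise ValidationError("model has no non-hydrogen atoms")
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    reference_by_shell = np.exp(-(_QSCORE_RADII**2) / (2.0 * sigma**2))

    per_atom = np.full(len(atoms), np.nan)
    for ai, center in enumerate(coords):
        points = center[None, None, :] + _QSCORE_RADII[:, None, None] * _DIRECTIONS
        points = points.reshape(-1, 3)
        radii = np.repeat(_QSCORE_RADII, _POINTS_PER_SHELL)
        # keep a point only if no other atom is nearer to it than this atom
        nn_dist, _ = tree.query(points, k=1)
        own_dist = radii  # by construction |point - center| == shell radius
        keep = own_dist <= nn_dist + 1e-9
        values = interpolate_at(grid, points[keep])
        finite = np.isfinite(values)
        sample_vals = values[finite]
        sample_ref = np.repeat(reference_by_shell, _POINTS_PER_SHELL)[keep][finite]
        center_val = interpolate_at(grid, center[None, :])
        if np.isfinite(center_val[0]):
            sample_vals = np.concatenate([[center_val[0]], sample_vals])
            sample_ref = np.concatenate([[1.0], sample_ref])
        if sample_vals.size < _MIN_SAMPLE_POINTS:
            continue  # unreliable: left as NaN
        per_atom[ai] = _pearson(sample_vals, sample_ref)

    result = QScoreResult(sigma=float(sigma), per_atom=per_atom.tolist())
    result.n_unreliable = int(np.count_nonzero(~np.isfinite(per_atom)))

    ai = 0
    chain_scores: dict[str, list[float]] = {}
    for chain in model.chains:
        for res in chain.residues:
            res_scores = []
            for _ in res.heavy_atoms():
                q = per_atom[ai]
                if np.isfinite(q):
                    res_scores.append(q)
                ai += 1
            if res_scores:
                score = float(np.mean(res_scores))
                result.per_residue.append(
                    ResidueScore(
                        chain_id=chain.chain_id,
                        seq_num=res.seq_num,
                        insertion_code=res.insertion_code,
                        name=res.name,
                        score=score,
                        n_atoms=len(res_scores),
                    )
                )
                chain_scores.setdefault(chain.chain_id, []).extend(res_scores)
    for cid, scores in chain_scores.items():
        result.per_chain[cid] = float(np.mean(scores))
    reliable = per_atom[np.isfinite(per_atom)]
    if reliable.size:
        result.overall = float(np.mean(reliable))
    return result
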