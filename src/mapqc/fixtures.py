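"""Deterministic synthetic maps, models and half-maps for testing and demos.

The generator builds a small poly-alanine-like helix, simulates its density
on a cubic lattice, and derives from it every input the validation metrics
need: a primary map with additive Gaussian noise, a pair of half-maps whose
noise spectrum is shaped to produce a designed FSC crossover, and perturbed
"failure-mode" variants of the entry (origin shift, voxel-size header error,
masking, and too-high / too-low recommended contour levels).  Every output
is fully determined by the spec's seed.

The half-map construction uses the FSC–SNR relation FSC = SNR/(SNR + 1):
independent noise is added to each half-map with per-shell power equal to
the clean map's shell power times ((1 − t)/t)·(f/f_c)^α, so the expected
FSC equals t = 0.143 exactly at the designed crossover frequency f_c and
falls steeply (α = 8) through it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from . import _fourier
from .core_io import (
    Atom,
    AtomicModel,
    Chain,
    EntryMetadata,
    Residue,
    ValidationError,
    VoxelGrid,
    write_map,
    write_model,
)
from .modelfit import simulate_map

__all__ = [
    "FixtureSpec",
    "SCENARIOS",
    "make_toy_model",
    "make_synthetic_map",
    "make_half_maps",
    "make_degraded_map",
    "make_scenario",
]

SCENARIOS = (
    "clean",
    "origin_shift",
    "pixel_scale_error",
    "masked",
    "high_contour",
    "low_contour",
)

#: steepness of the designed noise-spectrum ramp around the FSC crossover
NOISE_RAMP_ALPHA = 8.0

#: quantile of primary-map voxel values used as the recommended contour level
RECOMMENDED_QUANTILE = 0.995
HIGH_CONTOUR_QUANTILE = 0.999
LOW_CONTOUR_QUANTILE = 0.001

#: header voxel-size multiplier for the pixel_scale_error scenario
PIXEL_SCALE_FACTOR = 1.1


@dataclass
class FixtureSpec:
    """Parameters of one synthetic entry; the seed determines all outputs."""

    n_residues: int = 20
    box: int = 64  # voxels per edge
    voxel: float = 1.0  # Å / voxel
    resolution: float = 6.0  # Å; simulation width and half-map FSC crossover
    noise_sigma: float = 0.01  # map units, additive white noise on the primary
    seed: int = 0
    scenario: str = "clean"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.n_residues < 1:
            raise ValidationError("n_residues must be ≥ 1")


# --------------------------------------------------------------------------
# model generation

# local-frame offsets (Å) of the backbone + stub atoms relative to CA,
# expressed in the (tangent, normal, binormal) frame of the helix path
_ATOM_TEMPLATE = (
    # name, element, (t, n, b) offset, backbone
    ("N", "N", (-1.20, 0.60, 0.25), True),
    ("CA", "C", (0.00, 0.00, 0.00), True),
    ("C", "C", (1.25, 0.45, -0.30), True),
    ("O", "O", (1.60, 1.35, -0.95), True),
    ("CB", "C", (0.10, -1.30, 0.80), False),
)

_CA_SPACING = 3.8  # Å between consecutive CA atoms
_HELIX_RADIUS = 12.0  # Å
_Z_STEP = 0.5  # Å of axial drift per residue


def make_toy_model(n_residues: int, seed: int) -> AtomicModel:
    """Poly-alanine-like chain on a helical path, centered on the origin.

    Consecutive CA–CA distances are exactly 3.8 Å by construction; B-factors
    are drawn reproducibly from U[20, 80] Å².
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be ≥ 1")
    rng = np.random.default_rng(seed)
    # rotation per residue chosen so the CA–CA *chord* (not arc) is 3.8 Å
    horizontal_chord = math.sqrt(_CA_SPACING**2 - _Z_STEP**2)
    dtheta = 2.0 * math.asin(horizontal_chord / (2.0 * _HELIX_RADIUS))
    thetas = dtheta * np.arange(n_residues)
    zs = _Z_STEP * (np.arange(n_residues) - (n_residues - 1) / 2.0)
    ca = np.stack(
        [_HELIX_RADIUS * np.cos(thetas), _HELIX_RADIUS * np.sin(thetas), zs], axis=1
    )
    b_factors = rng.uniform(20.0, 80.0, size=n_residues)

    chain = Chain(chain_id="A")
    for i in range(n_residues):
        # local frame: tangent along the path, normal toward the helix axis
        tangent = np.array(
            [-math.sin(thetas[i]) * horizontal_chord, math.cos(thetas[i]) * horizontal_chord, _Z_STEP]
        )
        tangent /= np.linalg.norm(tangent)
        normal = np.array([-math.cos(thetas[i]), -math.sin(thetas[i]), 0.0])
        binormal = np.cross(tangent, normal)
        res = Residue(name="ALA", seq_num=i + 1, kind="amino-acid")
        for name, element, (t, n, b), backbone in _ATOM_TEMPLATE:
            pos = ca[i] + t * tangent + n * normal + b * binormal
            res.atoms.append(
                Atom(
                    element=element,
                    name=name,
                    coords=tuple(pos),
                    b_factor=float(b_factors[i]),
                    occupancy=1.0,
                    is_backbone=backbone,
                )
            )
        chain.residues.append(res)
    return AtomicModel(chains=[chain], label=f"toy model n={n_residues} seed={seed}")


def model_weight_kda(model: AtomicModel) -> float:
    """Molecular weight of the model in kDa (sum of element weights)."""
    return sum(gemmi.Element(a.element).weight for a in model.atoms()) / 1000.0


# --------------------------------------------------------------------------
# map generation


def _empty_grid(spec: FixtureSpec) -> VoxelGrid:
    shape = (spec.box,) * 3
    return VoxelGrid(
        data=np.zeros(shape), voxel_size=(spec.voxel,) * 3, origin=(0.0, 0.0, 0.0)
    )


def _centered_model(model: AtomicModel, spec: FixtureSpec) -> AtomicModel:
    """Translate the model so its centroid sits at the box center."""
    coords = model.heavy_coords()
    center = 0.5 * spec.voxel * (spec.box - 1)
    shift = np.array([center] * 3) - coords.mean(axis=0)
    return model.translated(shift)


def make_synthetic_map(
    model: AtomicModel, spec: FixtureSpec, noise_seed_offset: int = 0
) -> VoxelGrid:
    """Simulated density of the model plus seeded white Gaussian noise.

    The model must fit inside the box with ≥ 5 Å margin.
    """
    like = _empty_grid(spec)
    coords = model.heavy_coords()
    extent = spec.voxel * (spec.box - 1)
    if coords.min() < 5.0 or coords.max() > extent - 5.0:
        raise ValidationError(
            "model does not fit inside the box with a 5 Å margin; "
            f"coordinate range [{coords.min():.1f}, {coords.max():.1f}] Å in a {extent:.1f} Å box"
        )
    signal = simulate_map(model, like, spec.resolution).grid.data
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + noise_seed_offset)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    return like.with_data(signal, label=f"synthetic map ({spec.scenario}, seed={spec.seed})")


def _shaped_noise(
    clean: np.ndarray, voxel: float, f_c: float, ratio_at_fc: float, rng: np.random.Generator
) -> np.ndarray:
    """Noise field whose shell power is ratio(f) × the clean map's shell power.

    ratio(f) = ratio_at_fc · (f/f_c)^α with α = NOISE_RAMP_ALPHA; the DC
    shell gets no noise.
    """
    n = clean.shape[0]
    idx, counts = _fourier.shell_indices(n)
    n_shells = counts.size
    f_clean = np.fft.fftn(clean)
    shell_power = _fourier.shell_sum(np.abs(f_clean) ** 2, idx, n_shells) / counts
    freqs = np.arange(n_shells) / (n * voxel)
    ratio = np.zeros(n_shells)
    ratio[1:] = ratio_at_fc * (freqs[1:] / f_c) ** NOISE_RAMP_ALPHA
    target_power = shell_power * ratio
    white = rng.standard_normal(clean.shape)
    w = np.fft.fftn(white)
    # E|W|² = n³ for unit-variance white noise; rescale per shell
    scale = np.sqrt(target_power / clean.size)[idx]
    return np.fft.ifftn(w * scale).real


def make_half_maps(
    clean: VoxelGrid, crossover_resolution: float, seed: int
) -> tuple[VoxelGrid, VoxelGrid]:
    """Two half-maps = clean signal + independent shell-shaped noise.

    Noise power is chosen so the expected half-map FSC equals 0.143 at
    1/crossover_resolution (FSC = SNR/(SNR + 1)).
    """
    voxel = _fourier.require_cubic_voxels(clean)
    n = clean.shape[0]
    f_c = 1.0 / crossover_resolution
    if not (1.0 / (n * voxel)) < f_c <= 1.0 / (2.0 * voxel):
        raise ValidationError(
            f"crossover resolution {crossover_resolution} Å outside ({2 * voxel}, {n * voxel}) Å"
        )
    t = 0.143
    ratio = (1.0 - t) / t
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(2):
        noise = _shaped_noise(clean.data.astype(np.float64), voxel, f_c, ratio, rng)
        halves.append(clean.with_data(clean.data + noise, label="synthetic half-map"))
    return halves[0], halves[1]


def make_degraded_map(
    clean: VoxelGrid, crossover_resolution: float, seed: int, threshold: float = 0.5
) -> VoxelGrid:
    """A low-passed, noisy version of ``clean`` whose FSC against the clean
    map crosses ``threshold`` at 1/crossover_resolution.

    Against a noise-free reference FSC = 1/sqrt(1 + N/S), so the noise/signal
    power ratio at the crossover is 1/threshold² − 1.
    """
    voxel = _fourier.require_cubic_voxels(clean)
    n = clean.shape[0]
    f_c = 1.0 / crossover_resolution
    # gentle Gaussian low-pass with 50% amplitude at the crossover frequency
    idx, counts = _fourier.shell_indices(n)
    freqs = (np.arange(counts.size) / (n * voxel))[idx]
    sigma_f = f_c / math.sqrt(2.0 * math.log(2.0))
    h = np.exp(-(freqs**2) / (2.0 * sigma_f**2))
    filtered = np.fft.ifftn(np.fft.fftn(clean.data.astype(np.float64)) * h).real
    ratio = 1.0 / threshold**2 - 1.0
    rng = np.random.default_rng(seed)
    noise = _shaped_noise(filtered, voxel, f_c, ratio, rng)
    return clean.with_data(filtered + noise, label="degraded map")


# --------------------------------------------------------------------------
# scenario assembly


def _attained_quantile(data: np.ndarray, q: float) -> float:
    """The voxel value at quantile q, as an actually attained value."""
    flat = np.sort(data.ravel())
    idx = min(int(q * flat.size), flat.size - 1)
    return float(flat[idx])


def make_scenario(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a complete synthetic entry (map, half-maps, model, metadata).

    Perturbations by scenario: ``origin_shift`` displaces the primary map's
    origin by half the box; ``pixel_scale_error`` multiplies the header
    voxel size by 1.1; ``masked`` zeroes voxels outside a sphere (and writes
    the mask); ``high_contour``/``low_contour`` set the recommended level at
    the 99.9th / 0.1th percentile of voxel values.

    Returns a manifest dict with the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _centered_model(make_toy_model(spec.n_residues, spec.seed), spec)

    # noiseless signal shared by primary and half-maps
    clean_spec = FixtureSpec(**{**spec.__dict__, "noise_sigma": 0.0})
    signal = make_synthetic_map(model, clean_spec)
    primary = make_synthetic_map(model, spec, noise_seed_offset=1)
    half1, half2 = make_half_maps(signal, spec.resolution, spec.seed + 2)

    mask_path: Optional[Path] = None
    if spec.scenario == "masked":
        nz, ny, nx = primary.shape
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
        )
        c = (spec.box - 1) / 2.0
        r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
        mask = (r2 <= (0.4 * spec.box) ** 2).astype(np.float64)
        primary = primary.with_data(primary.data * mask, label=primary.label)
        mask_grid = primary.with_data(mask, label="spherical mask")
        mask_path = write_map(mask_grid, out / "mask.mrc")

    quantile = {
        "high_contour": HIGH_CONTOUR_QUANTILE,
        "low_contour": LOW_CONTOUR_QUANTILE,
    }.get(spec.scenario, RECOMMENDED_QUANTILE)
    recommended = _attained_quantile(primary.data, quantile)

    if spec.scenario == "origin_shift":
        half_box = spec.voxel * spec.box / 2.0
        primary = VoxelGrid(
            data=primary.data,
            voxel_size=primary.voxel_size,
            origin=tuple(o + half_box for o in primary.origin),
            label=primary.label,
        )
    elif spec.scenario == "pixel_scale_error":
        primary = VoxelGrid(
            data=primary.data,
            voxel_size=tuple(v * PIXEL_SCALE_FACTOR for v in primary.voxel_size),
            origin=primary.origin,
            label=primary.label,
        )

    primary_path = write_map(primary, out / "primary.mrc")
    half1_path = write_map(half1, out / "half_map_1.mrc")
    half2_path = write_map(half2, out / "half_map_2.mrc")
    model_path = write_model(model, out / "model.pdb")

    meta = EntryMetadata(
        recommended_contour_level=recommended,
        author_resolution=spec.resolution,
        molecular_weight=model_weight_kda(model),
        modality="SPA",
    )
    metadata = {
        **meta.to_dict(),
        "scenario": spec.scenario,
        "seed": spec.seed,
        "n_residues": spec.n_residues,
        "box": spec.box,
        "voxel": spec.voxel,
        "noise_sigma": spec.noise_sigma,
    }
    meta_path = out / "metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")

    manifest = {
        "primary": str(primary_path),
        "half1": str(half1_path),
        "half2": str(half2_path),
        "model": str(model_path),
        "metadata": str(meta_path),
    }
    if mask_path is not None:
        manifest["mask"] = str(mask_path)
    return manifest
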