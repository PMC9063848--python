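"""Aggregate every metric into a per-entry JSON report plus images.

`build_report` runs all applicable analyses on one entry directory: map
statistics always; the half-map block when both half-maps are present; one
fit block per model; mask-overlap statistics per mask.  Missing optional
inputs are recorded as explicit ``not_computed`` entries, and a failure in
any single metric is captured in the report's error list while the
remaining metrics still run.  Identical inputs and package version produce
a byte-identical ``report.json``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from . import __version__, halfmap, map_stats, modelfit
from .core_io import AtomicModel, EntryMetadata, VoxelGrid, read_map, read_model
from .luts import glow_lut
from .schema import ValidationReportModel

__all__ = ["render_image", "build_report", "discover_entry", "REPORT_NAME"]

REPORT_NAME = "report.json"
STANDARD_SIZE = 300
TOMOGRAM_SIZE = 1200

# default per-entry file naming convention (overridable via explicit paths)
_DEFAULT_NAMES = {
    "primary": ("primary.mrc", "primary.map", "emd.mrc"),
    "half1": ("half_map_1.mrc", "half1.mrc"),
    "half2": ("half_map_2.mrc", "half2.mrc"),
    "metadata": ("metadata.json",),
    "author_fsc": ("author_fsc.txt", "author_fsc.dat", "fsc.xml"),
}


def _round6(values) -> list:
    return [round(float(v), 6) for v in np.asarray(values).ravel()]


def render_image(
    image: np.ndarray,
    out_path: str | Path,
    colour: str = "grayscale",
    standardized: bool = False,
    tomogram: bool = False,
) -> Path:
    """Write a 2D array as a PNG.

    Grayscale maps min→black and max→white; ``glow`` applies the heated-body
    LUT to the same normalization.  Standardized output is resampled to
    300×300 (1200×1200 for tomograms) with aspect-preserving zero padding;
    otherwise the native size is kept.  Rows are flipped so the lowest array
    row appears at the bottom of the image.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"render_image needs a 2D array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    lo, hi = arr.min(), arr.max()
    norm = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    scaled = np.round(norm * 255.0).astype(np.uint8)
    scaled = np.flipud(scaled)
    if colour == "glow":
        img = Image.fromarray(glow_lut()[scaled], mode="RGB")
    elif colour == "grayscale":
        img = Image.fromarray(scaled, mode="L")
    else:
        raise ValueError(f"colour must be grayscale|glow, got {colour!r}")
    if standardized:
        side = max(img.size)
        padded = Image.new(img.mode, (side, side), 0)
        padded.paste(img, ((side - img.size[0]) // 2, (side - img.size[1]) // 2))
        target = TOMOGRAM_SIZE if tomogram else STANDARD_SIZE
        img = padded.resize((target, target), Image.BILINEAR)
    out_path = Path(out_path)
    img.save(out_path, format="PNG")
    return out_path


def discover_entry(entry_dir: Path) -> dict:
    """Locate entry files by the default naming convention."""
    found: dict = {}
    for key, names in _DEFAULT_NAMES.items():
        for name in names:
            p = entry_dir / name
            if p.exists():
                found[key] = p
                break
    found["models"] = sorted(
        p for p in entry_dir.iterdir()
        if p.suffix.lower() in {".pdb", ".cif", ".mmcif"} and p.is_file()
    )
    found["masks"] = sorted(p for p in entry_dir.glob("mask*.mrc"))
    return found


def _fsc_block(curve: halfmap.FSCCurve) -> dict:
    return {
        "frequencies": _round6(curve.frequencies),
        "fsc": _round6(curve.fsc),
        "n_voxels_per_shell": [int(c) for c in curve.n_voxels_per_shell],
        "criteria": {k: _round6(v) for k, v in curve.criteria.items()},
        "resolutions": {
            k: (round(v, 6) if v is not None else None) for k, v in curve.crossings.items()
        },
        "oscillation": dict(curve.oscillation),
    }


def _map_statistics_block(
    grid: VoxelGrid, meta: EntryMetadata, errors: list[str]
) -> dict:
    hist = map_stats.voxel_histogram(grid)
    sweep = map_stats.volume_sweep(grid, meta=meta)
    slices = map_stats.slice_set(grid)
    block = {
        "mean": round(float(grid.data.mean()), 6),
        "std": round(float(grid.data.std()), 6),
        "min": round(float(grid.data.min()), 6),
        "max": round(float(grid.data.max()), 6),
        "n_voxels": int(grid.data.size),
        "voxel_size": _round6(grid.voxel_size),
        "origin": _round6(grid.origin),
        "shape": list(grid.shape),
        "histogram": {
            "bin_edges": _round6(hist.bin_edges),
            "counts": [int(c) for c in hist.counts],
        },
        "volume_sweep": {
            "levels": _round6(sweep.levels),
            "volumes_nm3": _round6(sweep.volumes),
            "recommended_level": _opt(sweep.recommended_level),
            "volume_at_recommended_nm3": _opt(sweep.volume_at_recommended),
            "predicted_volume_nm3": _opt(sweep.predicted_volume),
        },
        "slices": {
            "central": {ax: s.index for ax, s in slices.central.items()},
            "max_variance": {ax: s.index for ax, s in slices.max_variance.items()},
        },
        "raps": None,
    }
    try:
        raps = map_stats.raps(grid)
        block["raps"] = {
            "frequencies": _round6(raps.frequencies),
            "intensities": _round6(raps.intensities),
            "n_voxels_per_shell": [int(c) for c in raps.n_voxels_per_shell],
        }
    except Exception as exc:  # e.g. anisotropic voxels
        errors.append(f"raps: {exc}")
    return block


def _opt(v: Optional[float]) -> Optional[float]:
    if v is None or not math.isfinite(v):
        return None
    return round(float(v), 6)


def _residue_entries(scores) -> list[dict]:
    return [
        {
            "chain": r.chain_id,
            "seq_num": r.seq_num,
            "insertion_code": r.insertion_code,
            "name": r.name,
            "score": round(r.score, 6),
            "n_atoms": r.n_atoms,
        }
        for r in scores
    ]


def _model_block(
    grid: VoxelGrid,
    model: AtomicModel,
    model_path: Path,
    meta: EntryMetadata,
) -> dict:
    block: dict = {
        "file": model_path.name,
        "n_chains": len(model.chains),
        "n_residues": sum(len(c.residues) for c in model.chains),
        "n_atoms": model.n_atoms,
        "model_map_overlap": None,
        "inclusion_sweep": None,
        "residue_inclusion": None,
        "map_model_fsc": None,
        "q_score": None,
        "errors": [],
    }
    try:
        sweep = modelfit.atom_inclusion_sweep(grid, model)
        block["inclusion_sweep"] = {
            "levels": _round6(sweep.levels),
            "fraction_all": _round6(sweep.fraction_all),
            "fraction_backbone": (
                _round6(sweep.fraction_backbone)
                if np.isfinite(sweep.fraction_backbone).all()
                else None
            ),
        }
    except Exception as exc:
        block["errors"].append(f"atom_inclusion_sweep: {exc}")
    if meta.recommended_contour_level is not None:
        try:
            inc = modelfit.residue_inclusion(grid, model, meta.recommended_contour_level)
            block["residue_inclusion"] = {
                "level": round(float(inc.level), 6),
                "average": round(float(inc.average), 6),
                "per_residue": _residue_entries(inc.per_residue),
                "chunks": [list(c) for c in inc.chunks],
            }
            if inc.average == 0.0:
                block["model_map_overlap"] = "none"
            elif inc.average < 0.5:
                block["model_map_overlap"] = "partial"
            else:
                block["model_map_overlap"] = "good"
        except Exception as exc:
            block["errors"].append(f"residue_inclusion: {exc}")
    resolution = meta.author_resolution
    if resolution is not None:
        try:
            curve, res05 = modelfit.map_model_fsc(grid, model, resolution)
            block["map_model_fsc"] = {
                "fsc": _fsc_block(curve),
                "resolution_fsc_0_5": _opt(res05),
                "simulation_resolution": round(float(resolution), 6),
            }
        except Exception as exc:
            block["errors"].append(f"map_model_fsc: {exc}")
    try:
        q = modelfit.q_score(grid, model)
        block["q_score"] = {
            "sigma": q.sigma,
            "overall": _opt(q.overall),
            "per_chain": {k: round(v, 6) for k, v in sorted(q.per_chain.items())},
            "per_residue": _residue_entries(q.per_residue),
            "n_atoms_scored": len(q.per_atom) - q.n_unreliable,
            "n_unreliable": q.n_unreliable,
        }
    except Exception as exc:
        block["errors"].append(f"q_score: {exc}")
    return block


def _write_images(
    grid: VoxelGrid, out_dir: Path, tomogram: bool
) -> list[dict]:
    """Write the standard slice/projection image set; returns the manifest."""
    manifest: list[dict] = []
    slices = map_stats.slice_set(grid)

    def emit(image, kind, axis, colour, statistic=None):
        for standardized in (True, False):
            suffix = "std" if standardized else "native"
            stat_part = f"_{statistic}" if statistic else ""
            name = f"{kind}{stat_part}_{axis}_{colour}_{suffix}.png"
            render_image(
                image, out_dir / name, colour=colour,
                standardized=standardized, tomogram=tomogram,
            )
            manifest.append(
                {
                    "file": name,
                    "kind": kind,
                    "axis": axis,
                    "statistic": statistic,
                    "colour": colour,
                    "standardized": standardized,
                }
            )

    for axis in map_stats.AXES:
        emit(slices.central[axis].image, "central_slice", axis, "grayscale")
        emit(slices.max_variance[axis].image, "max_variance_slice", axis, "grayscale")
        for stat in ("mean", "std", "max"):
            image = map_stats.project(grid, axis, stat)
            emit(image, "projection", axis, "grayscale", statistic=stat)
            if stat in ("std", "max"):  # false colour only for std/max
                emit(image, "projection", axis, "glow", statistic=stat)
    return manifest


def build_report(
    entry_dir: str | Path,
    *,
    primary: Optional[Path] = None,
    half1: Optional[Path] = None,
    half2: Optional[Path] = None,
    models: Optional[Sequence[Path]] = None,
    masks: Optional[Sequence[Path]] = None,
    author_fsc: Optional[Path] = None,
    metadata: Optional[EntryMetadata] = None,
    out_dir: Optional[Path] = None,
    json_only: bool = False,
    entry_id: Optional[str] = None,
) -> tuple[dict, Path]:
    """Run every applicable metric on one entry and write ``report.json``.

    Files not given explicitly are discovered in ``entry_dir`` by the
    default naming convention.  Returns (report dict, path of report.json).
    Raises on a missing/unreadable primary map; any other metric failure is
    recorded in the report.
    """
    entry_dir = Path(entry_dir)
    found = discover_entry(entry_dir) if entry_dir.is_dir() else {"models": [], "masks": []}
    primary = Path(primary) if primary else found.get("primary")
    half1 = Path(half1) if half1 else found.get("half1")
    half2 = Path(half2) if half2 else found.get("half2")
    model_paths = [Path(m) for m in models] if models else found["models"]
    mask_paths = [Path(m) for m in masks] if masks else found["masks"]
    author_fsc = Path(author_fsc) if author_fsc else found.get("author_fsc")
    if metadata is None:
        meta_path = found.get("metadata")
        if meta_path is not None:
            metadata = EntryMetadata.from_dict(json.loads(Path(meta_path).read_text()))
        else:
            metadata = EntryMetadata()
    if primary is None:
        raise FileNotFoundError(f"no primary map found in {entry_dir}")
    out_dir = Path(out_dir) if out_dir else entry_dir / "validation"
    out_dir.mkdir(parents=True, exist_ok=True)

    errors: list[str] = []
    grid = read_map(primary)
    tomogram = metadata.modality.lower() == "tomogram"

    report: dict = {
        "entry_id": entry_id or entry_dir.name,
        "software": {
            "name": "mapqc",
            "version": __version__,
            "parameters": {
                "histogram_bins": 128,
                "sweep_levels": 128,
                "inclusion_levels": 128,
                "q_score_sigma": 0.6,
            },
        },
        "metadata": metadata.to_dict(),
        "map_statistics": _map_statistics_block(grid, metadata, errors),
        "half_map": {"status": "not_computed: missing input", "raw_map": None,
                     "fsc": None, "author_fsc": None},
        "models": [],
        "masks": [],
        "images": [],
        "errors": errors,
    }

    if half1 is not None and half2 is not None:
        try:
            g1, g2 = read_map(half1), read_map(half2)
            raw = halfmap.make_raw_map(
                g1, g2, grid, recommended_level=metadata.recommended_contour_level
            )
            curve = halfmap.fsc(g1, g2)
            report["half_map"] = {
                "status": "computed",
                "raw_map": {
                    "mean": round(float(raw.grid.data.mean()), 6),
                    "std": round(float(raw.grid.data.std()), 6),
                    "matched_contour_level": _opt(raw.matched_level),
                },
                "fsc": _fsc_block(curve),
                "author_fsc": None,
            }
        except Exception as exc:
            errors.append(f"half_map: {exc}")
            report["half_map"]["status"] = f"not_computed: {exc}"
    if author_fsc is not None:
        try:
            freqs, values = halfmap.read_author_fsc(author_fsc)
            report["half_map"]["author_fsc"] = {
                "file": Path(author_fsc).name,
                "frequencies": _round6(freqs),
                "fsc": _round6(values),
            }
        except Exception as exc:
            errors.append(f"author_fsc: {exc}")

    for model_path in model_paths:
        try:
            model = read_model(model_path)
            report["models"].append(_model_block(grid, model, model_path, metadata))
        except Exception as exc:
            errors.append(f"model {model_path.name}: {exc}")

    level = metadata.recommended_contour_level
    for mask_path in mask_paths:
        entry = {"file": mask_path.name, "fraction_primary_inside": None,
                 "status": "computed"}
        try:
            mask_grid = read_map(mask_path)
            grid.same_geometry(mask_grid, check=True)
            if level is None:
                entry["status"] = "not_computed: no recommended contour level"
            else:
                above = grid.data >= level
                n_above = int(np.count_nonzero(above))
                if n_above:
                    inside = np.count_nonzero(above & (mask_grid.data > 0.5))
                    entry["fraction_primary_inside"] = round(inside / n_above, 6)
        except Exception as exc:
            errors.append(f"mask {mask_path.name}: {exc}")
            entry["status"] = f"not_computed: {exc}"
        report["masks"].append(entry)

    if not json_only:
        try:
            report["images"] = _write_images(grid, out_dir, tomogram)
        except Exception as exc:
            errors.append(f"images: {exc}")

    ValidationReportModel.model_validate(report)  # schema check before emission
    report_path = out_dir / REPORT_NAME
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report, report_path
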