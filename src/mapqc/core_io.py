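"""Reading and writing of density volumes and atomic models.

Density maps are held in a :class:`VoxelGrid`, a plain ``(z, y, x)``-indexed
array plus the physical metadata needed to place it in space: voxel size in
Å/voxel per axis and the physical position (Å) of the *center* of voxel
``(0, 0, 0)``.  Whatever axis order an MRC/CCP4 file was stored in, loading
normalizes to this one convention, so downstream metrics never need to look
at header fields.

Atomic models are held in a minimal chain → residue → atom hierarchy
(:class:`AtomicModel`) with only the attributes the validation metrics need:
coordinates, element, B-factor, occupancy, and backbone/hydrogen flags.

All file parsing and writing is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "MapFormatError",
    "ModelFormatError",
    "ValidationError",
    "VoxelGrid",
    "Atom",
    "Residue",
    "Chain",
    "AtomicModel",
    "EntryMetadata",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
]


class MapFormatError(ValueError):
    """The file is not a readable MRC2014/CCP4 volume."""


class ModelFormatError(ValueError):
    """The file is not a readable PDB/mmCIF coordinate file."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


# --------------------------------------------------------------------------
# voxel grids


@dataclass
class VoxelGrid:
    """A 3D density volume with physical placement metadata.

    Attributes
    ----------
    data:
        Real-valued array indexed ``(z, y, x)``.
    voxel_size:
        ``(sx, sy, sz)`` in Å per voxel; all components > 0.
    origin:
        Physical position (Å) of the center of voxel ``(0, 0, 0)``,
        as ``(ox, oy, oz)``.
    label:
        Free-text provenance.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"grid data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if not np.isfinite(self.data).all():
            raise ValidationError("grid data contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape as ``(nz, ny, nx)``."""
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        sx, sy, sz = self.voxel_size
        return sx * sy * sz

    def is_cubic_voxel(self, tol: float = 0.01) -> bool:
        """True if the voxel is isotropic within ``max/min ≤ 1 + tol``."""
        return max(self.voxel_size) / min(self.voxel_size) <= 1.0 + tol

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (Å) of voxel centers along ``axis`` (0=z,1=y,2=x)."""
        n = self.data.shape[axis]
        s = self.voxel_size[2 - axis]
        o = self.origin[2 - axis]
        return o + s * np.arange(n)

    def index_coords(self, points: np.ndarray) -> np.ndarray:
        """Map physical Å points (N, 3 as x,y,z) to fractional (z, y, x) indices."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        sx, sy, sz = self.voxel_size
        ox, oy, oz = self.origin
        ix = (p[:, 0] - ox) / sx
        iy = (p[:, 1] - oy) / sy
        iz = (p[:, 2] - oz) / sz
        return np.stack([iz, iy, ix], axis=1)

    def with_data(self, data: np.ndarray, label: Optional[str] = None) -> "VoxelGrid":
        """New grid with the same geometry but different voxel values."""
        return VoxelGrid(
            data=data,
            voxel_size=self.voxel_size,
            origin=self.origin,
            label=self.label if label is None else label,
        )

    def same_geometry(self, other: "VoxelGrid", *, check: bool = False) -> bool:
        """Compare shape, voxel size (1e-4 relative) and origin (half a voxel).

        With ``check=True`` a mismatch raises :class:`ValidationError` naming
        the offending field.
        """
        if self.shape != other.shape:
            if check:
                raise ValidationError(f"shape mismatch: {self.shape} vs {other.shape}")
            return False
        for a, b in zip(self.voxel_size, other.voxel_size):
            if abs(a - b) > 1e-4 * max(abs(a), abs(b)):
                if check:
                    raise ValidationError(
                        f"voxel_size mismatch: {self.voxel_size} vs {other.voxel_size}"
                    )
                return False
        half_voxel = 0.5 * min(self.voxel_size)
        for a, b in zip(self.origin, other.origin):
            if abs(a - b) > half_voxel:
                if check:
                    raise ValidationError(f"origin mismatch: {self.origin} vs {other.origin}")
                return False
        return True


def read_map(path: str | Path) -> VoxelGrid:
    """Load an MRC2014/CCP4 volume into a :class:`VoxelGrid`.

    Storage axis order (MAPC/MAPR/MAPS) is normalized so ``data`` is always
    indexed ``(z, y, x)``.  The origin is taken from the ORIGIN header record
    when any component is nonzero, otherwise from the NXSTART/NYSTART/NZSTART
    start indices times the voxel size.  Voxel size is cell length divided by
    grid sampling, per axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    # after setup the header words are in x,y,z order
    mxyz = [ccp4.header_i32(i) for i in (8, 9, 10)]
    cell = [ccp4.header_float(i) for i in (11, 12, 13)]
    if any(m <= 0 for m in mxyz):
        raise MapFormatError(f"{path}: non-positive grid sampling MX/MY/MZ={mxyz}")
    if any(c <= 0 for c in cell):
        raise MapFormatError(f"{path}: non-positive cell length CELLA={cell}")
    voxel = tuple(c / m for c, m in zip(cell, mxyz))
    origin_rec = tuple(ccp4.header_float(i) for i in (50, 51, 52))
    if any(v != 0.0 for v in origin_rec):
        origin = origin_rec
    else:
        nstart = [ccp4.header_i32(i) for i in (5, 6, 7)]
        origin = tuple(n * v for n, v in zip(nstart, voxel))
    data = np.ascontiguousarray(np.transpose(ccp4.grid.array, (2, 1, 0)))
    if not np.isfinite(data).all():
        raise ValidationError(f"{path}: map contains non-finite voxel values")
    return VoxelGrid(data=data, voxel_size=voxel, origin=origin, label=str(path))


def write_map(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as a mode-2 (32-bit float) MRC2014 file."""
    path = Path(path)
    nz, ny, nx = grid.shape
    sx, sy, sz = grid.voxel_size
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(
        np.ascontiguousarray(np.transpose(grid.data, (2, 1, 0)), dtype=np.float32)
    )
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(word, value)
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc
    return path


# --------------------------------------------------------------------------
# atomic models

ResidueKind = Literal["amino-acid", "nucleotide", "ligand"]

# atoms constituting the polymer backbone, per residue kind
_AMINO_BACKBONE = {"N", "CA", "C", "O"}
_NUC_BACKBONE = {"P", "O5'", "C5'", "C4'", "C3'", "O3'", "O5*", "C5*", "C4*", "C3*", "O3*"}


@dataclass
class Atom:
    element: str
    name: str
    coords: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_backbone: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = tuple(float(c) for c in self.coords)  # type: ignore[assignment]
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError(f"atom {self.name}: non-finite coordinates {self.coords}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    name: str
    seq_num: int
    insertion_code: str = ""
    kind: ResidueKind = "ligand"
    atoms: list[Atom] = field(default_factory=list)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AtomicModel:
    chains: list[Chain] = field(default_factory=list)
    label: str = ""

    def atoms(self) -> Iterator[Atom]:
        for chain in self.chains:
            for residue in chain.residues:
                yield from residue.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if not a.is_hydrogen]

    def residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for residue in chain.residues:
                yield chain, residue

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def heavy_coords(self) -> np.ndarray:
        """(N, 3) x,y,z coordinates of all non-hydrogen atoms."""
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float).reshape(-1, 3)

    def translated(self, shift: Sequence[float]) -> "AtomicModel":
        """A copy of the model with every atom displaced by ``shift`` (Å, x,y,z)."""
        dx, dy, dz = (float(s) for s in shift)
        out = AtomicModel(label=self.label)
        for chain in self.chains:
            new_chain = Chain(chain_id=chain.chain_id)
            for res in chain.residues:
                new_res = Residue(res.name, res.seq_num, res.insertion_code, res.kind)
                for a in res.atoms:
                    x, y, z = a.coords
                    new_res.atoms.append(
                        Atom(a.element, a.name, (x + dx, y + dy, z + dz),
                             a.b_factor, a.occupancy, a.is_backbone, a.is_hydrogen)
                    )
                new_chain.residues.append(new_res)
            out.chains.append(new_chain)
        return out


def _residue_kind(name: str) -> ResidueKind:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "amino-acid"
        if info.is_nucleic_acid():
            return "nucleotide"
    return "ligand"


def _classify_backbone(atom_name: str, kind: ResidueKind) -> bool:
    if kind == "amino-acid":
        return atom_name in _AMINO_BACKBONE
    if kind == "nucleotide":
        return atom_name in _NUC_BACKBONE
    return False


def read_model(path: str | Path, fmt: Optional[str] = None) -> AtomicModel:
    """Load a PDB or mmCIF coordinate file into an :class:`AtomicModel`.

    Format is detected from the extension unless ``fmt`` ("pdb" or "cif") is
    given.  When alternate locations are present only the first-listed
    conformer is kept.  Hydrogens are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    coor_format = gemmi.CoorFormat.Detect
    if fmt is not None:
        coor_format = {"pdb": gemmi.CoorFormat.Pdb, "cif": gemmi.CoorFormat.Mmcif}[fmt.lower()]
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()  # keeps the first-listed conformer
    if len(st) == 0:
        raise ValidationError(f"{path}: file contains no model")
    model = AtomicModel(label=str(path))
    gm = st[0]
    for gchain in gm:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            kind = _residue_kind(gres.name)
            res = Residue(
                name=gres.name,
                seq_num=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                kind=kind,
            )
            for ga in gres:
                elem = ga.element.name if ga.element else ga.name[:1]
                res.atoms.append(
                    Atom(
                        element=elem,
                        name=ga.name,
                        coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                        b_factor=ga.b_iso,
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        is_backbone=_classify_backbone(ga.name, kind),
                        is_hydrogen=bool(ga.element.is_hydrogen) if ga.element else False,
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise ValidationError(f"{path}: model contains no atoms")
    return model


def write_model(model: AtomicModel, path: str | Path, fmt: Optional[str] = None) -> Path:
    """Write an :class:`AtomicModel` as PDB or mmCIF (by extension or ``fmt``)."""
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = model.label or "mapqc model"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
            if res.kind != "ligand":
                gres.het_flag = "A"
            else:
                gres.het_flag = "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


# --------------------------------------------------------------------------
# entry metadata


@dataclass
class EntryMetadata:
    """Deposition-level metadata used by the validation metrics.

    recommended_contour_level is in map units; author_resolution in Å;
    molecular_weight in kDa.
    """

    recommended_contour_level: Optional[float] = None
    author_resolution: Optional[float] = None
    molecular_weight: Optional[float] = None
    modality: str = "SPA"

    def __post_init__(self) -> None:
        if self.author_resolution is not None and self.author_resolution <= 0:
            raise ValidationError(f"author_resolution must be > 0, got {self.author_resolution}")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValidationError(f"molecular_weight must be > 0, got {self.molecular_weight}")

    def to_dict(self) -> dict:
        return {
            "recommended_contour_level": self.recommended_contour_level,
            "author_resolution": self.author_resolution,
            "molecular_weight": self.molecular_weight,
            "modality": self.modality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EntryMetadata":
        return cls(
            recommended_contour_level=d.get("recommended_contour_level"),
            author_resolution=d.get("author_resolution"),
            molecular_weight=d.get("molecular_weight"),
            modality=d.get("modality", "SPA"),
        )
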