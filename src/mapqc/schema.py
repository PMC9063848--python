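"""Pydantic schema of the validation report.

The report is the machine-readable data layer of one entry's validation:
every metric block, the image manifest, and a record of the software
version and parameters used.  Reports are validated against this schema on
emission, and the exported JSON schema (``data/report.schema.json``) is the
stable contract for downstream consumers.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MetadataBlock(_Block):
    recommended_contour_level: Optional[float] = None
    author_resolution: Optional[float] = None
    molecular_weight: Optional[float] = None
    modality: str = "SPA"


class SoftwareBlock(_Block):
    name: str
    version: str
    parameters: dict[str, float | int | str | None] = {}


class HistogramBlock(_Block):
    bin_edges: list[float]
    counts: list[int]


class VolumeSweepBlock(_Block):
    levels: list[float]
    volumes_nm3: list[float]
    recommended_level: Optional[float] = None
    volume_at_recommended_nm3: Optional[float] = None
    predicted_volume_nm3: Optional[float] = None


class RapsBlock(_Block):
    frequencies: list[float]
    intensities: list[float]
    n_voxels_per_shell: list[int]


class SliceIndicesBlock(_Block):
    central: dict[str, int]
    max_variance: dict[str, int]


class MapStatisticsBlock(_Block):
    mean: float
    std: float
    min: float
    max: float
    n_voxels: int
    voxel_size: list[float]
    origin: list[float]
    shape: list[int]
    histogram: HistogramBlock
    volume_sweep: VolumeSweepBlock
    raps: Optional[RapsBlock] = None
    slices: SliceIndicesBlock


class FscBlock(_Block):
    frequencies: list[float]
    fsc: list[float]
    n_voxels_per_shell: list[int]
    criteria: dict[str, list[float]]
    resolutions: dict[str, Optional[float]]
    oscillation: dict[str, bool]


class AuthorFscBlock(_Block):
    file: str
    frequencies: list[float]
    fsc: list[float]


class RawMapBlock(_Block):
    mean: float
    std: float
    matched_contour_level: Optional[float] = None


class HalfMapBlock(_Block):
    status: str  # "computed" or "not_computed: <reason>"
    raw_map: Optional[RawMapBlock] = None
    fsc: Optional[FscBlock] = None
    author_fsc: Optional[AuthorFscBlock] = None


class ResidueScoreEntry(_Block):
    chain: str
    seq_num: int
    insertion_code: str
    name: str
    score: float
    n_atoms: int


class InclusionSweepBlock(_Block):
    levels: list[float]
    fraction_all: list[float]
    fraction_backbone: Optional[list[float]] = None


class ResidueInclusionBlock(_Block):
    level: float
    average: float
    per_residue: list[ResidueScoreEntry]
    chunks: list[list[int | str]]


class MapModelFscBlock(_Block):
    fsc: FscBlock
    resolution_fsc_0_5: Optional[float] = None
    simulation_resolution: float


class QScoreBlock(_Block):
    sigma: float
    overall: Optional[float] = None
    per_chain: dict[str, float]
    per_residue: list[ResidueScoreEntry]
    n_atoms_scored: int
    n_unreliable: int


class ModelBlock(_Block):
    file: str
    n_chains: int
    n_residues: int
    n_atoms: int
    model_map_overlap: Optional[str] = None  # none | partial | good
    inclusion_sweep: Optional[InclusionSweepBlock] = None
    residue_inclusion: Optional[ResidueInclusionBlock] = None
    map_model_fsc: Optional[MapModelFscBlock] = None
    q_score: Optional[QScoreBlock] = None
    errors: list[str] = []


class MaskBlock(_Block):
    file: str
    fraction_primary_inside: Optional[float] = None  # above-contour voxels inside mask
    status: str = "computed"


class ImageEntry(_Block):
    file: str
    kind: str  # central_slice | max_variance_slice | projection
    axis: str
    statistic: Optional[str] = None  # mean | std | max for projections
    colour: str  # grayscale | glow
    standardized: bool


class ValidationReportModel(_Block):
    entry_id: str
    software: SoftwareBlock
    metadata: MetadataBlock
    map_statistics: MapStatisticsBlock
    half_map: HalfMapBlock
    models: list[ModelBlock] = []
    masks: list[MaskBlock] = []
    images: list[ImageEntry] = []
    errors: list[str] = []
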