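# Methods

This note records what each metric in `mapqc` computes, the conventions and
numerical choices behind it, what the synthetic fixtures emulate, and the
known limitations.

## Coordinate and volume conventions

A `VoxelGrid` stores density as a `(z, y, x)`-indexed array with a voxel
size `(sx, sy, sz)` in Å/voxel and an `origin` giving the physical position
of the *center* of voxel `(0, 0, 0)`. Voxel `(k, j, i)` therefore sits at
`origin + (i·sx, j·sy, k·sz)`. All coordinates are Å, voxel indices are
0-based, everywhere.

MRC/CCP4 files may store their axes in any of six orders (MAPC/MAPR/MAPS)
and may record their placement either in the ORIGIN header record or as
start indices (NXSTART…). On load, axis order is always normalized to
`(z, y, x)`, and the origin is taken from the ORIGIN record when any
component is nonzero, otherwise as start index × voxel size. Deposited maps
use both conventions; this precedence is a package choice, applied
uniformly, and is what makes the origin-misalignment failure scenario
representable. Modes 0, 1 and 2 are read; mode 2 (32-bit float) is written,
so write→read round trips are bit-exact.

Non-cubic voxels are accepted at load. Fourier-domain metrics (RAPS, FSC)
require approximately isotropic voxels (max/min ≤ 1.01) because spherical
shell binning is ill-defined otherwise; they raise a validation error beyond
that tolerance. Non-cubic *boxes* are zero-padded to cubes before any FFT.

Model files (PDB/mmCIF) keep only what the metrics need. When alternate
conformations are present the first-listed conformer is kept — a
deterministic rule matching common validation practice. Hydrogens are
retained but flagged and excluded from every fit metric; they are invisible
at typical cryo-EM resolutions. Backbone atoms are N, CA, C, O for amino
acids and P, O5′, C5′, C4′, C3′, O3′ for nucleotides; residue kind
(amino-acid / nucleotide / ligand) only affects this classification.

## Map statistics

*Slices and projections.* Central slice index is `floor(n/2)`; the
largest-variance slice maximizes the population (1/N) variance of the
plane, ties broken toward the lowest index. Projections are per-pixel mean,
population standard deviation, or maximum along an axis.

*Histogram.* 128 uniform bins over `[min, max]` with the right-most bin
closed, so counts always sum to the voxel total. A constant map degenerates
to a single unit-width bin. The edge policy is a package choice; only the
bin count is canonical.

*Enclosed volume.* `volume(τ) = |{v : ρ(v) ≥ τ}| · v_voxel` in nm³
(1 nm³ = 1000 Å³), evaluated at 128 levels spanning `(min, max]`. The
threshold is closed (≥) so a binary mask at level 1 encloses exactly its
support. The molecular-weight prediction uses V = m/ρ with
ρ = 1.5 g cm⁻³: 1 kDa ↦ 1000 · 1.66054×10⁻²⁴ g / 1.5 g cm⁻³ ≈ 1.107 nm³.

*RAPS.* `⟨|F|²⟩` per spherical shell of one Fourier voxel (radius binned to
`[k−½, k+½)`), frequency `k/(N·voxel)` up to Nyquist. The volume is used
as-is — no mean subtraction — so shell 0 carries the DC term; rendering
decides how to display it on a log scale. Intensity (|F|², not amplitude)
is reported; the log is left to plotting.

## Half-map analyses

*Raw map.* Voxel-wise mean of the half-maps, then affine rescaling to the
primary map's mean and standard deviation. The rescaling is computed as one
multiply-add (`x·scale + offset`), so a map that already has the reference
moments passes through bit-identically — which makes the
average → scale → contour-match pathway exact when primary and half-maps
coincide.

*Contour matching.* The raw map has no recommended level of its own; it is
assigned the level (drawn from its own voxel values) whose enclosed voxel
count is closest to the primary map's count at the recommended level,
largest level winning ties. If the reference level encloses nothing, a
level just above the map maximum is returned with a warning flag.

*FSC.* `FSC(k) = Re Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²)` over the same shells as
RAPS. DFTs are unnormalized; FSC is normalization-invariant so the
convention is internal. Four criterion curves are attached: constants 0.5
and 0.143, the half-bit information curve
`(0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)`, and `3σ = 3/√(n/2)`, with `n`
the raw per-shell voxel count (no point-group symmetry correction — symmetry
analysis is out of scope). Resolution estimates use the *first* crossing
from low frequency, linearly interpolated between the bracketing shells;
if the curve later re-exceeds the criterion an `oscillation` flag is set,
since such re-crossings usually betray masking or interpolation artefacts
rather than signal. No crossing yields `None` ("beyond Nyquist").
Author-provided FSC curves (two-column text or simple XML) are overlaid in
the report, never recomputed.

## Map/model fit

*Inclusion.* An atom "lies inside the map" at level τ when the trilinearly
interpolated density at its center is ≥ τ. This center-point rule is the
simplest testable reading; no atomic-radius sphere test is applied. Points
outside the box evaluate to −∞, i.e. below any level. The sweep reports
the included fraction of all heavy atoms and of backbone atoms over 128
levels spanning the map range; per-residue scores at the recommended level
map linearly onto a red (0) → cyan (1) ramp and are chunked in groups of
≤ 200 residues per chain for presentation. Inclusion is inherently
contour-dependent — an unrealistically low level yields a deceptive 100% —
which is exactly why the contour-independent Q-score is computed alongside.

*Simulated map.* Each heavy atom contributes an isotropic Gaussian with
integral `occupancy × Z` and variance `σ² = B/(8π²) + (0.225·d)²` for
nominal resolution `d`, truncated at 4.5σ. The factor 0.225 calibrates the
Gaussian so its Fourier amplitude falls to ≈ 50% at frequency `1/d`,
preserving the semantics of the FSC = 0.5 cutoff. This is a deliberate
Gaussian-atom approximation — no electron form factors, no reciprocal-space
model build — adequate for FSC-level comparisons, not for map deposition.

*Map–model FSC.* FSC between the primary map and the simulated map, with
the headline resolution at the 0.5 crossing — a stricter cutoff than 0.143
because the model is not independent of the map.

*Q-score.* For each heavy atom the map is sampled at the atom center and on
20 shells of radius 0.1–2.0 Å. Sampling directions are 8 per shell taken
from a single global golden-spiral (Fibonacci sphere) sequence of 160
points, so consecutive shells probe different directions; the scheme is
deterministic — no RNG — where the original formulation randomizes.
A sample point is discarded if another atom is nearer to it than the atom
being scored, or if it falls outside the box. Q is the Pearson correlation
between the sampled values and the reference profile `exp(−r²/2σ²)`,
σ = 0.6 Å. Correlation is affine-invariant, so the reference amplitude and
any positive rescaling of the map are irrelevant; this is the key contrast
with inclusion scores. Atoms with fewer than 10 usable points are flagged
unreliable and excluded from aggregates; aggregates are arithmetic means of
atom scores (per residue, per chain, overall).

## Synthetic fixtures

The generator emulates just enough structure for every metric to have a
meaningful answer at desk scale; defaults are a 20-residue poly-alanine-like
helix in a 64³ box at 1 Å/voxel (≥ 30 FSC shells, seconds-scale tests),
6 Å nominal resolution, and additive white noise of σ = 0.01 map units
(about 2% of the signal peak — a visibly noisy but clearly interpretable
map). CA positions follow a helical path with exactly 3.8 Å chords;
B-factors are drawn from U[20, 80] Å². The recommended contour level is the
99.5th-percentile voxel value of the primary map, which in these fixtures
sits at a molecular isosurface (atom-center densities all exceed it); the
high/low-contour scenarios move it to the 99.9th / 0.1th percentile.

Half-maps are the clean signal plus independent noise whose per-shell power
is `S(k)·((1−t)/t)·(f_k/f_c)^8` with t = 0.143, so by the FSC–SNR relation
`FSC = SNR/(SNR+1)` the expected FSC is exactly 0.143 at the designed
crossover `f_c` and falls steeply through it (the exponent 8 keeps the
realized crossing within one shell of the design at 64³). The degraded-map
builder uses the same machinery against a noiseless reference, where
`FSC = 1/√(1+N/S)`, placing a designed 0.5 crossing for the map–model FSC.

What the fixtures do **not** emulate: CTF effects, particle statistics,
solvent background, B-factor sharpening artefacts, tomographic missing
wedges, or realistic side-chain chemistry. Passing tests therefore
demonstrate correctness of the *metric computations* and the detectability
of the engineered pathologies, not performance on experimental
reconstructions.

## Report and images

The report is plain JSON, schema-validated (pydantic) on every emission
against the published schema file shipped with the package; floats are
rounded to 6 decimals and identical inputs yield byte-identical output.
Missing optional inputs become explicit `not_computed` entries; a failure
in one metric is recorded and the rest still run. Slices and projections
are written as PNGs at native size and standardized to 300×300
(1200×1200 for tomograms) with aspect-preserving zero padding — padding,
not stretching, so anisotropic boxes are not distorted. The "glow"
false-colour table is generated analytically (black→red→yellow→white
piecewise-linear ramps, 256×3) as a synthetic stand-in for the classic
heated-body palette.

## Known limitations

- Symmetry analysis, motif-library scoring, EMRinger/SMOC/CCC/3DFSC and
  local-resolution estimation are out of scope.
- The simulated map is a Gaussian-atom approximation (see above).
- FSC is computed without masking or phase-randomization corrections;
  estimates on tightly masked experimental maps will be optimistic.
- The half-bit and 3σ criteria use raw shell counts; for symmetric
  reconstructions the effective independent-voxel count is lower and those
  criteria shift accordingly.
- The inclusion test is a center-point rule; atoms partially covered by
  density at their periphery count as outside.
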