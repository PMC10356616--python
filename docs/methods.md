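# Methods

`plantfish` models the computational side of a multiplexed, sequential
single-molecule FISH experiment in whole-mount plant tissue: gene-specific
barcoded SNAIL probe pairs are hybridized to transcripts, circularized by
ligation and amplified in situ into rolling-circle products (RCPs); the
barcodes are then read out over sequential rounds of bridge-probe /
fluorescent detection-probe hybridization, confocal imaging and stripping,
four genes per round (one per channel). Because every gene owns exactly one
(round, channel) slot, decoding an RCP spot is a pure table lookup.

## Probe design

**Windows.** Candidate target windows are enumerated exhaustively (every
start position, every length 40–50 nt) and kept when their GC content lies
in 40–60%. Each window is split into a 5′ padlock half and a 3′ primer half
of 20–25 nt with a fixed 2-nt gap; among all legal splits the one whose two
half melting temperatures are jointly closest to 60 °C is retained, and the
window is discarded if either half falls outside a hard 60 ± 5 °C band.

**Melting temperature.** Tm is computed with the unified nearest-neighbor
model (SantaLucia & Hicks 2004 ΔH/ΔS table, duplex initiation and terminal
A·T penalties), the 0.368·(N−1)·ln[Na+] entropic salt correction, and
Tm = 1000·ΔH / (ΔS + R ln C_T) − 273.15 with defaults of 50 mM monovalent
salt and 100 nM oligo. The implementation is written in-house so the window
scan can evaluate any substring in O(1) from prefix-summed ΔH/ΔS arrays
(~10⁵ Tm evaluations for one transcript); the test suite cross-checks it to
numerical identity against Biopython's `Tm_NN` with the same table.

**Specificity.** Instead of a heuristic homology search, windows are
screened by an exact shared-k-mer test (default k = 15, both strands)
against a background transcriptome. At probe-arm length scales this is
conservative: any alignment capable of supporting stable cross-hybridization
contains a shared 15-mer.

**Selection.** Up to four mutually non-overlapping windows per gene, taken
greedily in order of Tm objective (ties to the smaller start coordinate).
A transcript that cannot host four windows yields fewer, with a flag.

**Oligo assembly.** The padlock is
`[revcomp(plp half) | 6-nt linker | revcomp(barcode, 20 nt) | 6-nt linker |
anchor arm (12 nt)]`; the primer is `[revcomp(primer half) | splint
overhang]`. The overhang concatenates the 6 transcript bases at the 3′ end
of the padlock half with the reverse complement of the anchor arm, so that
the padlock's 5′ terminus and its 3′ anchor arm hybridize to adjacent
overhang segments, juxtaposing the padlock ends nick-to-nick (gap 0) for
ligation. `circularization_gap` verifies this generically: it finds every
primer site of the longest padlock 5′- and 3′-terminal complements, maps the
termini through the antiparallel duplex geometry, and reports the unpaired
bases between them at the closest site combination.

**Codebook.** Genes are assigned to (round, channel) slots in row-major
order (round 1 channels 1–4, then round 2, …), skipping slots beyond a
channel's usable-round limit; the number of rounds is minimized. Capacity is
Σ_channels min(rounds, limit): 7 rounds × 4 channels hold 28 genes, and 14
rounds with one channel usable only through round 8 hold 14+14+14+8 = 50.
Barcodes (20 nt), bridge oligos (30 nt: 15 barcode-complementary + 15
detection-complementary) and per-channel detection oligos (15 nt) come from
a seeded random search under GC 40–60% and pairwise Hamming distance ≥ 8.
The codebook RNG stream is keyed (`default_rng([seed, constant])`) so that
user code seeded with the same small integer cannot replay the identical
base sequence and create systematic barcode/transcript k-mer collisions.

## Synthetic data

The simulator provides ground-truthed inputs for every downstream stage; it
is a test bed, not a biological model.

* **Tissue**: n seeded-Voronoi cells inside a cylindrical mask (nuclei by
  best-candidate sampling, voxels assigned to the nearest nucleus in µm).
  Defaults: 200 cells in a 128×160×160 volume at 0.42 × 0.57 × 0.57 µm
  voxels — cells of roughly 1.4 × 10³ µm³ (~14 µm across), root-tip-like in
  scale. The wall channel is the Gaussian-blurred (σ 0.6 µm) boundary
  indicator plus the tissue rim, peak-normalized, with additive Gaussian
  noise.
* **Expression**: two cell-type programs, each marking half of the 28-gene
  panel; counts are negative binomial (Gamma–Poisson) with marker mean 3.0,
  background mean 0.2 and shape 2.0 — about 45 molecules per cell, the same
  order as real per-cell counts for a panel this size, with strong
  type-specific structure.
* **Imaging**: each molecule renders as a 3D Gaussian of 1 µm FWHM in its
  slot's (round, channel), amplitude 1.0 scaled by a per-round decay of
  0.93^(round−1) (emulating the observed signal loss over rounds) and
  forced to 0 past a channel's usable-round limit (the far-red fluorophore
  dying after round 8). Additive Gaussian noise σ = 0.05 on every channel.
* **Stage perturbations**: per round, a rotation about a random axis
  (≤ 5°), isotropic scale (±2%) and translation (≤ 10 voxels per axis),
  composed about the volume centre in physical µm. Round 1 is the identity
  reference.
* **Ground truth** records every molecule with its cell, slot and reference
  position, the per-(cell, gene) counts, the true affines and the decay
  table. Molecules that a round's stage shift moves outside the acquired
  volume are flagged `in_fov=False`: they emit no signal in that round, so
  evaluation excludes them from recall denominators.

Not emulated: optical PSF physics, autofluorescence and structured
background, incomplete stripping between rounds, probe efficiency
differences between genes, cell-size/expression coupling, and real root
anatomy (cell files, elongation gradients). Passing scores on this
simulator therefore demonstrate the pipeline's geometric and statistical
correctness, not its robustness to every real-data artifact.

## Registration

Each round's wall channel is registered onto round 1 by a global 3D affine
in physical µm. Features are 26-neighbourhood maxima of the negated
scale-normalized LoG (σ = 1 µm) of the wall — wall-junction corners —
thresholded at 25% of the peak response (a relative cut stays comparable
between raw and interpolation-smoothed volumes), up to 1500 strongest, each
described by a z-scored 5×9×9-voxel intensity patch. Matching is mutual
nearest neighbour in descriptor space with a Lowe ratio test (0.9). RANSAC
(2000 iterations, 2 µm inlier tolerance, seeded) repeats 4-point minimal
affine fits, rejects degenerate (near-coplanar) samples, and refits by least
squares on the consensus set, twice. An optional coarse stage (integer
translation from phase correlation) pre-shifts the moving volume to widen
the capture range; the returned transform composes both stages.

Signal volumes are **not** resampled for spot calling: detections are made
on each round's native grid and their coordinates mapped through the
estimated affine into the reference frame. Affine interpolation would both
blur spots and spatially correlate the noise floor, which destabilizes
MAD-based detection thresholds; transforming coordinates is exact.
`apply_transform` (linear resampling through the µm-space affine) remains
for wall volumes and general use.

## Spot calling

Preprocessing per channel: per-xy-plane difference-of-Gaussians bandpass
(lshort = 0.5, llong = 11 pixels), 1D Gaussian z low-pass (σ = 1 voxel,
no truncation threshold), percentile clip (0.5–99.9, computed per volume).
Detection: scale-normalized LoG at 3 geometric scales bracketing the
nominal spot radius (0.5 µm for a 1 µm RCP), anisotropy-corrected per axis;
local maxima over the 26-neighbourhood and adjacent scales; sub-voxel
refinement by per-axis 3-point quadratic fits (clamped to ±0.5 voxel, with
an integer-position fallback on flat, clipped peaks).

The detection threshold is 6 robust sigmas (1.4826 × MAD) of each scale's
own LoG response. Two numerical points matter: finer scales smooth less and
are noisier, so a single shared threshold floods the stack from the finest
scale; and extreme-value statistics of a smoothed Gaussian noise field put
the largest of its ~10⁴–10⁵ local maxima near 4.5σ, so a 3σ cut admits
thousands of false positives while true RCP responses sit at ≥ 30σ under
the default conditions — 6σ leaves wide margins on both sides.

Decoding annotates each spot with the gene owning its (round, channel)
slot. Spots in unused slots — including any round past a channel's usable
limit — are dropped and counted, with a warning for past-limit slots. The
stage contains no randomness. No cross-round duplicate merging is
performed: stripping is assumed complete, so slot exclusivity holds and
residual signal is treated as noise.

## Segmentation

A classical boundary-map + seeded 3D watershed stands in for learned
boundary prediction: the smoothed (σ 0.5 µm) wall intensity, normalized
between its 1st and 99th percentiles (robust to bright junction hotspots),
is the boundary probability; the tissue mask is the Otsu threshold of a
heavily smoothed (σ 4 µm) wall, hole-filled. Seeds are the h-minima basins
(depth 0.1) of the seed-smoothed (σ 1 voxel) probability, restricted below
the boundary threshold (0.3) — h-minima make seeding insensitive to the
absolute wall level, where a bare threshold has a cliff between over- and
under-segmentation. Regions under 64 voxels (~9 µm³, far below any cell)
are merged into the neighbour sharing the largest boundary. Agreement with
the simulator's cells is the contract (adjusted Rand index), not operator
identity with any particular published workflow.

## Quantification and clustering

Spots are assigned to the segmentation label at their nearest voxel; label
0 (extracellular) and out-of-volume spots are kept in the assignment table,
flagged, and excluded from the matrix, so spot counts are conserved end to
end. The cell-by-gene matrix keeps one row per segmented cell (zero rows
included). Cells with fewer than six transcripts are filtered out. Analysis
follows the standard single-cell stack via scanpy: log(1+x), PCA (10
components), kNN graph (5 neighbours), Leiden at resolution 1 (leidenalg
backend, seeded), UMAP for visualization only. Replicate agreement is the
Pearson correlation of log1p(proportion × 10⁴) bulk profiles — a
proportions-with-pseudocount scale chosen here as the documented contract.
Per-cluster summaries are per-gene z-scores of cluster mean log expression.

At resolution 1 Leiden typically subdivides each expression program into
several communities; evaluation therefore uses majority-type purity (and
checks that no cluster mixes programs) rather than demanding exactly one
cluster per program.

## Problem sizes and determinism

The default validation experiment is 200 cells, 28 genes, 7 rounds in a
128×160×160 volume (~3.3 M voxels, ~9 × 10³ molecules) — large enough that
per-slot spot densities and cell sizes are in a realistic regime, while a
full simulate + pipeline cycle stays at a few minutes on one CPU. All
randomness flows from explicit integer seeds (`SeedSequence`-derived child
seeds per stage); identical seeds give bit-identical datasets, transforms
and cluster assignments.

## Known limitations

* Lookup decoding cannot correct a spot detected in the wrong channel or
  round; there is no error-correcting redundancy in one-slot-per-gene
  codebooks.
* Two molecules of the same gene closer than the matching radius merge into
  one detection; recovered counts slightly undercount dense cells.
* The specificity screen is exact-match only; it does not model mismatch
  thermodynamics or secondary structure.
* The affine model cannot absorb non-rigid tissue deformation between
  rounds.
* Segmentation quality degrades for cells only a few voxels across, where
  wall blur floods the interior basin.
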