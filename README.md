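# plantfish

Probe design, simulation and 3D image analysis for **multiplexed sequential
single-molecule FISH in whole-mount plant tissue**.

In this class of experiment, each target transcript is bound by pairs of
DNA probes (SNAIL pairs: a padlock probe plus a primer) carrying a
gene-specific barcode. The padlock is circularized by ligation and
amplified in situ by rolling-circle amplification into a bright ~1 µm DNA
nanoball (RCP). Barcodes are then read out by sequence-by-hybridization:
in each imaging round, four bridge probes couple four barcodes to four
fluorescent detection oligos, the tissue is imaged in 3D on a confocal
(cell-wall stain + 4 signal channels), the probes are stripped, and the
next round reads the next four genes. Each gene therefore owns exactly one
(round, channel) slot, and the codebook capacity is

    capacity = Σ_channels min(n_rounds, usable_rounds(channel))

so 7 rounds × 4 channels read 28 genes, and 14 rounds with one fluorophore
usable only through round 8 read 14 + 14 + 14 + 8 = 50.

`plantfish` implements the full computational workflow for a lab running
such experiments on roots or other whole-mount tissue:

| stage | module | what it does |
|---|---|---|
| probe design | `plantfish.probe_design` | window scan (40–50 nt, GC 40–60%, half-Tm 60 ± 5 °C, 2-nt gap), k-mer specificity screen, 4 non-overlapping SNAIL pairs/gene, barcode + bridge + detection oligos, codebook, order sheets |
| simulation | `plantfish.synth_data` | ground-truthed tissue (Voronoi cells in a cylinder), negative-binomial expression programs, Gaussian RCP spots, per-round affine stage shifts, noise and signal decay |
| registration | `plantfish.registration` | LoG wall-junction features, ratio-test matching, RANSAC 3D affine onto round 1 (physical µm, anisotropic voxels) |
| spot calling | `plantfish.spot_calling` | bandpass + z low-pass + percentile clip, multiscale LoG detection with sub-voxel refinement, (round, channel) lookup decoding |
| segmentation | `plantfish.segmentation` | boundary probability map + h-minima-seeded 3D watershed from the cell-wall channel |
| quantification | `plantfish.quantify_cluster` | spot→cell assignment, cell-by-gene matrix, ≥6-spot cell filter, log1p / PCA(10) / kNN(5) / Leiden(res 1) / UMAP |

A `plantfish` console command exposes each stage (`design`, `simulate`,
`register`, `detect`, `segment`, `quantify`, `cluster`); `plantfish
<command> --help` shows the file interfaces (TIFF stacks, TSV/CSV tables,
MatrixMarket matrices).

## Worked example

Simulate a compact experiment (40 cells, 8 genes → 2 rounds × 4 channels)
and run the whole pipeline against its ground truth:

```python
from plantfish import synth_data as sd
from plantfish.pipeline import run_pipeline
from plantfish import validation as val

exp = sd.simulate_experiment(n_cells=40, n_genes=8, shape=(48, 80, 80), seed=1)
result = run_pipeline(exp.acquisitions, exp.codebook, seed=0)

scores = val.spot_scores(result.spots, exp.truth.true_spots, exp.tissue.voxel_size)
print(f"decoded spots : {len(result.spots)}")
print(f"recall        : {scores.recall:.3f}")
print(f"precision     : {scores.precision:.3f}")
print(f"gene accuracy : {scores.decode_accuracy:.3f}")
print(f"cells found   : {result.mask.n_cells} (simulated: {exp.tissue.n_cells})")
print(f"cells >= 6 spots: {result.filtered.n_cells}")
print(f"clusters      : {result.clusters.cluster.nunique()}")
```

prints

```
decoded spots : 431
recall        : 0.959
precision     : 0.984
gene accuracy : 1.000
cells found   : 44 (simulated: 40)
cells >= 6 spots: 33
clusters      : 4
```

Reading the numbers: of the 525 simulated molecules, those actually imaged
(a per-round stage shift can push edge molecules out of the field of view)
are recovered at 95.9% recall and 98.4% precision within a 1.5-voxel
matching radius, and every matched spot is decoded to the right gene —
lookup decoding is exact once the detection sits in the correct (round,
channel) slot. Watershed finds 44 cells against 40 simulated (a few edge
slivers), 33 of which clear the six-transcript filter, and Leiden splits
them into 4 clusters that align with the two simulated expression programs.

Designing real probes takes FASTA input:

```sh
plantfish design --targets targets.fa --transcriptome txome.fa --out design/
```

which writes `design/order_sheet.tsv` (one row per padlock, primer, bridge
and detection oligo) and `design/codebook.csv` (gene → round, channel,
barcode).

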