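"""Ground-truthed synthetic tissue, expression and multi-round image stacks.

The simulator emulates the test bed the image pipeline needs: a root-tip-like
labeled 3D tissue (seeded Voronoi cells inside a cylinder, cell-wall channel
as a blurred boundary indicator), per-cell gene expression drawn from
negative-binomial cell-type programs, diffraction-limited RCP spots
(~1 µm FWHM at 0.42 x 0.57 x 0.57 µm voxels), per-round affine stage
perturbations, additive Gaussian noise, multiplicative per-round signal
decay, and a far-red channel whose signal vanishes after a configurable
round.

Everything is deterministic per seed; the returned :class:`GroundTruth`
carries the per-(cell, gene) counts, every planted spot with its (round,
channel) slot, the true per-round transforms and the decay table, so each
downstream stage can be scored without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from plantfish.core import DEFAULT_VOXEL_SIZE, AffineTransform3D, RoundAcquisition, VolumeStack
from plantfish.probe_design import Codebook, build_codebook

__all__ = [
    "SyntheticTissue",
    "GroundTruth",
    "generate_tissue",
    "simulate_expression",
    "place_spots",
    "make_decay",
    "make_perturbations",
    "render_rounds",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
    "default_codebook",
    "default_programs",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SyntheticTissue:
    """Labeled tissue: cells partition the cylindrical foreground."""

    label_volume: np.ndarray  # int32, 0 = background
    wall_volume: VolumeStack
    cell_centroids: np.ndarray  # (n_cells, 3) µm, row k -> label k+1
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    @property
    def n_cells(self) -> int:
        return self.cell_centroids.shape[0]

    def cell_voxel_lists(self) -> list[np.ndarray]:
        """Flat voxel indices per cell label (1..n), computed by one sort."""
        flat = self.label_volume.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        out = []
        for label in range(1, self.n_cells + 1):
            lo = np.searchsorted(sorted_labels, label)
            hi = np.searchsorted(sorted_labels, label + 1)
            out.append(order[lo:hi])
        return out


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    genes: list[str]
    true_counts: np.ndarray  # (n_cells, n_genes) int
    cell_types: np.ndarray  # (n_cells,) program names
    true_spots: pd.DataFrame  # gene, cell, z_um, y_um, x_um, round, channel
    round_transforms: dict[int, AffineTransform3D] = field(default_factory=dict)
    decay: dict[int, dict[int, float]] = field(default_factory=dict)


def generate_tissue(
    n_cells: int,
    shape: tuple[int, int, int] = (128, 160, 160),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    cylinder_radius_frac: float = 0.92,
    wall_sigma_um: float = 0.6,
    wall_noise_sd: float = 0.03,
    seed: int = 0,
) -> SyntheticTissue:
    """Seeded-Voronoi cell partition inside a cylindrical mask.

    Cell nuclei positions are drawn by greedy best-candidate sampling (keeps
    cells roughly equal-sized); every foreground voxel is assigned to the
    nearest nucleus in physical µm. The wall channel is a Gaussian-blurred
    boundary indicator (cell-cell walls plus the tissue rim) with additive
    background noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vs = np.asarray(voxel_size)

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = cylinder_radius_frac * min(ny, nx) / 2.0
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    mask = np.broadcast_to(disk, shape)
    fg = np.argwhere(mask)  # (m, 3) voxel coords
    if n_cells > fg.shape[0]:
        raise ValueError(f"n_cells={n_cells} exceeds foreground capacity {fg.shape[0]}")
    fg_um = fg * vs

    # best-candidate (Mitchell) sampling of nuclei in µm space
    first = fg_um[rng.integers(fg_um.shape[0])]
    nuclei = [first]
    for _ in range(1, n_cells):
        cand = fg_um[rng.integers(fg_um.shape[0], size=32)]
        d = np.min(
            np.linalg.norm(cand[:, None, :] - np.asarray(nuclei)[None, :, :], axis=-1), axis=1
        )
        nuclei.append(cand[int(np.argmax(d))])
    nuclei = np.asarray(nuclei)

    tree = cKDTree(nuclei)
    _, nearest = tree.query(fg_um, workers=-1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(fg.T)] = nearest.astype(np.int32) + 1

    centroids = np.asarray(ndimage.center_of_mass(mask, labels, range(1, n_cells + 1))) * vs

    walls = find_boundaries(labels, mode="thick") & mask
    rim = mask & ~ndimage.binary_erosion(mask, iterations=1)
    indicator = (walls | rim).astype(np.float32)
    sigma_vox = wall_sigma_um / vs
    wall = ndimage.gaussian_filter(indicator, sigma=sigma_vox)
    peak = wall.max()
    if peak > 0:
        wall /= peak
    wall += rng.normal(0.0, wall_noise_sd, size=shape).astype(np.float32)
    return SyntheticTissue(
        label_volume=labels,
        wall_volume=VolumeStack(wall.astype(np.float32), tuple(voxel_size)),
        cell_centroids=centroids,
        voxel_size=tuple(voxel_size),
    )


def simulate_expression(
    tissue: SyntheticTissue,
    genes: list[str],
    programs: dict[str, np.ndarray],
    dispersion: float = 2.0,
    cell_types: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial per-cell counts under cell-type expression programs.

    ``programs`` maps type name -> per-gene mean vector. Counts for a cell of
    type t are NB with mean ``programs[t]`` and shape ``dispersion``
    (variance µ + µ²/dispersion), sampled as a Gamma-Poisson mixture. When
    ``cell_types`` is None, types are assigned uniformly at random.
    Returns ``(counts, cell_types)``.
    """
    rng = np.random.default_rng(seed)
    for name, mean in programs.items():
        mean = np.asarray(mean, dtype=float)
        if mean.shape != (len(genes),):
            raise ValueError(f"program {name!r} mean vector length != number of genes")
        if np.any(mean < 0):
            raise ValueError(f"program {name!r} has negative means")
    type_names = list(programs)
    if cell_types is None:
        cell_types = np.asarray(type_names)[rng.integers(len(type_names), size=tissue.n_cells)]
    cell_types = np.asarray(cell_types)
    if cell_types.shape != (tissue.n_cells,):
        raise ValueError("cell_types must have one entry per cell")

    counts = np.zeros((tissue.n_cells, len(genes)), dtype=np.int64)
    for name in type_names:
        idx = np.flatnonzero(cell_types == name)
        if idx.size == 0:
            continue
        mu = np.asarray(programs[name], dtype=float)
        lam = np.zeros((idx.size, len(genes)))
        pos = mu > 0
        if pos.any():
            lam[:, pos] = rng.gamma(dispersion, mu[pos] / dispersion, size=(idx.size, pos.sum()))
        counts[idx] = rng.poisson(lam)
    return counts, cell_types


def place_spots(
    tissue: SyntheticTissue,
    genes: list[str],
    counts: np.ndarray,
    codebook: Codebook,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop each transcript uniformly at random inside its cell's voxels.

    Returns one row per molecule: gene, cell (1-based label), µm position,
    and the gene's (round, channel) slot from the codebook.
    """
    missing = [g for g in genes if g not in codebook.entries]
    if missing:
        raise ValueError(f"genes absent from codebook: {missing}")
    rng = np.random.default_rng(seed)
    vs = np.asarray(tissue.voxel_size)
    shape = tissue.label_volume.shape
    voxel_lists = tissue.cell_voxel_lists()
    rows: list[tuple] = []
    for cell_idx in range(tissue.n_cells):
        voxels = voxel_lists[cell_idx]
        for gene_idx, gene in enumerate(genes):
            n = int(counts[cell_idx, gene_idx])
            if n == 0:
                continue
            chosen = voxels[rng.integers(voxels.size, size=n)]
            zyx = np.column_stack(np.unravel_index(chosen, shape)).astype(float)
            zyx += rng.uniform(-0.5, 0.5, size=zyx.shape)
            pos_um = zyx * vs
            rnd, ch = codebook.entries[gene]
            for p in pos_um:
                rows.append((gene, cell_idx + 1, p[0], p[1], p[2], rnd, ch))
    return pd.DataFrame(
        rows, columns=["gene", "cell", "z_um", "y_um", "x_um", "round", "channel"]
    )


def annotate_fov(
    spots: pd.DataFrame,
    round_transforms: dict[int, AffineTransform3D],
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> pd.DataFrame:
    """Flag each spot by whether its round's stage shift keeps it imaged.

    A molecule planted at reference position p appears in its slot's round r
    at T_r(p); when that falls outside the voxel grid it emits no signal in
    the acquired stack (``in_fov=False``) and no pipeline can recover it.
    """
    out = spots.copy()
    vs = np.asarray(voxel_size)
    lo = -0.5 * vs  # voxel footprints extend half a voxel beyond the centres
    hi = (np.asarray(shape) - 0.5) * vs
    in_fov = np.ones(len(out), dtype=bool)
    pos = out[["z_um", "y_um", "x_um"]].to_numpy()
    for rnd, transform in round_transforms.items():
        sel = (out["round"] == rnd).to_numpy()
        if not sel.any():
            continue
        moved = transform.apply(pos[sel])
        in_fov[sel] = np.all((moved >= lo[None, :]) & (moved < hi[None, :]), axis=1)
    out["in_fov"] = in_fov
    return out


def make_decay(
    n_rounds: int,
    n_channels: int = 4,
    per_round: float = 0.93,
    channel_round_limit: dict[int, int] | None = None,
) -> dict[int, dict[int, float]]:
    """Multiplicative per-round per-channel signal decay.

    ``per_round**(r-1)`` everywhere, forced to 0 for rounds past a channel's
    usable limit (emulating a fluorophore whose signal dies after round L).
    """
    limits = channel_round_limit or {}
    return {
        r: {
            c: (0.0 if limits.get(c) is not None and r > limits[c] else per_round ** (r - 1))
            for c in range(1, n_channels + 1)
        }
        for r in range(1, n_rounds + 1)
    }


def make_perturbations(
    n_rounds: int,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    max_rotation_deg: float = 5.0,
    max_translation_vox: float = 10.0,
    max_scale: float = 0.02,
    seed: int = 0,
) -> dict[int, AffineTransform3D]:
    """Per-round true affines (round 1 = identity), centered on the volume.

    Rotation about a uniformly random axis (angle <= max), isotropic scale
    within ±max_scale, translation uniform within ±max_translation voxels
    per axis — all composed in physical µm space.
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size)
    center = (np.asarray(shape) - 1) * vs / 2.0
    out = {1: AffineTransform3D.identity()}
    for r in range(2, n_rounds + 1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        scale = 1.0 + rng.uniform(-max_scale, max_scale)
        lin = scale * rot
        trans_um = rng.uniform(-max_translation_vox, max_translation_vox, size=3) * vs
        offset = center - lin @ center + trans_um
        out[r] = AffineTransform3D(lin, offset)
    return out


def _render_gaussian_spots(
    volume: np.ndarray,
    positions_vox: np.ndarray,
    amplitudes: np.ndarray,
    sigma_vox: np.ndarray,
) -> None:
    """Add sub-voxel-centered 3D Gaussians in-place (±4σ local patches)."""
    shape = np.asarray(volume.shape)
    half = np.ceil(4.0 * sigma_vox).astype(int)
    for pos, amp in zip(positions_vox, amplitudes):
        lo = np.maximum(np.floor(pos).astype(int) - half, 0)
        hi = np.minimum(np.floor(pos).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = [np.arange(lo[a], hi[a]) - pos[a] for a in range(3)]
        g = [np.exp(-0.5 * (grid / sigma_vox[a]) ** 2) for a, grid in enumerate(grids)]
        patch = amp * g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += patch.astype(volume.dtype)


def render_rounds(
    tissue: SyntheticTissue,
    truth: GroundTruth,
    codebook: Codebook,
    psf_fwhm_um: float = 1.0,
    noise_sd: float = 0.05,
    amplitude: float = 1.0,
    seed: int = 0,
) -> list[RoundAcquisition]:
    """Render every round: transformed wall + Gaussian RCP spots + noise.

    A spot planted at reference position p appears in its slot's round r at
    ``T_r(p)`` (the round's true affine), scaled by ``amplitude *
    decay[r][channel]``; channels past their usable round carry noise only.
    The wall channel is the tissue wall resampled through the same affine.
    """
    from plantfish.registration import apply_transform

    missing = set(truth.true_spots["gene"]) - set(codebook.entries)
    if missing:
        raise ValueError(f"ground-truth genes absent from codebook: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    vs = np.asarray(tissue.voxel_size)
    shape = tissue.label_volume.shape
    sigma_vox = psf_fwhm_um * FWHM_TO_SIGMA / vs
    n_rounds = max(truth.round_transforms)
    n_channels = codebook.n_channels
    spots = truth.true_spots
    acquisitions = []
    for r in range(1, n_rounds + 1):
        transform = truth.round_transforms[r]
        wall = apply_transform(tissue.wall_volume, transform)
        wall_data = wall.data + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
        signal: dict[int, VolumeStack] = {}
        for c in range(1, n_channels + 1):
            vol = np.zeros(shape, dtype=np.float32)
            decay = truth.decay.get(r, {}).get(c, 1.0)
            sel = spots[(spots["round"] == r) & (spots["channel"] == c)]
            if decay > 0 and len(sel):
                pos_um = sel[["z_um", "y_um", "x_um"]].to_numpy()
                pos_vox = transform.apply(pos_um) / vs
                amps = np.full(len(sel), amplitude * decay, dtype=np.float32)
                _render_gaussian_spots(vol, pos_vox, amps, sigma_vox)
            vol += rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
            signal[c] = VolumeStack(vol, tissue.voxel_size)
        acquisitions.append(
            RoundAcquisition(
                round_index=r,
                wall=VolumeStack(wall_data.astype(np.float32), tissue.voxel_size),
                signal=signal,
            )
        )
    return acquisitions


# ---------------------------------------------------------------------------
# default experiment
# ---------------------------------------------------------------------------


def default_genes(n_genes: int = 28) -> list[str]:
    return [f"g{i + 1:02d}" for i in range(n_genes)]


def default_codebook(
    n_genes: int = 28,
    n_channels: int = 4,
    n_rounds: int | None = None,
    channel_round_limit: dict[int, int] | None = None,
    seed: int = 0,
) -> Codebook:
    return build_codebook(
        default_genes(n_genes),
        n_channels=n_channels,
        n_rounds=n_rounds,
        channel_round_limit=channel_round_limit,
        seed=seed,
    )


def default_programs(
    genes: list[str], marker_mean: float = 3.0, background_mean: float = 0.2
) -> dict[str, np.ndarray]:
    """Two cell-type programs, each marking half of the gene panel."""
    n = len(genes)
    a = np.full(n, background_mean)
    a[: n // 2] = marker_mean
    b = np.full(n, background_mean)
    b[n // 2 :] = marker_mean
    return {"typeA": a, "typeB": b}


@dataclass
class SyntheticExperiment:
    tissue: SyntheticTissue
    codebook: Codebook
    truth: GroundTruth
    acquisitions: list[RoundAcquisition]


def simulate_experiment(
    n_cells: int = 200,
    n_genes: int = 28,
    n_rounds: int | None = None,
    n_channels: int = 4,
    channel_round_limit: dict[int, int] | None = None,
    shape: tuple[int, int, int] = (128, 160, 160),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    programs: dict[str, np.ndarray] | None = None,
    dispersion: float = 2.0,
    psf_fwhm_um: float = 1.0,
    noise_sd: float = 0.05,
    decay_per_round: float = 0.93,
    seed: int = 0,
) -> SyntheticExperiment:
    """One fully ground-truthed multi-round experiment with the default knobs.

    Child seeds for tissue, expression, spot placement, perturbations and
    rendering are spawned deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(5)
    seeds = [int(s % (2**31 - 1)) for s in seeds]
    genes = default_genes(n_genes)
    codebook = default_codebook(
        n_genes, n_channels=n_channels, n_rounds=n_rounds, channel_round_limit=channel_round_limit,
        seed=seed,
    )
    tissue = generate_tissue(n_cells, shape=shape, voxel_size=voxel_size, seed=seeds[0])
    progs = programs or default_programs(genes)
    counts, cell_types = simulate_expression(tissue, genes, progs, dispersion, seed=seeds[1])
    spots = place_spots(tissue, genes, counts, codebook, seed=seeds[2])
    rounds_used = codebook.n_rounds
    transforms = make_perturbations(rounds_used, shape, voxel_size, seed=seeds[3])
    spots = annotate_fov(spots, transforms, shape, voxel_size)
    decay = make_decay(rounds_used, n_channels, decay_per_round, codebook.channel_round_limit)
    truth = GroundTruth(
        genes=genes,
        true_counts=counts,
        cell_types=cell_types,
        true_spots=spots,
        round_transforms=transforms,
        decay=decay,
    )
    acquisitions = render_rounds(
        tissue, truth, codebook, psf_fwhm_um=psf_fwhm_um, noise_sd=noise_sd, seed=seeds[4]
    )
    return SyntheticExperiment(tissue=tissue, codebook=codebook, truth=truth, acquisitions=acquisitions)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def write_dataset(experiment: SyntheticExperiment, out_dir) -> Path:
    """Write TIFF stacks (`r{round}_c{channel}.tif`, c0 = wall), truth tables
    and a JSON manifest. Arrays round-trip bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for acq in experiment.acquisitions:
        name = f"r{acq.round_index}_c0.tif"
        tifffile.imwrite(out / name, acq.wall.data)
        files.append(name)
        for ch, vol in sorted(acq.signal.items()):
            name = f"r{acq.round_index}_c{ch}.tif"
            tifffile.imwrite(out / name, vol.data)
            files.append(name)
    tifffile.imwrite(out / "labels.tif", experiment.tissue.label_volume)
    truth = experiment.truth
    truth.true_spots.to_csv(out / "true_spots.tsv", sep="\t", index=False)
    pd.DataFrame(truth.true_counts, columns=truth.genes).assign(
        cell=np.arange(1, truth.true_counts.shape[0] + 1), cell_type=truth.cell_types
    ).to_csv(out / "true_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [[r, *t.as_flat()] for r, t in sorted(truth.round_transforms.items())],
        columns=["round"] + [f"p{i}" for i in range(12)],
    ).to_csv(out / "true_transforms.csv", index=False)
    pd.DataFrame(
        [(r, c, m) for r, row in truth.decay.items() for c, m in row.items()],
        columns=["round", "channel", "multiplier"],
    ).to_csv(out / "decay.csv", index=False)
    from plantfish.probe_design import write_codebook_csv

    write_codebook_csv(experiment.codebook, out / "codebook.csv")
    manifest = {
        "voxel_size_um": list(experiment.tissue.voxel_size),
        "shape": list(experiment.tissue.label_volume.shape),
        "n_rounds": len(experiment.acquisitions),
        "n_channels": experiment.codebook.n_channels,
        "channel_round_limit": experiment.codebook.channel_round_limit,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(in_dir) -> tuple[list[RoundAcquisition], dict]:
    """Load the TIFF stacks of a written dataset back into acquisitions."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    voxel_size = tuple(manifest["voxel_size_um"])
    acquisitions = []
    for r in range(1, manifest["n_rounds"] + 1):
        wall = VolumeStack(tifffile.imread(src / f"r{r}_c0.tif"), voxel_size)
        signal = {
            c: VolumeStack(tifffile.imread(src / f"r{r}_c{c}.tif"), voxel_size)
            for c in range(1, manifest["n_channels"] + 1)
        }
        acquisitions.append(RoundAcquisition(round_index=r, wall=wall, signal=signal))
    return acquisitions, manifest
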