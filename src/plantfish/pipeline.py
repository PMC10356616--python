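"""End-to-end orchestration: rounds of images -> clustered cell-by-gene data.

Thin glue over the stage modules, in the order a real experiment is
processed: register every round onto round 1, preprocess + detect + decode
spots per (round, channel), segment cells from the round-1 wall, assign
spots to cells, build and filter the count matrix, and cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from plantfish.core import AffineTransform3D, RoundAcquisition
from plantfish.probe_design import Codebook
from plantfish.quantify_cluster import (
    CellByGeneMatrix,
    ClusterResult,
    assign_spots,
    build_matrix,
    embed_and_cluster,
    filter_cells,
)
from plantfish.registration import register_rounds
from plantfish.segmentation import SegmentationMask, segment_wall
from plantfish.spot_calling import decode_spots, detect_round, spots_to_frame

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    transforms: dict[int, AffineTransform3D]
    spots: pd.DataFrame  # decoded spots in the round-1 frame
    dropped_slots: dict[tuple[int, int], int]
    mask: SegmentationMask
    assignments: pd.DataFrame
    matrix: CellByGeneMatrix  # unfiltered
    filtered: CellByGeneMatrix
    clusters: ClusterResult | None = None
    raw_spots: dict = field(default_factory=dict, repr=False)


def run_pipeline(
    acquisitions: list[RoundAcquisition],
    codebook: Codebook,
    seed: int = 0,
    min_spots: int = 6,
    spot_diameter_um: float = 1.0,
    threshold_factor: float = 6.0,
    cluster: bool = True,
    n_pcs: int = 10,
    n_neighbors: int = 5,
    resolution: float = 1.0,
) -> PipelineResult:
    """Run registration, spot calling, segmentation and quantification."""
    transforms = register_rounds(acquisitions, seed=seed)
    raw: dict[tuple[int, int], pd.DataFrame] = {}
    for acq in acquisitions:
        raw.update(
            detect_round(
                acq,
                transforms[acq.round_index],
                spot_diameter_um=spot_diameter_um,
                threshold_factor=threshold_factor,
            )
        )
    decoded, dropped = decode_spots(raw, codebook)
    spots = spots_to_frame(decoded)
    mask = segment_wall(acquisitions[0].wall)
    assignments = assign_spots(spots, mask)
    matrix = build_matrix(assignments, codebook.genes(), mask)
    filtered = filter_cells(matrix, min_spots=min_spots)
    clusters = None
    if cluster and filtered.n_cells >= n_neighbors + 1:
        clusters = embed_and_cluster(
            filtered, n_pcs=n_pcs, n_neighbors=n_neighbors, resolution=resolution, seed=seed
        )
    return PipelineResult(
        transforms=transforms,
        spots=spots,
        dropped_slots=dropped,
        mask=mask,
        assignments=assignments,
        matrix=matrix,
        filtered=filtered,
        clusters=clusters,
        raw_spots=raw,
    )
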