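"""Scoring of pipeline outputs against simulator ground truth.

Spot detections are matched to planted spots by minimum-cost bipartite
(Hungarian) assignment within a matching radius expressed in voxel units
(each axis divided by its voxel size before the Euclidean norm), per
(round, channel) slot so the matching itself never uses gene identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from plantfish.core import AffineTransform3D

__all__ = [
    "match_spots",
    "spot_scores",
    "transform_landmark_error",
    "segmentation_ari",
    "cluster_purity",
    "gene_total_spearman",
    "assignment_accuracy",
]


def _to_voxel_units(frame: pd.DataFrame, voxel_size) -> np.ndarray:
    return frame[["z_um", "y_um", "x_um"]].to_numpy() / np.asarray(voxel_size)


def match_spots(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    voxel_size,
    radius_vox: float = 1.5,
) -> pd.DataFrame:
    """Hungarian matching of detections to true spots within ``radius_vox``.

    Both tables need z_um/y_um/x_um plus round and channel columns; matching
    is performed independently per (round, channel). Returns one row per
    match with detected and truth indices and the distance (voxel units).
    """
    rows = []
    for (rnd, ch), det in detected.groupby(["round", "channel"]):
        tru = truth[(truth["round"] == rnd) & (truth["channel"] == ch)]
        if len(det) == 0 or len(tru) == 0:
            continue
        d = np.linalg.norm(
            _to_voxel_units(det, voxel_size)[:, None, :]
            - _to_voxel_units(tru, voxel_size)[None, :, :],
            axis=-1,
        )
        cost = np.where(d <= radius_vox, d, 1e6)
        det_idx, tru_idx = linear_sum_assignment(cost)
        ok = d[det_idx, tru_idx] <= radius_vox
        for di, ti in zip(det_idx[ok], tru_idx[ok]):
            rows.append((rnd, ch, det.index[di], tru.index[ti], d[di, ti]))
    return pd.DataFrame(
        rows, columns=["round", "channel", "detected_index", "truth_index", "distance_vox"]
    )


@dataclass
class SpotScores:
    recall: float
    precision: float
    decode_accuracy: float
    n_detected: int
    n_truth: int
    n_matched: int


def spot_scores(
    decoded: pd.DataFrame,
    truth: pd.DataFrame,
    voxel_size,
    radius_vox: float = 1.5,
) -> SpotScores:
    """Recall, precision and decoded-gene accuracy of matched spots.

    When the truth table carries an ``in_fov`` column, spots whose round's
    stage shift moved them outside the acquired volume (never imaged, hence
    unrecoverable) are excluded from both matching and the recall
    denominator.
    """
    if "in_fov" in truth.columns:
        truth = truth[truth["in_fov"]]
    matches = match_spots(decoded, truth, voxel_size, radius_vox)
    n_matched = len(matches)
    recall = n_matched / len(truth) if len(truth) else 0.0
    precision = n_matched / len(decoded) if len(decoded) else 0.0
    if n_matched:
        det_genes = decoded.loc[matches["detected_index"], "gene"].to_numpy()
        true_genes = truth.loc[matches["truth_index"], "gene"].to_numpy()
        accuracy = float(np.mean(det_genes == true_genes))
    else:
        accuracy = 0.0
    return SpotScores(
        recall=float(recall),
        precision=float(precision),
        decode_accuracy=accuracy,
        n_detected=len(decoded),
        n_truth=len(truth),
        n_matched=n_matched,
    )


def transform_landmark_error(
    estimated: AffineTransform3D,
    true_round_transform: AffineTransform3D,
    landmarks_um: np.ndarray,
    voxel_size,
) -> float:
    """Mean voxel-unit landmark discrepancy between estimated and true maps.

    The estimated registration maps round-r coordinates back to the
    reference; the truth maps reference to round r, so the estimate is
    compared with the truth's inverse on the given reference landmarks.
    """
    expected = true_round_transform.inverse()
    moved = true_round_transform.apply(landmarks_um)
    diff = (estimated.apply(moved) - expected.apply(moved)) / np.asarray(voxel_size)
    return float(np.mean(np.linalg.norm(diff, axis=1)))


def segmentation_ari(predicted_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Adjusted Rand index over voxels inside the true foreground."""
    fg = true_labels > 0
    return float(adjusted_rand_score(true_labels[fg].ravel(), predicted_labels[fg].ravel()))


def cluster_purity(clusters, true_types) -> float:
    """Weighted majority-type purity of a clustering against true types."""
    df = pd.DataFrame({"cluster": np.asarray(clusters), "type": np.asarray(true_types)})
    if len(df) == 0:
        return 0.0
    majority = df.groupby("cluster")["type"].agg(lambda s: s.value_counts().iloc[0]).rename("n")
    return float(majority.sum() / len(df))


def map_labels_by_overlap(predicted: np.ndarray, truth: np.ndarray) -> pd.Series:
    """Map each predicted label to the true label it overlaps most."""
    both = (predicted > 0) & (truth > 0)
    pairs = pd.DataFrame({"p": predicted[both].ravel(), "t": truth[both].ravel()})
    return pairs.groupby("p")["t"].agg(lambda s: s.value_counts().index[0])


def gene_total_spearman(recovered: pd.Series, truth: pd.Series) -> float:
    """Spearman correlation of per-gene totals, aligned on gene names."""
    aligned = pd.concat([recovered, truth], axis=1, join="inner")
    rho, _ = spearmanr(aligned.iloc[:, 0], aligned.iloc[:, 1])
    return float(rho)


def assignment_accuracy(
    assignments: pd.DataFrame,
    matches: pd.DataFrame,
    truth: pd.DataFrame,
) -> float:
    """Fraction of matched true-positive spots assigned to their true cell."""
    if len(matches) == 0:
        return 0.0
    assigned_cell = assignments.loc[matches["detected_index"], "cell"].to_numpy()
    true_cell = truth.loc[matches["truth_index"], "cell"].to_numpy()
    return float(np.mean(assigned_cell == true_cell))
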