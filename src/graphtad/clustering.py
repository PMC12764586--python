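"""Density clustering of embedded bins and conversion to candidate domains.

Embedding rows are clustered with HDBSCAN (mutual-reachability single
linkage + cluster-stability extraction; scikit-learn implementation).
Clusters live in embedding space and need not be genomically contiguous,
but a TAD is an interval: each maximal run of consecutive bins sharing a
non-noise label becomes one candidate, and candidates outside the
100 Kb - 5 Mb mammalian TAD size range are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.metrics import pairwise_distances

from .embedding import EmbeddingMatrix
from .io import TadInterval
from .partition import SubmatrixWindow

__all__ = [
    "ClusterConfig",
    "mutual_reachability",
    "hdbscan_cluster",
    "labels_to_candidates",
    "filter_by_size",
]

MIN_TAD_BP = 100_000
MAX_TAD_BP = 5_000_000


@dataclass(frozen=True)
class ClusterConfig:
    """HDBSCAN parameters (Euclidean metric is fixed)."""

    min_cluster_size: int = 5
    min_samples: int | None = None

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")

    @property
    def effective_min_samples(self) -> int:
        return self.min_samples if self.min_samples is not None \
            else self.min_cluster_size


def mutual_reachability(points: np.ndarray, min_samples: int) -> np.ndarray:
    """All-pairs mutual-reachability distance matrix.

    The core distance of a point is the Euclidean distance to its k-th
    nearest *other* point (k = ``min_samples``); the mutual reachability
    of a pair is the maximum of both core distances and their direct
    distance.  The diagonal is zero by convention.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples >= n:
        raise ValueError(
            f"min_samples={min_samples} must be < number of points ({n})"
        )
    d = pairwise_distances(pts, metric="euclidean")
    # k-th nearest other point: drop self-distance column-wise via sort
    core = np.sort(d, axis=1)[:, min_samples]
    mr = np.maximum(d, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(mr, 0.0)
    return mr


def hdbscan_cluster(
    emb: EmbeddingMatrix, cfg: ClusterConfig | None = None
) -> np.ndarray:
    """Per-bin cluster labels over the window's extended range.

    Inactive (unembedded) bins are labeled -1; windows with fewer active
    bins than ``min_cluster_size`` are all noise.
    """
    cfg = cfg or ClusterConfig()
    labels = np.full(emb.n_nodes, -1, dtype=int)
    if emb.m_active < cfg.min_cluster_size:
        return labels
    if np.ptp(emb.vectors, axis=0).max(initial=0.0) == 0.0:
        # coincident points: one maximally dense cluster
        labels[emb.bin_index] = 0
        return labels
    clusterer = HDBSCAN(
        min_cluster_size=cfg.min_cluster_size,
        min_samples=cfg.effective_min_samples,
        metric="euclidean",
        copy=True,
    )
    row_labels = clusterer.fit_predict(emb.vectors)
    labels[emb.bin_index] = row_labels
    return labels


def labels_to_candidates(
    labels: np.ndarray,
    window: SubmatrixWindow,
    resolution: int,
    chrom: str = ".",
) -> list[TadInterval]:
    """Maximal runs of consecutive equal non-noise labels, as intervals.

    Coordinates are absolute: label position 0 corresponds to the
    window's extended start bin.  Noise (-1) breaks runs.
    """
    labels = np.asarray(labels)
    if len(labels) != window.ext_len:
        raise ValueError(
            f"{len(labels)} labels for a {window.ext_len}-bin window"
        )
    out: list[TadInterval] = []
    start = 0
    for pos in range(1, len(labels) + 1):
        if pos < len(labels) and labels[pos] == labels[start]:
            continue
        if labels[start] != -1:
            out.append(
                TadInterval(
                    chrom=chrom,
                    start_bin=window.ext_start_bin + start,
                    end_bin=window.ext_start_bin + pos,
                    resolution=resolution,
                    source_window=window.index,
                    cluster_label=int(labels[start]),
                )
            )
        start = pos
    return out


def filter_by_size(
    candidates: list[TadInterval],
    min_bp: int = MIN_TAD_BP,
    max_bp: int = MAX_TAD_BP,
) -> list[TadInterval]:
    """Keep candidates whose bp span lies in the closed range [min_bp, max_bp]."""
    if min_bp > max_bp:
        raise ValueError(f"min_bp {min_bp} > max_bp {max_bp}")
    return [t for t in candidates if min_bp <= t.span_bp <= max_bp]
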