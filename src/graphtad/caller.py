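"""Scikit-learn-style estimators wiring the full domain-calling pipeline.

``TadCaller`` is a clusterer over the bins of a single-chromosome contact
matrix: ``fit(X)`` partitions the matrix into overlapping windows,
smooths, embeds (NetMF), clusters (HDBSCAN), converts label runs to
candidate intervals, filters by size and stitches the windows into a
final sorted, non-overlapping domain set (``tads_``; per-bin labels in
``labels_``).  ``NetMFEmbedding`` exposes the embedding stage alone as a
transformer.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .clustering import (
    MAX_TAD_BP,
    MIN_TAD_BP,
    ClusterConfig,
    filter_by_size,
    hdbscan_cluster,
    labels_to_candidates,
)
from .embedding import NetMFConfig, netmf_embed
from .io import ContactMatrix, TadSet
from .partition import (
    DEFAULT_OVERLAP_BP,
    DEFAULT_THRESHOLD_BINS,
    extract_submatrix,
    gaussian_smooth,
    plan_partition,
)
from .stitching import assemble_genome_tads

logger = logging.getLogger(__name__)

__all__ = ["TadCaller", "NetMFEmbedding", "call_tads"]


class NetMFEmbedding(TransformerMixin, BaseEstimator):
    """Closed-form DeepWalk-matrix embedding of a weighted adjacency.

    ``fit_transform(X)`` takes a symmetric non-negative square matrix and
    returns an (n, e_eff) array of node vectors; zero-degree nodes get
    zero vectors (they carry no edges to embed).

    Parameters
    ----------
    dim : target embedding size (default 455).
    window : random-walk context window (default 2).
    neg : negative-sampling constant (default 1).
    variant : "auto" | "exact-small" | "approx-large".
    rank : eigenpairs kept on the approximate path (default 256).
    """

    def __init__(self, dim: int = 455, window: int = 2, neg: int = 1,
                 variant: str = "auto", rank: int = 256):
        self.dim = dim
        self.window = window
        self.neg = neg
        self.variant = variant
        self.rank = rank

    def _config(self) -> NetMFConfig:
        return NetMFConfig(dim=self.dim, window=self.window, neg=self.neg,
                           variant=self.variant, rank=self.rank)

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        emb = netmf_embed(X, self._config())
        out = np.zeros((X.shape[0], max(emb.e_eff, 1)))
        if emb.m_active:
            out[emb.bin_index] = emb.vectors
        self.embedding_ = out
        self.active_mask_ = np.zeros(X.shape[0], dtype=bool)
        self.active_mask_[emb.bin_index] = True
        self.e_eff_ = emb.e_eff
        self.n_features_in_ = X.shape[1]
        return out

    def transform(self, X):
        check_is_fitted(self, "embedding_")
        return self.fit_transform(X)


class TadCaller(ClusterMixin, BaseEstimator):
    """Call topologically associating domains from a Hi-C contact matrix.

    Parameters
    ----------
    resolution : bin width in bp (default 10_000); ignored when ``fit``
        receives a :class:`ContactMatrix`, which carries its own.
    chrom : chromosome name used when ``fit`` receives a bare array.
    t : window threshold in bins (default 5000); matrices wider than this
        are processed in ``ceil(n/t)`` overlapping windows.
    q_bp : left/top window overlap in bp (default 3 Mb).
    sigma : Gaussian smoothing width in bins (default 1.0; 0 disables).
    dim, window, neg, variant, rank : embedding parameters, see
        :class:`NetMFEmbedding`.
    min_cluster_size, min_samples : HDBSCAN density parameters.
    min_tad_bp, max_tad_bp : closed size-filter bounds
        (defaults 100 Kb and 5 Mb).

    Attributes
    ----------
    tads_ : TadSet — final sorted, non-overlapping domain calls.
    labels_ : (n_bins,) int array — index of the domain containing each
        bin, -1 outside every domain.
    plan_ : PartitionPlan used for windowing.
    q_records_ : per-overlap-region adjudication records.
    """

    def __init__(
        self,
        resolution: int = 10_000,
        chrom: str = ".",
        t: int = DEFAULT_THRESHOLD_BINS,
        q_bp: int = DEFAULT_OVERLAP_BP,
        sigma: float = 1.0,
        dim: int = 455,
        window: int = 2,
        neg: int = 1,
        variant: str = "auto",
        rank: int = 256,
        min_cluster_size: int = 5,
        min_samples: int | None = None,
        min_tad_bp: int = MIN_TAD_BP,
        max_tad_bp: int = MAX_TAD_BP,
    ):
        self.resolution = resolution
        self.chrom = chrom
        self.t = t
        self.q_bp = q_bp
        self.sigma = sigma
        self.dim = dim
        self.window = window
        self.neg = neg
        self.variant = variant
        self.rank = rank
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.min_tad_bp = min_tad_bp
        self.max_tad_bp = max_tad_bp

    def _as_contact_matrix(self, X) -> ContactMatrix:
        if isinstance(X, ContactMatrix):
            return X
        X = np.asarray(X, dtype=float)
        return ContactMatrix(
            chrom=self.chrom, resolution=self.resolution,
            values=(X + X.T) / 2.0,
        )

    def fit(self, X, y=None):
        """Run the full pipeline on a square contact matrix."""
        cm = self._as_contact_matrix(X)
        plan = plan_partition(cm.n_bins, cm.resolution, t=self.t, q_bp=self.q_bp)
        logger.info("%s", plan)
        netmf_cfg = NetMFConfig(dim=self.dim, window=self.window, neg=self.neg,
                                variant=self.variant, rank=self.rank)
        cluster_cfg = ClusterConfig(min_cluster_size=self.min_cluster_size,
                                    min_samples=self.min_samples)
        per_window = []
        self.e_eff_ = []
        for w in plan.windows:
            sub = gaussian_smooth(extract_submatrix(cm, w), sigma=self.sigma)
            emb = netmf_embed(sub, netmf_cfg)
            self.e_eff_.append(emb.e_eff)
            if emb.m_active == 0:
                per_window.append([])
                continue
            labels = hdbscan_cluster(emb, cluster_cfg)
            cands = labels_to_candidates(labels, w, cm.resolution, chrom=cm.chrom)
            per_window.append(
                filter_by_size(cands, self.min_tad_bp, self.max_tad_bp)
            )
        tads, records = assemble_genome_tads(cm, per_window, plan)
        self.tads_ = tads
        self.q_records_ = records
        self.plan_ = plan
        labels = np.full(cm.n_bins, -1, dtype=int)
        for k, tad in enumerate(tads):
            labels[tad.start_bin:tad.end_bin] = k
        self.labels_ = labels
        self.n_features_in_ = cm.n_bins
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def call_tads(
    cm: ContactMatrix,
    **params,
) -> TadSet:
    """Functional wrapper: run :class:`TadCaller` and return the TadSet."""
    return TadCaller(**params).fit(cm).tads_
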