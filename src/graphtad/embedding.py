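"""Closed-form network embedding of a contact sub-matrix (NetMF).

A smoothed sub-matrix is treated as a weighted graph: bins are nodes and
interaction frequencies edge weights.  NetMF factorizes the matrix that
random-walk skip-gram (DeepWalk) implicitly factorizes,

    chi = vol(G) / (b * T) * (sum_{r=1..T} P^r) * D^-1,     P = D^-1 A,

where ``T`` is the context window, ``b`` the negative-sampling constant,
``D`` the degree matrix and ``vol(G)`` the total edge weight.  For large
windows the same matrix is approximated through the top-``h`` eigenpairs
of the normalized adjacency ``D^-1/2 A D^-1/2``.  The embedding is the
rank-``a`` factorization of ``log max(chi, 1)`` (shifted-PPMI floor), with
node vectors ``U_a sqrt(Sigma_a)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "NetMFConfig",
    "EmbeddingMatrix",
    "EmptyGraphError",
    "matrix_to_graph",
    "deepwalk_matrix_exact",
    "deepwalk_matrix_approx",
    "shifted_log_factorize",
    "netmf_embed",
]

DEFAULT_EMBEDDING_DIM = 455
EXACT_VARIANT_MAX_NODES = 4000
EXACT_VARIANT_MAX_WINDOW = 4


class EmptyGraphError(ValueError):
    """Raised when a sub-matrix has no edges at all (vol(G) == 0)."""


@dataclass
class WeightedGraph:
    """Undirected weighted graph over the bins of one sub-matrix.

    ``adjacency`` keeps all m nodes (zero-degree rows included);
    ``active_nodes`` indexes the nodes with positive degree, which are the
    only ones that can be embedded (the random-walk transition matrix is
    undefined at degree zero).
    """

    adjacency: np.ndarray
    degrees: np.ndarray
    vol: float
    active_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m_active(self) -> int:
        return len(self.active_nodes)


@dataclass(frozen=True)
class NetMFConfig:
    """Embedding hyperparameters.

    dim
        Target embedding size ``e`` (default 455); clamped to the rank of
        the factored matrix on small sub-matrices.
    window
        Random-walk context window ``T`` (default 2).
    neg
        Negative-sampling constant ``b`` (default 1).
    variant
        ``"exact-small"`` computes the DeepWalk matrix by dense powers;
        ``"approx-large"`` uses the top-``rank`` eigenpairs; ``"auto"``
        picks per sub-matrix size.
    rank
        Eigenpairs kept on the approximate path (default 256).
    """

    dim: int = DEFAULT_EMBEDDING_DIM
    window: int = 2
    neg: int = 1
    variant: str = "auto"
    rank: int = 256

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.neg < 1 or self.rank < 1:
            raise ValueError("dim, window, neg and rank must all be >= 1")
        if self.variant not in ("auto", "exact-small", "approx-large"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class EmbeddingMatrix:
    """Node vectors for the active bins of one window.

    ``vectors`` is (m_active, e_eff); ``bin_index[r]`` is the window-local
    bin the r-th row describes.
    """

    vectors: np.ndarray
    bin_index: np.ndarray
    n_nodes: int = 0

    @property
    def e_eff(self) -> int:
        return self.vectors.shape[1] if self.vectors.size else 0

    @property
    def m_active(self) -> int:
        return self.vectors.shape[0]


def matrix_to_graph(m: np.ndarray, keep_diagonal: bool = False) -> WeightedGraph:
    """Build the weighted graph of a (smoothed) sub-matrix.

    Self-contacts carry no pairwise proximity, so the diagonal is zeroed
    unless ``keep_diagonal`` is set.  An all-zero adjacency raises
    :class:`EmptyGraphError` — the window yields no TADs.
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T):
        raise ValueError("sub-matrix must be symmetric")
    if (a < 0).any():
        raise ValueError("negative edge weights")
    a = (a + a.T) / 2.0
    if not keep_diagonal:
        a = a.copy()
        np.fill_diagonal(a, 0.0)
    degrees = a.sum(axis=1)
    vol = float(degrees.sum())
    if vol == 0:
        raise EmptyGraphError("graph has no edges")
    active = np.flatnonzero(degrees > 0)
    return WeightedGraph(adjacency=a, degrees=degrees, vol=vol, active_nodes=active)


def _active_block(g: WeightedGraph) -> tuple[np.ndarray, np.ndarray]:
    idx = g.active_nodes
    return g.adjacency[np.ix_(idx, idx)], g.degrees[idx]


def deepwalk_matrix_exact(g: WeightedGraph, cfg: NetMFConfig) -> np.ndarray:
    """DeepWalk matrix by direct dense powers, over active nodes.

    chi = vol/(b*T) * (sum_{r=1..T} (D^-1 A)^r) * D^-1, symmetrized to
    remove floating-point skew before the log step.
    """
    a, deg = _active_block(g)
    inv_d = 1.0 / deg
    p = a * inv_d[:, None]          # D^-1 A
    acc = np.zeros_like(p)
    pr = np.eye(len(deg))
    for _ in range(cfg.window):
        pr = pr @ p
        acc += pr
    chi = (g.vol / (cfg.neg * cfg.window)) * (acc * inv_d[None, :])
    return (chi + chi.T) / 2.0


def deepwalk_matrix_approx(g: WeightedGraph, cfg: NetMFConfig) -> np.ndarray:
    """Eigen-approximated DeepWalk matrix (large-window path).

    Top-``h`` eigenpairs (largest |lambda|) of D^-1/2 A D^-1/2 give
    chi_hat = vol/b * D^-1/2 U_h (1/T sum_r Lambda_h^r) U_h^T D^-1/2.
    With a full eigenbasis this reproduces the exact matrix.
    """
    a, deg = _active_block(g)
    m = len(deg)
    h = cfg.rank
    if h > m:
        warnings.warn(
            f"rank {h} exceeds {m} active nodes; clamping", stacklevel=2
        )
        h = m
    inv_sqrt_d = 1.0 / np.sqrt(deg)
    norm_adj = a * inv_sqrt_d[:, None] * inv_sqrt_d[None, :]
    evals, evecs = linalg.eigh(norm_adj)
    # keep the h eigenpairs with largest magnitude
    order = np.argsort(-np.abs(evals), kind="stable")[:h]
    lam = evals[order]
    u = evecs[:, order]
    lam_sum = np.zeros_like(lam)
    lam_pow = np.ones_like(lam)
    for _ in range(cfg.window):
        lam_pow = lam_pow * lam
        lam_sum += lam_pow
    core = (u * (lam_sum / cfg.window)[None, :]) @ u.T
    chi = (g.vol / cfg.neg) * (core * inv_sqrt_d[:, None] * inv_sqrt_d[None, :])
    return (chi + chi.T) / 2.0


def _signed_magnitude_order(evals: np.ndarray) -> np.ndarray:
    """Sort eigenpairs by |lambda| descending; positive wins magnitude ties."""
    return np.lexsort((-np.sign(evals), -np.abs(evals)))


def shifted_log_factorize(chi: np.ndarray, dim: int) -> tuple[np.ndarray, int]:
    """Shifted-PPMI floor, elementwise log, rank-``a`` factorization.

    L = log(max(chi, 1)) is symmetric PSD-agnostic; its SVD is obtained
    from the symmetric eigendecomposition (singular values |lambda|,
    left vectors the eigenvectors), which is deterministic and keeps the
    column-sign convention platform-stable.  Returns (embedding, e_eff)
    with embedding = U_a sqrt(Sigma_a).
    """
    chi = np.asarray(chi, dtype=float)
    if not np.isfinite(chi).all():
        raise ValueError("non-finite entries in DeepWalk matrix")
    m = chi.shape[0]
    log_chi = np.log(np.maximum(chi, 1.0))
    log_chi = (log_chi + log_chi.T) / 2.0
    if not log_chi.any():
        warnings.warn(
            "log-shifted matrix is identically zero; embedding collapses",
            stacklevel=2,
        )
        return np.zeros((m, 1)), 0
    evals, evecs = linalg.eigh(log_chi)
    order = _signed_magnitude_order(evals)
    sigma = np.abs(evals[order])
    u = evecs[:, order]
    tol = m * np.finfo(float).eps * sigma[0]
    rank = int((sigma > tol).sum())
    e_eff = max(1, min(dim, rank, m - 1)) if m > 1 else min(dim, rank)
    e_eff = min(e_eff, rank)
    if e_eff == 0:
        warnings.warn("factored matrix has rank 0; zero embedding", stacklevel=2)
        return np.zeros((m, 1)), 0
    u = u[:, :e_eff]
    # fixed sign convention: the largest-|entry| component of each
    # singular vector is made positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(e_eff)])
    flip[flip == 0] = 1.0
    u = u * flip[None, :]
    emb = u * np.sqrt(sigma[:e_eff])[None, :]
    return emb, e_eff


def _choose_variant(cfg: NetMFConfig, m_active: int) -> str:
    if cfg.variant != "auto":
        return cfg.variant
    if m_active <= EXACT_VARIANT_MAX_NODES and cfg.window <= EXACT_VARIANT_MAX_WINDOW:
        return "exact-small"
    return "approx-large"


def netmf_embed(m: np.ndarray, cfg: NetMFConfig | None = None) -> EmbeddingMatrix:
    """Embed a smoothed sub-matrix; empty graphs yield an empty embedding."""
    cfg = cfg or NetMFConfig()
    try:
        g = matrix_to_graph(m)
    except EmptyGraphError:
        logger.info("sub-matrix has no edges; skipping embedding")
        return EmbeddingMatrix(
            vectors=np.zeros((0, 1)),
            bin_index=np.zeros(0, dtype=int),
            n_nodes=np.asarray(m).shape[0],
        )
    variant = _choose_variant(cfg, g.m_active)
    if variant == "exact-small":
        chi = deepwalk_matrix_exact(g, cfg)
    else:
        chi = deepwalk_matrix_approx(g, cfg)
    emb, e_eff = shifted_log_factorize(chi, cfg.dim)
    logger.info(
        "embedded %d/%d nodes with e_eff=%d (%s)",
        g.m_active, g.n_nodes, e_eff, variant,
    )
    return EmbeddingMatrix(
        vectors=emb, bin_index=g.active_nodes.copy(), n_nodes=g.n_nodes
    )
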