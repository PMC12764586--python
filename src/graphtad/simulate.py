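"""Synthetic Hi-C matrices with known ground-truth domain partitions.

The generator emulates the block-plus-decay phenotype of real contact
maps: an exponential distance-decay background, a multiplicative boost
``gamma`` for bin pairs inside the same ground-truth domain, Poisson
counting noise, and an additive folded-normal noise term scaled by
``noise``.  Domain sizes are drawn uniformly from a bp range (default
250 Kb - 1.75 Mb, the bulk of the mammalian TAD size distribution) and
short unorganized gaps may separate domains.

This simulator is a synthetic stand-in for published in-silico Hi-C
benchmarks; it reproduces their qualitative design (triangle blocks on a
decay background at graded noise levels), not any specific dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ContactMatrix, TadInterval, TadSet

__all__ = ["SyntheticTruth", "simulate_hic", "perturb_partition"]


@dataclass
class SyntheticTruth:
    """A simulated contact matrix together with its generating partition."""

    matrix: ContactMatrix
    truth: TadSet
    params: dict


def _draw_partition(
    rng: np.random.Generator,
    n_bins: int,
    resolution: int,
    tad_kb_range: tuple[float, float],
    gap_prob: float,
    chrom: str,
) -> TadSet:
    lo_bins = max(1, round(tad_kb_range[0] * 1000 / resolution))
    hi_bins = max(lo_bins, round(tad_kb_range[1] * 1000 / resolution))
    if lo_bins > n_bins:
        raise ValueError(
            f"minimum domain size {lo_bins} bins exceeds n_bins={n_bins}"
        )
    intervals = []
    pos = 0
    while pos + lo_bins <= n_bins:
        size = int(rng.integers(lo_bins, hi_bins + 1))
        size = min(size, n_bins - pos)
        if size < lo_bins:
            break
        intervals.append(
            TadInterval(chrom=chrom, start_bin=pos, end_bin=pos + size,
                        resolution=resolution)
        )
        pos += size
        if rng.random() < gap_prob:
            pos += int(rng.integers(1, max(2, lo_bins // 2)))
    return TadSet(chrom=chrom, resolution=resolution, intervals=intervals)


def simulate_hic(
    n_bins: int = 600,
    resolution: int = 10_000,
    tad_kb_range: tuple[float, float] = (250.0, 1750.0),
    gap_prob: float = 0.2,
    decay_bins: float = 100.0,
    gamma: float = 4.0,
    beta: float = 10.0,
    noise: float = 1.0,
    seed: int = 0,
    chrom: str = "chrS",
) -> SyntheticTruth:
    """Simulate one chromosome's contact matrix with known domains.

    Mean contact ``mu_ij = beta * exp(-|i-j|/decay_bins) * gamma`` when
    bins i and j share a ground-truth domain, without the ``gamma``
    factor otherwise; observed counts are ``Poisson(mu) + noise * |z|``
    with standard-normal z, symmetrized.  Deterministic for a fixed seed.
    """
    if n_bins < 1 or resolution < 1:
        raise ValueError("n_bins and resolution must be positive")
    if gamma < 1 or beta <= 0 or noise < 0 or decay_bins <= 0:
        raise ValueError("require gamma >= 1, beta > 0, noise >= 0, decay > 0")
    rng = np.random.default_rng(seed)
    truth = _draw_partition(rng, n_bins, resolution, tad_kb_range, gap_prob, chrom)
    dom = np.full(n_bins, -1, dtype=int)
    for k, t in enumerate(truth):
        dom[t.start_bin:t.end_bin] = k
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    mu = beta * np.exp(-dist / decay_bins)
    same = (dom[:, None] >= 0) & (dom[:, None] == dom[None, :])
    mu = mu * np.where(same, gamma, 1.0)
    counts = rng.poisson(mu).astype(float)
    counts += noise * np.abs(rng.standard_normal(mu.shape))
    upper = np.triu(counts)
    values = upper + np.triu(upper, 1).T
    cm = ContactMatrix(chrom=chrom, resolution=resolution, values=values)
    params = dict(
        n_bins=n_bins, resolution=resolution, tad_kb_range=tad_kb_range,
        gap_prob=gap_prob, decay_bins=decay_bins, gamma=gamma, beta=beta,
        noise=noise, seed=seed,
    )
    return SyntheticTruth(matrix=cm, truth=truth, params=params)


def perturb_partition(truth: TadSet, op: str, seed: int = 0) -> TadSet:
    """Apply one structural perturbation to a domain partition.

    ``"split"`` halves one random domain of >= 2 bins; ``"merge"`` fuses
    one random adjacent pair into a single spanning domain; ``"shift"``
    moves every internal boundary one bin later.
    """
    if len(truth) == 0:
        raise ValueError("cannot perturb an empty partition")
    rng = np.random.default_rng(seed)
    ivs = list(truth)
    if op == "split":
        wide = [i for i, t in enumerate(ivs) if t.n_bins >= 2]
        if not wide:
            raise ValueError("no domain wide enough to split")
        k = int(rng.choice(wide))
        t = ivs[k]
        cut = t.start_bin + t.n_bins // 2
        ivs[k:k + 1] = [
            replace(t, end_bin=cut),
            replace(t, start_bin=cut),
        ]
    elif op == "merge":
        if len(ivs) < 2:
            raise ValueError("need >= 2 domains to merge")
        k = int(rng.integers(0, len(ivs) - 1))
        merged = replace(ivs[k], end_bin=ivs[k + 1].end_bin)
        ivs[k:k + 2] = [merged]
    elif op == "shift":
        out = []
        for i, t in enumerate(ivs):
            s = t.start_bin + 1 if i > 0 else t.start_bin
            e = t.end_bin + 1 if i < len(ivs) - 1 else t.end_bin
            if e > s:
                out.append(replace(t, start_bin=s, end_bin=e))
        ivs = out
    else:
        raise ValueError(f"unknown perturbation {op!r}")
    return TadSet(chrom=truth.chrom, resolution=truth.resolution, intervals=ivs)
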