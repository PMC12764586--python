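"""Evaluation statistics for domain partitions.

* ``moc`` — Measure of Concordance between two domain partitions, a
  normalized squared-overlap statistic in [0, 1].
* ``tad_adj_r2`` — adjusted R-squared explaining contact-frequency
  variance at each genomic distance by the TAD/background grouping,
  penalized by the number of domains spanning that distance.
* ``boundary_signal_profile`` — mean signal (e.g. CTCF ChIP-seq) around
  domain boundaries, +/- 250 Kb by default.
* ``recovery_rate`` — fraction of reference domains matched by a
  detected domain at a Jaccard threshold.
* ``classify_split_merge`` — domain rearrangement events between two
  conditions (one interval splitting into several, or several merging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ContactMatrix, SignalTrack, TadInterval, TadSet

__all__ = [
    "moc",
    "tad_adj_r2",
    "boundary_signal_profile",
    "recovery_rate",
    "classify_split_merge",
    "RearrangementReport",
    "covered_bp_jaccard",
]


def _overlap_bp(a: TadInterval, b: TadInterval) -> int:
    return max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp))


def moc(p: TadSet, q: TadSet) -> float:
    """Measure of Concordance between two domain partitions.

    MoC = (sum_ij F_ij^2 / (|P_i| |Q_j|) - 1) / (sqrt(N_P N_Q) - 1)
    with F_ij the bp overlap of domains P_i and Q_j; defined as 1 when
    both partitions consist of a single domain.  Symmetric, in [0, 1],
    and 1 exactly when the partitions coincide.
    """
    if len(p) == 0 or len(q) == 0:
        raise ValueError("MoC is undefined for an empty domain set")
    n_p, n_q = len(p), len(q)
    if n_p == 1 and n_q == 1:
        return 1.0
    total = 0.0
    for a in p:
        for b in q:
            f = _overlap_bp(a, b)
            if f:
                total += f * f / (a.span_bp * b.span_bp)
    return (total - 1.0) / (math.sqrt(n_p * n_q) - 1.0)


def tad_adj_r2(
    cm: ContactMatrix,
    tads: TadSet,
    d_max_bp: int = 1_500_000,
) -> pd.DataFrame:
    """Adjusted R-squared of the domain grouping per genomic distance.

    At each distance ``d`` the contact values ``X_i = cm[i, i+d]`` are
    grouped by the domain containing both endpoints (pairs straddling a
    domain edge, or outside every domain, form one background group).
    ``r2 = 1 - [SS_res/(N - N_t - 1)] / [SS_tot/(N - 1)]`` with ``N_t``
    the number of domains whose bp span is >= d.  Distances with zero
    total variance or ``N - N_t - 1 <= 0`` are reported as NaN.

    Returns a DataFrame with columns ``d_bp, n_pairs, n_tads, r2``.
    """
    res = cm.resolution
    if d_max_bp < res:
        raise ValueError(f"d_max_bp {d_max_bp} below resolution {res}")
    n = cm.n_bins
    # domain id per bin, -1 = background
    dom = np.full(n, -1, dtype=int)
    for k, t in enumerate(tads):
        dom[t.start_bin:min(t.end_bin, n)] = k
    spans = np.array([t.span_bp for t in tads], dtype=np.int64)
    rows = []
    for d in range(1, d_max_bp // res + 1):
        if d >= n:
            break
        x = np.diagonal(cm.values, offset=d)
        i = np.arange(n - d)
        same = (dom[i] >= 0) & (dom[i] == dom[i + d])
        group = np.where(same, dom[i], -1)
        n_pairs = len(x)
        n_t = int((spans >= d * res).sum())
        ss_tot = float(((x - x.mean()) ** 2).sum())
        dof_res = n_pairs - n_t - 1
        if ss_tot == 0.0 or dof_res <= 0:
            r2 = np.nan
        else:
            ss_res = 0.0
            for g in np.unique(group):
                xs = x[group == g]
                ss_res += float(((xs - xs.mean()) ** 2).sum())
            r2 = 1.0 - (ss_res / dof_res) / (ss_tot / (n_pairs - 1))
        rows.append({"d_bp": d * res, "n_pairs": n_pairs, "n_tads": n_t, "r2": r2})
    return pd.DataFrame(rows, columns=["d_bp", "n_pairs", "n_tads", "r2"])


def _track_mean(track: SignalTrack, lo: int, hi: int) -> float:
    """Mean signal over [lo, hi) bp, uncovered bp counting as 0."""
    if hi <= lo:
        return 0.0
    ov = np.minimum(track.ends, hi) - np.maximum(track.starts, lo)
    ov = np.clip(ov, 0, None)
    return float((ov * track.values).sum() / (hi - lo))


def boundary_signal_profile(
    boundaries_bp: list[int],
    track: SignalTrack,
    flank_bp: int = 250_000,
    nbins: int = 51,
) -> np.ndarray:
    """Mean signal per offset bin across [-flank, +flank] around boundaries.

    ``nbins`` must be odd so the center bin sits on the boundary.  Offset
    bins truncated by the chromosome start are averaged over their
    covered part only; uncovered bp inside the track range count as 0.
    """
    if not boundaries_bp:
        raise ValueError("no boundaries given")
    if nbins % 2 == 0 or nbins < 1:
        raise ValueError("nbins must be odd and positive")
    edges = np.linspace(-flank_bp, flank_bp, nbins + 1)
    prof = np.zeros(nbins)
    counts = np.zeros(nbins)
    for b in boundaries_bp:
        for k in range(nbins):
            lo = int(round(b + edges[k]))
            hi = int(round(b + edges[k + 1]))
            lo = max(lo, 0)
            if hi <= lo:
                continue  # fully truncated offset bin
            prof[k] += _track_mean(track, lo, hi)
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, prof / np.maximum(counts, 1), 0.0)
    return out


def _jaccard_bp(a: TadInterval, b: TadInterval) -> float:
    inter = _overlap_bp(a, b)
    union = a.span_bp + b.span_bp - inter
    return inter / union if union else 0.0


def recovery_rate(
    detected: TadSet, reference: TadSet, jaccard_min: float = 0.5
) -> float:
    """Fraction of reference domains matched by a detected domain.

    A reference domain counts as recovered when some detected domain
    overlaps it with bp-Jaccard >= ``jaccard_min``.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    if len(detected) == 0:
        return 0.0
    hit = 0
    for r in reference:
        if any(_jaccard_bp(r, d) >= jaccard_min for d in detected):
            hit += 1
    return hit / len(reference)


@dataclass
class RearrangementReport:
    """Split/merge events between two domain sets A and B."""

    splits: list[tuple[TadInterval, list[TadInterval]]]
    merges: list[tuple[list[TadInterval], TadInterval]]

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    @property
    def n_merges(self) -> int:
        return len(self.merges)


def _find_splits(
    a: TadSet, b: TadSet, cover_min: float
) -> list[tuple[TadInterval, list[TadInterval]]]:
    events = []
    for big in a:
        parts = [
            s for s in b
            if s.span_bp and _overlap_bp(big, s) / s.span_bp >= cover_min
        ]
        if len(parts) < 2:
            continue
        covered = sum(_overlap_bp(big, s) for s in parts)
        if covered / big.span_bp >= cover_min:
            events.append((big, parts))
    return events


def classify_split_merge(
    a: TadSet, b: TadSet, cover_min: float = 0.8
) -> RearrangementReport:
    """Domain rearrangement events going from condition A to condition B.

    A split is one A-domain containing (at >= ``cover_min`` of their
    length) two or more B-domains whose union covers >= ``cover_min`` of
    it; a merge is the symmetric event with roles swapped.
    """
    return RearrangementReport(
        splits=_find_splits(a, b, cover_min),
        merges=[(parts, big) for big, parts in _find_splits(b, a, cover_min)],
    )


def covered_bp_jaccard(a: TadSet, b: TadSet) -> float:
    """Jaccard index of the bp covered by two domain sets (coverage overlap)."""
    def covered(ts: TadSet) -> set[int]:
        bins: set[int] = set()
        for t in ts:
            bins.update(range(t.start_bin, t.end_bin))
        return bins

    ca, cb = covered(a), covered(b)
    union = ca | cb
    if not union:
        return 1.0
    return len(ca & cb) / len(union)
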