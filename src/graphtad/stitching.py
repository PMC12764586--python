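"""Resolve duplicated domains in overlap regions and assemble the final set.

Because window ``i+1`` re-embeds the 3 Mb region it borrows from window
``i``, both windows may call (possibly different) TADs there.  The TAD
Quality (TQ) score of each side's calls inside the overlap — mean
intra-TAD contact minus mean inter-TAD contact — decides which side's
calls survive; ties go to the newer window.  Residual overlaps after the
pairwise Q-region passes are resolved in favour of the earlier interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import ContactMatrix, TadInterval, TadSet
from .partition import PartitionPlan

logger = logging.getLogger(__name__)

__all__ = ["QResolution", "tad_quality", "resolve_q_region", "assemble_genome_tads"]


@dataclass(frozen=True)
class QResolution:
    """Record of one overlap-region adjudication."""

    window: int
    q_range: tuple[int, int]
    tq_prev: float
    tq_curr: float
    winner: str  # "prev" | "curr"


def _clip_to_region(
    tads: list[TadInterval], region: tuple[int, int]
) -> list[TadInterval]:
    lo, hi = region
    out = []
    for t in tads:
        s, e = max(t.start_bin, lo), min(t.end_bin, hi)
        if e > s:
            out.append(replace(t, start_bin=s, end_bin=e))
    return out


def tad_quality(
    cm: ContactMatrix,
    tads: list[TadInterval],
    region: tuple[int, int],
) -> float:
    """TQ = mean intra-TAD contact minus mean inter-TAD contact in a region.

    Pairs (i < j) with both bins inside one TAD are intra; pairs whose
    bins fall in two different TADs are inter; pairs touching unassigned
    bins are ignored.  An empty pair class contributes 0.
    """
    lo, hi = region
    if hi - lo < 2:
        raise ValueError(f"region [{lo},{hi}) must span at least 2 bins")
    clipped = _clip_to_region(tads, region)
    member = np.full(hi - lo, -1, dtype=int)
    for k, t in enumerate(clipped):
        member[t.start_bin - lo:t.end_bin - lo] = k
    assigned = np.flatnonzero(member >= 0) + lo
    if len(assigned) < 2:
        return 0.0
    sub = cm.values[np.ix_(assigned, assigned)]
    lab = member[assigned - lo]
    same = lab[:, None] == lab[None, :]
    upper = np.triu(np.ones_like(same, dtype=bool), 1)
    intra_mask = same & upper
    inter_mask = ~same & upper
    intra = sub[intra_mask].mean() if intra_mask.any() else 0.0
    inter = sub[inter_mask].mean() if inter_mask.any() else 0.0
    return float(intra - inter)


def _intersects(t: TadInterval, region: tuple[int, int]) -> bool:
    lo, hi = region
    return t.start_bin < hi and t.end_bin > lo


def resolve_q_region(
    cm: ContactMatrix,
    prev_tads: list[TadInterval],
    curr_tads: list[TadInterval],
    q_range: tuple[int, int],
    window_index: int = 0,
) -> tuple[list[TadInterval], list[TadInterval], QResolution]:
    """Keep the side whose calls score higher inside the overlap region.

    Only intervals overlapping ``q_range`` by >= 1 bin compete; the losing
    side's overlapping intervals are dropped in full, the winner's are
    kept unclipped.  Equal scores keep the current window's calls.
    """
    p_prev = [t for t in prev_tads if _intersects(t, q_range)]
    p_curr = [t for t in curr_tads if _intersects(t, q_range)]
    tq_prev = tad_quality(cm, p_prev, q_range) if p_prev else 0.0
    tq_curr = tad_quality(cm, p_curr, q_range) if p_curr else 0.0
    if not p_prev and not p_curr:
        winner = "curr"
    elif not p_curr:
        winner = "prev"
    elif not p_prev:
        winner = "curr"
    else:
        winner = "prev" if tq_prev > tq_curr else "curr"
    if winner == "prev":
        kept, dropped = p_prev, p_curr
    else:
        kept, dropped = p_curr, p_prev
    rec = QResolution(
        window=window_index, q_range=q_range,
        tq_prev=tq_prev, tq_curr=tq_curr, winner=winner,
    )
    return kept, dropped, rec


def assemble_genome_tads(
    cm: ContactMatrix,
    per_window_candidates: list[list[TadInterval]],
    plan: PartitionPlan,
) -> tuple[TadSet, list[QResolution]]:
    """Sequentially adjudicate each overlap region and merge all windows.

    After the pairwise passes, any residual overlap between a retained
    earlier interval and a later one drops the later interval, giving a
    sorted, non-overlapping set.
    """
    if len(per_window_candidates) != plan.ns:
        raise ValueError(
            f"{len(per_window_candidates)} candidate lists for {plan.ns} windows"
        )
    records: list[QResolution] = []
    kept: list[TadInterval] = list(per_window_candidates[0])
    for w in plan.windows[1:]:
        curr = list(per_window_candidates[w.index])
        q_range = w.q_range
        if q_range[1] - q_range[0] >= 2:
            prev_q = [t for t in kept if _intersects(t, q_range)]
            curr_q = [t for t in curr if _intersects(t, q_range)]
            won, lost, rec = resolve_q_region(
                cm, prev_q, curr_q, q_range, window_index=w.index
            )
            records.append(rec)
            logger.info(
                "Q region %s window %d: TQ_prev=%.4g TQ_curr=%.4g -> %s",
                q_range, w.index, rec.tq_prev, rec.tq_curr, rec.winner,
            )
            lost_keys = {(t.start_bin, t.end_bin) for t in lost}
            if rec.winner == "prev":
                curr = [t for t in curr
                        if (t.start_bin, t.end_bin) not in lost_keys
                        or not _intersects(t, q_range)]
            else:
                kept = [t for t in kept
                        if (t.start_bin, t.end_bin) not in lost_keys
                        or not _intersects(t, q_range)]
        kept.extend(curr)
    # residual overlaps: earlier interval wins, later is dropped
    kept.sort(key=lambda t: (t.start_bin, t.end_bin))
    final: list[TadInterval] = []
    for t in kept:
        if final and t.start_bin < final[-1].end_bin:
            if (t.start_bin, t.end_bin) == (
                final[-1].start_bin, final[-1].end_bin
            ):
                continue  # exact duplicate
            logger.info(
                "dropping residual overlap [%d,%d) vs kept [%d,%d)",
                t.start_bin, t.end_bin,
                final[-1].start_bin, final[-1].end_bin,
            )
            continue
        final.append(t)
    return TadSet(chrom=cm.chrom, resolution=cm.resolution, intervals=final), records
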