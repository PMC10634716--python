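"""Genome-wide sliding-window peak calling and evaluation.

Short-fragment (observed-ligation) read 5' ends are scanned with a window
of half-width ``w`` at every ``step`` bp. Windows with at least
``min_reads`` reads get a statistic and a table p-value; windows passing
the significance threshold are merged into peaks, and the peak summit is
placed at the window maximizing the statistic (ties: larger total count,
then the midpoint of the tied run of centers — a flat maximum is common on
clean pile-ups, and the midpoint is the unbiased choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .readwrite import as_contact_frame
from .stats import GRID, NullTable, QuadrantCounts, stat_grid_index
from .types import GenomicInterval, Motif

__all__ = [
    "CallerParams",
    "Peak",
    "quadrant_counts",
    "window_counts",
    "short_fragment_reads",
    "scan_windows",
    "call_peaks",
    "assign_motif_qvalues",
    "evaluate_pr",
    "summit_distances",
]


@dataclass(frozen=True)
class CallerParams:
    """Sliding-window caller parameters.

    halfwidth : window half-width in bp (reads within +/- halfwidth count).
    step : spacing of evaluated window centers, bp.
    min_reads : minimum total window count for a test (matches the null
        table's smallest tabulated N).
    p_threshold : significance threshold on the table p-value.
    merge_gap : significant windows within this many bp are merged into one
        peak.
    """

    halfwidth: int = 100
    step: int = 1
    min_reads: int = 5
    p_threshold: float = 1e-5
    merge_gap: int = 30

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")


@dataclass(frozen=True)
class Peak:
    """A called binding site: merged significant windows with a summit."""

    interval: GenomicInterval
    summit: int
    stat: float
    pvalue: float
    n: int
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must be in (0, 1]")


def window_counts(
    plus_pos: np.ndarray,
    minus_pos: np.ndarray,
    centers: np.ndarray,
    halfwidth: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Quadrant counts (n1..n4) at each center, vectorized.

    ``plus_pos`` / ``minus_pos`` must be sorted 5'-end positions. Reads with
    |pos - center| <= halfwidth are counted; a read exactly at the center
    goes to the downstream quadrant (Q1/Q4).
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    c = np.asarray(centers, dtype=np.int64)
    lo = np.searchsorted(plus_pos, c - halfwidth, side="left")
    mid = np.searchsorted(plus_pos, c, side="left")
    hi = np.searchsorted(plus_pos, c + halfwidth, side="right")
    n2 = mid - lo
    n1 = hi - mid
    lo = np.searchsorted(minus_pos, c - halfwidth, side="left")
    mid = np.searchsorted(minus_pos, c, side="left")
    hi = np.searchsorted(minus_pos, c + halfwidth, side="right")
    n3 = mid - lo
    n4 = hi - mid
    return n1, n2, n3, n4


def quadrant_counts(
    reads: Sequence[Tuple[int, str]], center: int, halfwidth: int
) -> QuadrantCounts:
    """Quadrant counts from (pos5, strand) reads around one center."""
    plus = np.sort([p for p, s in reads if s == "+"])
    minus = np.sort([p for p, s in reads if s == "-"])
    n1, n2, n3, n4 = window_counts(plus, minus, np.array([center]), halfwidth)
    return QuadrantCounts(int(n1[0]), int(n2[0]), int(n3[0]), int(n4[0]))


def short_fragment_reads(contacts) -> pd.DataFrame:
    """Observed-ligation (short-fragment) 5' read ends from both sides.

    Both sides of a contact contribute: each observed-ligation side is an
    independent short-fragment read. Columns: chrom, pos5, strand.
    """
    frame = as_contact_frame(contacts)
    parts = []
    for i in (1, 2):
        sub = frame.loc[frame[f"obs{i}"], [f"chrom{i}", f"pos{i}", f"strand{i}"]]
        sub.columns = ["chrom", "pos5", "strand"]
        parts.append(sub)
    if not parts:
        return pd.DataFrame(columns=["chrom", "pos5", "strand"])
    return pd.concat(parts, ignore_index=True)


def scan_windows(
    contacts,
    table: NullTable,
    params: CallerParams = CallerParams(),
    chunk: int = 2_000_000,
) -> pd.DataFrame:
    """Evaluate sliding windows genome-wide.

    Every center position (at ``step`` spacing) whose window holds at least
    ``min_reads`` short-fragment reads is tested. Returns a frame with
    columns chrom, center, n1..n4, n, stat, p sorted by (chrom, center).
    """
    reads = short_fragment_reads(contacts)
    out = []
    for chrom, grp in reads.groupby("chrom", sort=True):
        plus = np.sort(grp.loc[grp["strand"] == "+", "pos5"].to_numpy())
        minus = np.sort(grp.loc[grp["strand"] == "-", "pos5"].to_numpy())
        if len(plus) + len(minus) < params.min_reads:
            continue
        allpos = np.concatenate([plus, minus])
        first = max(int(allpos.min()) - params.halfwidth, 0)
        last = int(allpos.max()) + params.halfwidth
        for block in range(first, last + 1, chunk):
            centers = np.arange(block, min(block + chunk, last + 1), params.step,
                                dtype=np.int64)
            n1, n2, n3, n4 = window_counts(plus, minus, centers, params.halfwidth)
            total = n1 + n2 + n3 + n4
            keep = total >= params.min_reads
            if not keep.any():
                continue
            n1, n2, n3, n4 = n1[keep], n2[keep], n3[keep], n4[keep]
            centers, total = centers[keep], total[keep]
            idx = stat_grid_index(n1, n2, n3, n4)
            p = table.pvalues(n1, n2, n3, n4)
            stat = np.where(idx >= 0, GRID[np.maximum(idx, 0)], -np.inf)
            out.append(pd.DataFrame({
                "chrom": chrom, "center": centers,
                "n1": n1, "n2": n2, "n3": n3, "n4": n4,
                "n": total, "stat": stat, "p": p,
            }))
    if not out:
        return pd.DataFrame(
            columns=["chrom", "center", "n1", "n2", "n3", "n4", "n", "stat", "p"]
        )
    return pd.concat(out, ignore_index=True)


def _merge_to_peaks(sig: pd.DataFrame, merge_gap: int) -> List[Peak]:
    peaks: List[Peak] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("center")
        centers = grp["center"].to_numpy()
        breaks = np.flatnonzero(np.diff(centers) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(centers)]])
        for a, b in zip(starts, ends):
            block = grp.iloc[a:b]
            best_stat = block["stat"].max()
            at_stat = block[block["stat"] == best_stat]
            best_n = at_stat["n"].max()
            tied = at_stat[at_stat["n"] == best_n].sort_values("center")
            summit = int(tied["center"].to_numpy()[len(tied) // 2])
            row = tied[tied["center"] == summit].iloc[0]
            peaks.append(Peak(
                interval=GenomicInterval(chrom, int(centers[a]),
                                         int(centers[b - 1]) + 1),
                summit=summit,
                stat=float(best_stat),
                pvalue=float(block["p"].min()),
                n=int(row["n"]),
            ))
    return peaks


def call_peaks(
    contacts,
    params: CallerParams = CallerParams(),
    table: NullTable = None,
    windows: Optional[pd.DataFrame] = None,
) -> List[Peak]:
    """Call peaks from contacts (or precomputed windows from scan_windows)."""
    if windows is None:
        if table is None:
            raise ValueError("either a null table or precomputed windows required")
        windows = scan_windows(contacts, table, params)
    if windows.empty:
        return []
    sig = windows[windows["p"] < params.p_threshold]
    if sig.empty:
        return []
    return _merge_to_peaks(sig, params.merge_gap)


def assign_motif_qvalues(
    motifs: Sequence[Motif],
    windows: pd.DataFrame,
    max_dist: int = 1000,
) -> pd.DataFrame:
    """Per-motif (p, q): nearest tested window's p, then Benjamini-Hochberg.

    Each motif takes the p-value of the window whose center is closest to
    the motif center (ties: the smaller p). Motifs with no tested window
    within ``max_dist`` bp get p = 1. q-values are BH-adjusted across all
    motifs.
    """
    ps = np.ones(len(motifs), dtype=float)
    by_chrom = {c: g.sort_values(["center", "p"]) for c, g in windows.groupby("chrom")}
    for i, m in enumerate(motifs):
        grp = by_chrom.get(m.chrom)
        if grp is None:
            continue
        centers = grp["center"].to_numpy()
        pvals = grp["p"].to_numpy()
        j = np.searchsorted(centers, m.center)
        cand = [k for k in (j - 1, j) if 0 <= k < len(centers)]
        if not cand:
            continue
        dists = [abs(int(centers[k]) - m.center) for k in cand]
        best = min(dists)
        if best > max_dist:
            continue
        ps[i] = min(pvals[k] for k, d in zip(cand, dists) if d == best)
    if len(ps):
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
    else:
        qs = np.array([])
    return pd.DataFrame({
        "chrom": [m.chrom for m in motifs],
        "center": [m.center for m in motifs],
        "strand": [m.strand for m in motifs],
        "p": ps,
        "q": qs,
    })


def _match_counts(summits: np.ndarray, truth: np.ndarray, match_dist: int):
    """(matched truth count, matched summit mask) for sorted truth centers."""
    if len(truth) == 0:
        return 0, np.zeros(len(summits), dtype=bool)
    truth = np.sort(truth)
    j = np.searchsorted(truth, summits)
    lo = np.clip(j - 1, 0, len(truth) - 1)
    hi = np.clip(j, 0, len(truth) - 1)
    dist = np.minimum(np.abs(summits - truth[lo]), np.abs(summits - truth[hi]))
    summit_hits = dist <= match_dist
    # truth side
    hit_truth = set()
    for s in summits[summit_hits]:
        for k in (np.searchsorted(truth, s) - 1, np.searchsorted(truth, s)):
            if 0 <= k < len(truth) and abs(int(truth[k]) - int(s)) <= match_dist:
                hit_truth.add(int(k))
    return len(hit_truth), summit_hits


def evaluate_pr(
    called: Sequence[Peak],
    truth_positives: Sequence[Motif],
    truth_negatives: Sequence[Motif] = (),
    match_dist: int = 20,
) -> Tuple[float, float]:
    """Precision and recall of called summits against planted positives.

    TP = positives with a significant summit within ``match_dist`` bp;
    FP = summits matching no positive; FN = unmatched positives.
    Precision = TP / (TP + FP), recall = TP / (TP + FN).
    """
    if len(truth_positives) == 0:
        raise ValueError("empty truth-positive set: precision/recall undefined")
    pos_set = {(m.chrom, m.center) for m in truth_positives}
    neg_set = {(m.chrom, m.center) for m in truth_negatives}
    if pos_set & neg_set:
        raise ValueError("truth positive and negative sets overlap")
    tp = 0
    fp = 0
    fn = 0
    by_chrom_truth = {}
    for m in truth_positives:
        by_chrom_truth.setdefault(m.chrom, []).append(m.center)
    by_chrom_summit = {}
    for pk in called:
        by_chrom_summit.setdefault(pk.interval.chrom, []).append(pk.summit)
    chroms = set(by_chrom_truth) | set(by_chrom_summit)
    for chrom in chroms:
        truth = np.array(by_chrom_truth.get(chrom, []), dtype=np.int64)
        summits = np.array(by_chrom_summit.get(chrom, []), dtype=np.int64)
        n_hit, summit_hits = _match_counts(summits, truth, match_dist)
        tp += n_hit
        fp += int((~summit_hits).sum())
        fn += len(truth) - n_hit
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return precision, recall


def summit_distances(
    called: Sequence[Peak],
    truth_positives: Sequence[Motif],
    max_dist: int = 150,
) -> np.ndarray:
    """|summit - nearest planted center| for summits within ``max_dist`` bp."""
    by_chrom = {}
    for m in truth_positives:
        by_chrom.setdefault(m.chrom, []).append(m.center)
    dists = []
    for pk in called:
        centers = by_chrom.get(pk.interval.chrom)
        if not centers:
            continue
        arr = np.sort(np.array(centers, dtype=np.int64))
        j = np.searchsorted(arr, pk.summit)
        best = min(
            abs(int(arr[k]) - pk.summit)
            for k in (j - 1, j) if 0 <= k < len(arr)
        )
        if best <= max_dist:
            dists.append(best)
    return np.array(dists, dtype=np.int64)
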