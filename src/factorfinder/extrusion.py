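"""Contact-decay curves, extruded-loop-size estimation and the
fully-extruded-state estimator.

A HiChIP library is a snapshot of extruding cohesin loops across millions
of cells; the interaction-length distribution of CTCF/cohesin-protected
fragments therefore carries the average loop size extruded by cohesin, and
the fraction of partners landing on a downstream convergent '-' motif
measures how often the loop is in the fully extruded CTCF-CTCF state.
Because that convergence fraction is conditional on CTCF being bound at
the focal anchor, it is multiplied by the CTCF occupancy (~50%) to obtain
the unconditional genome-wide frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .fragments import ClassParams, side_table
from .types import GenomicInterval, Motif, SignalPeak

__all__ = [
    "PsCurve",
    "ExtrusionParams",
    "ExtrudedStateEstimate",
    "RegionAnnotation",
    "LoopSizeEstimate",
    "ps_curve",
    "fully_extruded_fraction",
    "annotate_region",
    "group_states",
    "top_fraction_members",
    "loop_size_by_stratum",
    "cohesin_effect",
]

ACTIVE = "ACTIVE"
POLYCOMB_BIVALENT = "POLYCOMB_BIVALENT"
QUIESCENT = "QUIESCENT"
GROUPS = (ACTIVE, POLYCOMB_BIVALENT, QUIESCENT)


# ---------------------------------------------------------------------------
# P(s)
# ---------------------------------------------------------------------------

@dataclass
class PsCurve:
    """Contact probability vs genomic separation, on log-spaced bins.

    ``freq`` is per-bp density: counts normalized by total in-range cis
    contacts and bin width, so sum(freq * widths) = 1.
    """

    edges: np.ndarray
    freq: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def loglog_slope(self) -> float:
        """OLS slope of log10(freq) on log10(s) over non-empty bins."""
        ok = self.freq > 0
        x = np.log10(self.centers[ok])
        y = np.log10(self.freq[ok])
        return float(np.polyfit(x, y, 1)[0])


def ps_curve(
    lengths,
    bins_per_decade: int = 20,
    s_min: float = 1e3,
    s_max: float = 1e7,
) -> PsCurve:
    """P(s) from cis interaction lengths (array, or a contact frame).

    Lengths outside [s_min, s_max] are dropped; empty bins report 0.
    """
    if isinstance(lengths, pd.DataFrame):
        cis = lengths[lengths["chrom1"] == lengths["chrom2"]]
        lengths = np.abs(cis["pos2"].to_numpy() - cis["pos1"].to_numpy())
    lengths = np.asarray(lengths, dtype=float)
    lengths = lengths[(lengths >= s_min) & (lengths <= s_max)]
    if len(lengths) == 0:
        raise ValueError("no cis contacts in [s_min, s_max]")
    n_bins = int(round(bins_per_decade * np.log10(s_max / s_min)))
    edges = np.logspace(np.log10(s_min), np.log10(s_max), n_bins + 1)
    counts, _ = np.histogram(lengths, bins=edges)
    widths = np.diff(edges)
    freq = counts / (counts.sum() * widths)
    return PsCurve(edges=edges, freq=freq, counts=counts)


# ---------------------------------------------------------------------------
# Motif-level fragment assignment
# ---------------------------------------------------------------------------

def _fragments_at_motifs(
    contacts,
    motifs: Sequence[Motif],
    params: ClassParams,
    tf_only: bool = True,
    upstream_only: bool = True,
    longrange_only: bool = True,
) -> List[pd.DataFrame]:
    """Per-motif frames of qualifying focal fragments.

    A fragment qualifies when it overlaps the motif interval and passes the
    requested filters: TF-protected (known length < tf_max_len, both edges
    >= min_edge_dist from the center) vs nucleosome also available via
    ``tf_only=False`` (adds a 'tf' column instead of filtering); upstream
    partner orientation; long-range cis contact. Fragments whose partner
    overlaps the motif are dropped (ambiguous orientation).
    """
    sides = side_table(contacts, read_length=params.read_length)
    by_chrom = {c: g.sort_values("start") for c, g in sides.groupby("chrom")}
    out = []
    for m in motifs:
        grp = by_chrom.get(m.chrom)
        if grp is None:
            out.append(pd.DataFrame())
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i0 = np.searchsorted(starts, m.interval.start - params.read_length, "left")
        i1 = np.searchsorted(starts, m.interval.end, "right")
        block = grp.iloc[i0:i1]
        s, e = starts[i0:i1], ends[i0:i1]
        sel = e > m.interval.start
        block = block[sel]
        s, e = s[sel], e[sel]
        if block.empty:
            out.append(block)
            continue
        flen = block["flen"].to_numpy()
        obs = block["obs"].to_numpy()
        c = m.center
        edge_ok = np.minimum(np.abs(s - c), np.abs(e - 1 - c)) >= params.min_edge_dist
        is_tf = obs & (flen < params.tf_max_len) & edge_ok
        is_nuc = ~obs | (flen >= params.tf_max_len)
        block = block.assign(tf=is_tf, nuc=is_nuc)
        if tf_only:
            block = block[block["tf"]]
        else:
            block = block[block["tf"] | block["nuc"]]
        if longrange_only:
            block = block[block["cis"] & (block["ilen"] > params.longrange_min)]
        else:
            block = block[block["cis"]]
        if block.empty:
            out.append(block)
            continue
        # partner orientation; ambiguous (partner overlaps motif) dropped
        clear = (block["pend"] <= m.interval.start) | \
            (block["pstart"] >= m.interval.end) | (block["pchrom"] != m.chrom)
        block = block[clear]
        pdown = block["pstart"] > m.center
        if m.strand == "-":
            pdown = ~pdown
        block = block.assign(upstream=pdown)
        if upstream_only:
            block = block[block["upstream"]]
        out.append(block)
    return out


# ---------------------------------------------------------------------------
# Fully extruded state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtrusionParams:
    """occupancy: CTCF occupancy correction multiplying the conditional
    convergence fraction (~0.5: the estimate is conditional on a bound
    anchor). min_frags: minimum qualifying fragments for a CBS-level value.
    pad: extra bp around a '-' motif counted as overlap."""

    occupancy: float = 0.5
    min_frags: int = 50
    pad: int = 0
    class_params: ClassParams = field(default_factory=ClassParams)


@dataclass
class ExtrudedStateEstimate:
    """Genome-wide % fully extruded, with the CBS-level percentile range."""

    point: float
    range_lo: float
    range_hi: float
    n_fragments: int
    n_convergent: int
    n_cbs: int
    per_cbs: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0 <= self.point <= 100):
            raise ValueError("point estimate must be a percentage in [0, 100]")
        if self.range_lo > self.range_hi:
            raise ValueError("range_lo must be <= range_hi")


def fully_extruded_fraction(
    contacts,
    bound_cbs_plus: Sequence[Motif],
    motifs_minus: Sequence[Motif],
    params: ExtrusionParams = ExtrusionParams(),
) -> ExtrudedStateEstimate:
    """Frequency of the fully extruded CTCF-CTCF state.

    Uses TF-protected upstream fragments with long-range contacts that
    overlap a bound '+' CBS. A partner is convergent when its fragment
    interval overlaps a '-' motif downstream of the CBS. The point estimate
    is the genome-wide convergent/total ratio times the occupancy
    correction; the range is the occupancy-scaled 1st/99th percentile of
    CBS-level values over CBS with >= min_frags fragments.
    """
    cp = params.class_params
    minus_by_chrom: Dict[str, np.ndarray] = {}
    tmp: Dict[str, list] = {}
    for mm in motifs_minus:
        if mm.strand != "-":
            continue
        tmp.setdefault(mm.chrom, []).append(
            (mm.interval.start - params.pad, mm.interval.end + params.pad, mm.center)
        )
    for chrom, ivs in tmp.items():
        minus_by_chrom[chrom] = np.array(sorted(ivs), dtype=np.int64)
    per_motif = _fragments_at_motifs(
        contacts, bound_cbs_plus, cp,
        tf_only=True, upstream_only=True, longrange_only=True,
    )
    rows = []
    total = 0
    convergent = 0
    for m, block in zip(bound_cbs_plus, per_motif):
        if m.strand != "+":
            raise ValueError("bound_cbs_plus must contain '+' motifs only")
        n = len(block)
        if n == 0:
            rows.append((m.chrom, m.center, 0, 0, np.nan))
            continue
        conv = np.zeros(n, dtype=bool)
        arr = minus_by_chrom.get(m.chrom)
        if arr is not None:
            # downstream of a '+' CBS: '-' motif center > CBS center
            down = arr[arr[:, 2] > m.center]
            if len(down):
                ps = block["pstart"].to_numpy()
                pe = block["pend"].to_numpy()
                same = (block["pchrom"] == m.chrom).to_numpy()
                # any '-' motif with start < pend and end > pstart
                maxend = np.maximum.accumulate(down[:, 1])
                j = np.searchsorted(down[:, 0], pe, side="left")
                prev = np.clip(j - 1, 0, len(down) - 1)
                conv = same & (j > 0) & (maxend[prev] > ps)
        total += n
        convergent += int(conv.sum())
        pct = 100.0 * params.occupancy * conv.sum() / n if n >= params.min_frags \
            else np.nan
        rows.append((m.chrom, m.center, n, int(conv.sum()), pct))
    per_cbs = pd.DataFrame(
        rows, columns=["chrom", "center", "n_fragments", "n_convergent", "pct"]
    )
    eligible = per_cbs["pct"].dropna()
    if eligible.empty:
        raise ValueError(
            f"no CBS with >= {params.min_frags} qualifying fragments"
        )
    point = 100.0 * params.occupancy * convergent / total
    lo, hi = np.percentile(eligible.to_numpy(), [1, 99])
    return ExtrudedStateEstimate(
        point=float(point), range_lo=float(lo), range_hi=float(hi),
        n_fragments=total, n_convergent=convergent,
        n_cbs=int(len(eligible)), per_cbs=per_cbs,
    )


# ---------------------------------------------------------------------------
# Chromatin-state annotation of extrusion windows
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Chromatin annotation of the window a CBS-anchored cohesin extrudes
    through (1 Mb downstream of the CBS, motif-strand oriented)."""

    cbs: Motif
    window: GenomicInterval
    state_fractions: Dict[str, float]
    k27ac_bp: int
    pol2_peaks: int
    truncated: bool = False
    group: Optional[str] = None


def _union_bp(ivs: List[Tuple[int, int]]) -> int:
    if not ivs:
        return 0
    ivs = sorted(ivs)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def annotate_region(
    cbs: Motif,
    segmentation: pd.DataFrame,
    peaks_k27ac: Sequence[SignalPeak] = (),
    peaks_pol2: Sequence[SignalPeak] = (),
    window: int = 1_000_000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> RegionAnnotation:
    """Annotate the 1 Mb window downstream of a CBS.

    ``segmentation`` is a ChromHMM-style frame with columns chrom, start,
    end, state (0-based half-open; gaps allowed). State fractions are bp
    overlap divided by the (possibly truncated) window length; the H3K27ac
    covariate is the union bp covered by peaks in the window, the RNAPII
    covariate the count of peaks overlapping the window. Windows running
    past a chromosome end are truncated and flagged.
    """
    c = cbs.center
    if cbs.strand == "+":
        w_start, w_end = c, c + window
    else:
        w_start, w_end = c - window, c + 1
    truncated = False
    if w_start < 0:
        w_start, truncated = 0, True
    if chrom_sizes is not None and cbs.chrom in chrom_sizes:
        size = chrom_sizes[cbs.chrom]
        if w_end > size:
            w_end, truncated = size, True
    if w_end <= w_start:
        raise ValueError("annotation window collapsed to zero length")
    wlen = w_end - w_start
    seg = segmentation[segmentation["chrom"] == cbs.chrom]
    ov_start = np.maximum(seg["start"].to_numpy(), w_start)
    ov_end = np.minimum(seg["end"].to_numpy(), w_end)
    ov = ov_end - ov_start
    keep = ov > 0
    fractions: Dict[str, float] = {}
    if keep.any():
        df = pd.DataFrame({"state": seg["state"].to_numpy()[keep], "bp": ov[keep]})
        for state, bp in df.groupby("state")["bp"].sum().items():
            fractions[state] = float(bp) / wlen
    k27 = [
        (max(p.interval.start, w_start), min(p.interval.end, w_end))
        for p in peaks_k27ac
        if p.chrom == cbs.chrom and p.interval.start < w_end
        and p.interval.end > w_start
    ]
    pol2 = sum(
        1 for p in peaks_pol2
        if p.chrom == cbs.chrom and p.interval.start < w_end
        and p.interval.end > w_start
    )
    return RegionAnnotation(
        cbs=cbs,
        window=GenomicInterval(cbs.chrom, w_start, w_end, cbs.strand),
        state_fractions=fractions,
        k27ac_bp=_union_bp(k27),
        pol2_peaks=pol2,
        truncated=truncated,
    )


_GROUP_KEYWORDS = {
    ACTIVE: ("tss", "enh", "tx", "prom"),
    POLYCOMB_BIVALENT: ("repr", "biv", "pc", "znf"),
    QUIESCENT: ("quies", "het", "low"),
}


def _name_clusters(states: List[str], cluster_ids: np.ndarray) -> Dict[int, str]:
    """Name each cluster by keyword vote over its member state names."""
    names: Dict[int, str] = {}
    used = set()
    for cid in sorted(set(cluster_ids)):
        members = [states[i].lower() for i in np.flatnonzero(cluster_ids == cid)]
        votes = {
            g: sum(any(k in s for k in kws) for s in members)
            for g, kws in _GROUP_KEYWORDS.items()
        }
        best = max(votes, key=lambda g: (votes[g], g))
        if votes[best] == 0 or best in used:
            best = f"GROUP_{cid}"
        used.add(best)
        names[cid] = best
    return names


def group_states(
    annotations: Sequence[RegionAnnotation],
    mapping: Optional[Dict[str, str]] = None,
    n_groups: int = 3,
    top_frac: float = 0.2,
) -> Tuple[Dict[str, str], pd.DataFrame, Dict[str, np.ndarray]]:
    """Collapse chromatin states to groups; find each group's top regions.

    With ``mapping=None`` the states are clustered automatically: Ward
    agglomerative clustering on 1 - Pearson correlation of the per-state
    fraction vectors across regions, cut at ``n_groups``; clusters are
    named by keyword match on state names where possible. With an explicit
    state->group ``mapping``, clustering is skipped.

    Returns (state->group map, per-region group-fraction frame, dict of
    group -> region indices in that group's top ``top_frac`` by summed
    fraction, ties broken toward the lowest region index).
    """
    states = sorted({s for a in annotations for s in a.state_fractions})
    if mapping is None:
        if len(states) < n_groups:
            raise ValueError(
                f"need >= {n_groups} distinct states for automatic grouping"
            )
        mat = np.array([
            [a.state_fractions.get(s, 0.0) for s in states] for a in annotations
        ])
        corr = np.corrcoef(mat.T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="ward")
        cluster_ids = fcluster(z, t=n_groups, criterion="maxclust")
        names = _name_clusters(states, cluster_ids)
        mapping = {s: names[cid] for s, cid in zip(states, cluster_ids)}
    groups = sorted(set(mapping.values()))
    frac = pd.DataFrame(0.0, index=range(len(annotations)), columns=groups)
    for i, a in enumerate(annotations):
        for s, f in a.state_fractions.items():
            g = mapping.get(s)
            if g is not None:
                frac.loc[i, g] += f
    n_top = max(1, int(np.ceil(top_frac * len(annotations))))
    members: Dict[str, np.ndarray] = {}
    for g in groups:
        order = np.lexsort((np.arange(len(frac)), -frac[g].to_numpy()))
        members[g] = np.sort(order[:n_top])
    for i, a in enumerate(annotations):
        a.group = frac.iloc[i].idxmax() if frac.iloc[i].sum() > 0 else None
    return mapping, frac, members


def top_fraction_members(values: np.ndarray, top_frac: float = 0.1,
                         bottom: bool = False) -> np.ndarray:
    """Indices of the top (or bottom) fraction of a covariate, stable ties."""
    n_top = max(1, int(np.ceil(top_frac * len(values))))
    key = values if bottom else -values
    order = np.lexsort((np.arange(len(values)), key))
    return np.sort(order[:n_top])


# ---------------------------------------------------------------------------
# Loop size and the cohesin effect
# ---------------------------------------------------------------------------

@dataclass
class LoopSizeEstimate:
    """Average extruded loop size for a stratum of CBS.

    ``mean_log10`` is the mean log10 interaction length of qualifying
    fragments; ``kb`` is the back-transform 10**mean_log10 / 1000.
    """

    stratum: str
    mean_log10: float
    sd_log10: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a reported estimate requires n >= 1")

    @property
    def kb(self) -> float:
        return 10.0 ** self.mean_log10 / 1000.0

    @property
    def se_log10(self) -> float:
        return self.sd_log10 / np.sqrt(self.n)


def loop_size_by_stratum(
    contacts,
    cbs: Sequence[Motif],
    strata: Dict[str, np.ndarray],
    params: ClassParams = ClassParams(),
    upstream_only: bool = True,
) -> Dict[str, LoopSizeEstimate]:
    """Mean log10 interaction length per CBS stratum.

    ``strata`` maps stratum name -> indices into ``cbs``. Long-range
    TF-protected fragments overlapping the CBS (upstream partners by
    default) are pooled within each stratum. Empty strata are omitted.
    """
    per_motif = _fragments_at_motifs(
        contacts, cbs, params,
        tf_only=True, upstream_only=upstream_only, longrange_only=True,
    )
    out: Dict[str, LoopSizeEstimate] = {}
    for name, idx in strata.items():
        lens: List[np.ndarray] = []
        for i in idx:
            block = per_motif[int(i)]
            if len(block):
                lens.append(block["ilen"].to_numpy())
        if not lens:
            continue
        x = np.log10(np.concatenate(lens).astype(float))
        out[name] = LoopSizeEstimate(
            stratum=name, mean_log10=float(x.mean()),
            sd_log10=float(x.std(ddof=1)) if len(x) > 1 else 0.0, n=len(x),
        )
    return out


def cohesin_effect(
    contacts,
    cbs: Sequence[Motif],
    params: ClassParams = ClassParams(),
) -> Tuple[float, float, pd.DataFrame]:
    """Increase in mean log10 interaction length, TF vs nucleosome fragments.

    For each CBS with at least one fragment of each class, the difference
    of class means is computed; the overall effect is the inverse-variance
    weighted mean of per-CBS differences, with variances built from a
    pooled within-(CBS, class) residual variance so CBS with single-
    fragment classes remain usable. Returns (effect, SE, per-CBS frame).
    """
    per_motif = _fragments_at_motifs(
        contacts, cbs, params,
        tf_only=False, upstream_only=False, longrange_only=False,
    )
    rows = []
    ss = 0.0
    dof = 0
    for m, block in zip(cbs, per_motif):
        if block.empty:
            continue
        block = block[block["ilen"] > 0]
        tf = np.log10(block.loc[block["tf"], "ilen"].to_numpy().astype(float))
        nuc = np.log10(block.loc[block["nuc"], "ilen"].to_numpy().astype(float))
        if len(tf) == 0 or len(nuc) == 0:
            continue
        rows.append((m.chrom, m.center, len(tf), len(nuc),
                     tf.mean() - nuc.mean()))
        for x in (tf, nuc):
            if len(x) > 1:
                ss += float(((x - x.mean()) ** 2).sum())
                dof += len(x) - 1
    if not rows:
        raise ValueError("no CBS with both TF and nucleosome fragments")
    per = pd.DataFrame(rows, columns=["chrom", "center", "n_tf", "n_nuc", "diff"])
    sigma2 = ss / dof if dof > 0 else np.nan
    if not np.isfinite(sigma2) or sigma2 <= 0:
        # degenerate: no residual spread; unweighted mean
        eff = float(per["diff"].mean())
        se = float(per["diff"].std(ddof=1) / np.sqrt(len(per))) if len(per) > 1 else 0.0
        return eff, se, per
    var = sigma2 * (1.0 / per["n_tf"].to_numpy() + 1.0 / per["n_nuc"].to_numpy())
    w = 1.0 / var
    eff = float(np.sum(w * per["diff"].to_numpy()) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return eff, se, per
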