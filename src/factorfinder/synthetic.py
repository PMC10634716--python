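"""Synthetic MNase HiChIP contact generator with planted ground truth.

The generator emulates the features of CTCF MNase HiChIP that the analysis
stages consume, each with a planted, recoverable parameter:

* bimodal fragment lengths: ~40-60 bp TF-protected fragments from MNase
  cutting around bound CTCF (protected span +/- cut jitter), 147 bp
  nucleosome fragments censored by the 150 bp read length;
* strand-specific 5'-end bimodality at bound motifs (a '+' read starts at
  the fragment's left edge, upstream of the motif; a '-' read at its right
  edge, downstream) — the quadrant enrichment arises by construction;
* ~200 bp phased nucleosome arrays around motifs;
* observed-ligation censoring at read_length - 25 mappable bp;
* a cohesin footprint: extra downstream protection on TF fragments whose
  contact partner lies downstream (the looping orientation), planted only
  at cohesin-positive (high RAD21) motifs;
* a contact-distance model: s^-1 power-law background plus a log-normal
  (in log10 distance) extruded component whose mean is set per chromatin
  group, so the mean-log10 loop-size estimand equals the planted value;
* a plantable convergent CTCF-CTCF capture fraction c: upstream TF
  fragments at a bound '+' motif ligate to a dedicated downstream '-'
  motif with probability c; non-convergent extruded partners are
  resampled away from '-' motifs so c is exactly the conditional
  convergence among long-range upstream TF fragments.

MNase cut bias is not modeled: cutting is uniform within accessible
linker, which is this simulator's declared simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import extrusion as _ex
from .readwrite import (
    empty_contact_frame, order_contact_frame, write_contacts, write_motifs,
    write_signal_peaks,
)
from .types import GenomicInterval, Motif, SignalPeak

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimResult",
    "simulate_dataset",
    "simulate_null_region",
    "benchmark_config",
    "recovery_config",
    "write_dataset",
]

#: 15 ChromHMM-like states in three planted groups of five.
STATE_GROUPS: Dict[str, Tuple[str, ...]] = {
    _ex.ACTIVE: ("TssA", "TssFlnk", "TxFlnk", "Tx", "EnhA"),
    _ex.POLYCOMB_BIVALENT: ("ReprPC", "ReprPCWk", "BivTss", "BivEnh", "ZNF"),
    _ex.QUIESCENT: ("Quies", "QuiesWk", "Het", "QuiesLow", "Quies2"),
}
STATE_TO_GROUP = {s: g for g, ss in STATE_GROUPS.items() for s in ss}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated dataset.

    Key planted parameters: ``occupancy`` (theta, fraction of cells with
    CTCF bound at a bound motif; ~50% genome average), ``convergent_capture``
    (c, conditional probability that a long-range upstream TF fragment at a
    bound '+' motif ligates to its downstream convergent '-' motif),
    ``group_log10_size`` (lambda, per-chromatin-group mean log10 extruded
    distance; defaults are the active/quiescent contrast of ~144 kb vs
    ~252 kb), and ``class_effect_delta`` (delta, deficit in mean log10
    contact distance of nucleosome- vs TF-protected fragments at the same
    motif).
    """

    chrom: str = "chrS"
    n_bound: int = 1000
    n_decoy: int = 1000
    spacing: int = 5000
    motif_width: int = 19
    bound_plus_frac: float = 0.5
    occupancy: float = 0.5
    depth_mean: float = 50.0
    ctcf_protect: int = 40
    cut_jitter: int = 10
    cohesin_ext: int = 40
    cohesin_frac: float = 0.5
    nucleosome_len: int = 147
    nucleosome_spacing: int = 200
    nucleosome_jitter: int = 10
    read_length: int = 150
    min_mappable: int = 25
    background_fraction: float = 0.10
    bg_s_lo: int = 1000
    bg_s_hi: int = 2_000_000
    convergent_capture: float = 0.10
    partner_short_prob: float = 0.3
    group_log10_size: Dict[str, float] = field(default_factory=lambda: {
        _ex.ACTIVE: 5.16, _ex.POLYCOMB_BIVALENT: 5.28, _ex.QUIESCENT: 5.40,
    })
    frag_log10_sd: float = 0.25
    cbs_log10_sd: float = 0.05
    class_effect_delta: float = 0.4
    region_window: int = 1_000_000
    seg_tile: int = 2000
    dominant_state_prob: float = 0.8
    k27ac_rate: Dict[str, float] = field(default_factory=lambda: {
        _ex.ACTIVE: 30.0, _ex.POLYCOMB_BIVALENT: 8.0, _ex.QUIESCENT: 2.0,
    })
    pol2_rate: Dict[str, float] = field(default_factory=lambda: {
        _ex.ACTIVE: 25.0, _ex.POLYCOMB_BIVALENT: 6.0, _ex.QUIESCENT: 1.0,
    })

    def __post_init__(self) -> None:
        for p in (self.occupancy, self.convergent_capture, self.cohesin_frac,
                  self.background_fraction, self.partner_short_prob,
                  self.bound_plus_frac, self.dominant_state_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability parameter out of [0, 1]: {p}")
        if self.spacing <= 0 or self.depth_mean < 0:
            raise ValueError("spacing must be > 0 and depth_mean >= 0")

    @property
    def observed_max_len(self) -> int:
        return self.read_length - self.min_mappable

    @property
    def genome_length(self) -> int:
        n = self.n_bound + self.n_decoy
        return (n + 1) * self.spacing + self.region_window + self.bg_s_hi + 200_000


@dataclass
class TruthSet:
    """Planted ground truth consistent with the emitted contacts."""

    bound_motifs: List[Motif]
    decoy_motifs: List[Motif]
    partner_minus_motifs: List[Motif]
    rad21_peaks: List[SignalPeak]
    k27ac_peaks: List[SignalPeak]
    pol2_peaks: List[SignalPeak]
    segmentation: pd.DataFrame
    cohesin_flags: np.ndarray          # per bound motif
    groups: List[Optional[str]]        # per bound motif ('+' motifs annotated)
    state_to_group: Dict[str, str]
    params: Dict[str, object]
    true_lengths: pd.DataFrame         # len1/len2 before censoring

    @property
    def bound_plus(self) -> List[Motif]:
        return [m for m in self.bound_motifs if m.strand == "+"]

    @property
    def groups_plus(self) -> List[str]:
        return [g for m, g in zip(self.bound_motifs, self.groups)
                if m.strand == "+"]


@dataclass
class SimResult:
    contacts: pd.DataFrame
    truth: TruthSet


def _power_law_s(rng, n, s_lo, s_hi) -> np.ndarray:
    """Distances with density proportional to 1/s on [s_lo, s_hi]."""
    u = rng.random(n)
    return np.round(s_lo * (s_hi / s_lo) ** u).astype(np.int64)


def _make_motif(chrom, center, width, strand, name, score=0.0) -> Motif:
    half = width // 2
    return Motif(GenomicInterval(chrom, center - half, center - half + width,
                                 strand), score=score, name=name)


def simulate_dataset(config: SimConfig, seed: Optional[int] = None) -> SimResult:
    """Generate contacts plus a full truth set; deterministic under seed."""
    rng = np.random.default_rng(seed)
    cfg = config
    L = cfg.genome_length
    n_mot = cfg.n_bound + cfg.n_decoy
    slots = cfg.spacing * (np.arange(n_mot) + 1)
    bound_idx = np.sort(rng.permutation(n_mot)[: cfg.n_bound])
    is_bound = np.zeros(n_mot, dtype=bool)
    is_bound[bound_idx] = True

    bound_centers = slots[is_bound]
    decoy_centers = slots[~is_bound]
    plus = rng.random(cfg.n_bound) < cfg.bound_plus_frac
    bound_strands = np.where(plus, "+", "-")
    cohesin = rng.random(cfg.n_bound) < cfg.cohesin_frac

    group_names = list(cfg.group_log10_size)
    groups = [group_names[i % len(group_names)] for i in range(cfg.n_bound)]
    lam = np.array([cfg.group_log10_size[g] for g in groups])
    mu = lam + rng.normal(0.0, cfg.cbs_log10_sd, cfg.n_bound)

    bound_motifs = [
        _make_motif(cfg.chrom, int(c), cfg.motif_width, s, f"bound_{i}")
        for i, (c, s) in enumerate(zip(bound_centers, bound_strands))
    ]
    decoy_motifs = [
        _make_motif(cfg.chrom, int(c), cfg.motif_width,
                    "+" if rng.random() < 0.5 else "-", f"decoy_{i}")
        for i, c in enumerate(decoy_centers)
    ]

    # dedicated downstream convergent '-' motif per bound '+' motif
    partner_center = np.full(cfg.n_bound, -1, dtype=np.int64)
    partner_minus: List[Motif] = []
    for i in np.flatnonzero(plus):
        d = int(round(10 ** rng.normal(mu[i], cfg.frag_log10_sd)))
        d = max(d, 12_000)
        pc = min(int(bound_centers[i]) + d, L - 1000)
        partner_center[i] = pc
        partner_minus.append(
            _make_motif(cfg.chrom, pc, cfg.motif_width, "-", f"conv_{i}")
        )
    minus_iv = np.array(
        sorted((m.interval.start, m.interval.end) for m in partner_minus),
        dtype=np.int64,
    ).reshape(-1, 2)

    half = cfg.ctcf_protect // 2
    nhalf = cfg.nucleosome_len // 2

    def emit_motif_fragments(centers, strands, theta, mu_arr, coh, pcenters):
        """Vectorized fragment emission for one motif set."""
        n_per = rng.poisson(cfg.depth_mean, len(centers))
        idx = np.repeat(np.arange(len(centers)), n_per)
        M = len(idx)
        if M == 0:
            empty = pd.DataFrame()
            return empty, np.zeros(0, np.int64), np.zeros(0, np.int64)
        c = centers[idx]
        sm = strands[idx]
        is_plus_m = sm == "+"
        tf = rng.random(M) < theta

        # contact distances drawn first so the partner direction can be
        # constrained to stay inside the genome (no edge pile-ups)
        mu_f = mu_arr[idx] - cfg.class_effect_delta * (~tf)
        d = np.round(10 ** rng.normal(mu_f, cfg.frag_log10_sd)).astype(np.int64)
        d = np.maximum(d, 200)
        down = rng.random(M) < 0.5
        down[c - d < 300] = True
        down[c + d > L - 300] = False
        upstream = np.where(is_plus_m, down, ~down)

        j1 = rng.integers(0, cfg.cut_jitter + 1, M)
        j2 = rng.integers(0, cfg.cut_jitter + 1, M)
        s_tf = c - half - j1
        e_tf = c + half + j2
        ext = tf & coh[idx] & upstream
        e_tf = np.where(ext & is_plus_m, e_tf + cfg.cohesin_ext, e_tf)
        s_tf = np.where(ext & ~is_plus_m, s_tf - cfg.cohesin_ext, s_tf)

        k = rng.integers(-2, 3, M)
        cn = c + k * cfg.nucleosome_spacing + np.round(
            rng.normal(0, cfg.nucleosome_jitter, M)).astype(np.int64)
        s_nuc = cn - nhalf
        e_nuc = s_nuc + cfg.nucleosome_len

        s = np.where(tf, s_tf, s_nuc)
        e = np.where(tf, e_tf, e_nuc)
        flen = e - s
        fstrand = rng.random(M) < 0.5  # True => '+'
        pos5 = np.where(fstrand, s, e - 1)

        conv = tf & is_plus_m & down & (pcenters[idx] >= 0) \
            & (rng.random(M) < cfg.convergent_capture)

        # keep non-convergent partners of '+'-motif upstream TF fragments
        # off '-' motifs so the planted conditional convergence is exact
        if len(minus_iv):
            need = tf & is_plus_m & down & ~conv
            for _ in range(30):
                bad = np.zeros(M, dtype=bool)
                pc_probe = c + d
                j = np.searchsorted(minus_iv[:, 0], pc_probe[need] + 100)
                prev = np.clip(j - 1, 0, len(minus_iv) - 1)
                hit = (j > 0) & (minus_iv[prev, 1] > pc_probe[need] - 100)
                bad[np.flatnonzero(need)[hit]] = True
                if not bad.any():
                    break
                d[bad] = np.maximum(np.round(
                    10 ** rng.normal(mu_f[bad], cfg.frag_log10_sd)
                ).astype(np.int64), 200)

        pcen = np.where(down, c + d, c - d)
        pcen = np.clip(pcen, 200, L - 200)
        pcen = np.where(conv, pcenters[idx], pcen)

        p_short = rng.random(M) < cfg.partner_short_prob
        plen = np.where(p_short, rng.integers(40, 81, M), cfg.nucleosome_len)
        ps = pcen - plen // 2
        pe = ps + plen
        # convergent partners are TF-like fragments on the '-' motif
        pj1 = rng.integers(0, cfg.cut_jitter + 1, M)
        pj2 = rng.integers(0, cfg.cut_jitter + 1, M)
        ps = np.where(conv, pcen - half - pj1, ps)
        pe = np.where(conv, pcen + half + pj2, pe)
        plen = pe - ps
        pstrand = rng.random(M) < 0.5
        ppos5 = np.where(pstrand, ps, pe - 1)

        frame = pd.DataFrame({
            "chrom1": cfg.chrom, "pos1": pos5,
            "strand1": np.where(fstrand, "+", "-"),
            "len1": flen, "obs1": flen <= cfg.observed_max_len,
            "chrom2": cfg.chrom, "pos2": ppos5,
            "strand2": np.where(pstrand, "+", "-"),
            "len2": plen, "obs2": plen <= cfg.observed_max_len,
        })
        return frame, flen.copy(), plen.copy()

    frames = []
    lens1 = []
    lens2 = []
    f, l1, l2 = emit_motif_fragments(
        bound_centers, bound_strands, cfg.occupancy, mu, cohesin, partner_center
    )
    if len(f):
        frames.append(f); lens1.append(l1); lens2.append(l2)
    decoy_strands = np.array([m.strand for m in decoy_motifs])
    f, l1, l2 = emit_motif_fragments(
        decoy_centers, decoy_strands, 0.0,
        np.full(cfg.n_decoy, 5.0), np.zeros(cfg.n_decoy, bool),
        np.full(cfg.n_decoy, -1, np.int64),
    )
    if len(f):
        frames.append(f); lens1.append(l1); lens2.append(l2)

    n_signal_reads = sum(2 * len(fr) for fr in frames)
    if cfg.background_fraction > 0 and n_signal_reads:
        bf = cfg.background_fraction
        n_bg = int(round(bf / (1 - bf) * n_signal_reads / 2))
        pos = rng.integers(1000, L - cfg.bg_s_hi - 1000, n_bg)
        d = _power_law_s(rng, n_bg, cfg.bg_s_lo, cfg.bg_s_hi)
        l1b = rng.integers(30, 121, n_bg)
        l2b = rng.integers(30, 121, n_bg)
        frames.append(pd.DataFrame({
            "chrom1": cfg.chrom, "pos1": pos,
            "strand1": np.where(rng.random(n_bg) < 0.5, "+", "-"),
            "len1": l1b, "obs1": True,
            "chrom2": cfg.chrom, "pos2": pos + d,
            "strand2": np.where(rng.random(n_bg) < 0.5, "+", "-"),
            "len2": l2b, "obs2": True,
        }))
        lens1.append(l1b); lens2.append(l2b)

    contacts = (pd.concat(frames, ignore_index=True) if frames
                else empty_contact_frame())
    true_lengths = pd.DataFrame({
        "len1": np.concatenate(lens1) if lens1 else np.zeros(0, np.int64),
        "len2": np.concatenate(lens2) if lens2 else np.zeros(0, np.int64),
    })
    if len(contacts):
        contacts.loc[~contacts["obs1"], "len1"] = 0
        contacts.loc[~contacts["obs2"], "len2"] = 0
        contacts = order_contact_frame(contacts)

    # RAD21 peaks at bound motifs: strong where cohesin was planted
    rad21 = []
    for i, m in enumerate(bound_motifs):
        sig = rng.uniform(60, 100) if cohesin[i] else rng.uniform(1, 40)
        rad21.append(SignalPeak(
            GenomicInterval(cfg.chrom, m.center - 15, m.center + 15),
            signal_value=float(sig), name=f"rad21_{i}",
        ))

    # chromatin-state segmentation + activity peaks over '+' CBS windows
    seg_rows = []
    k27: List[SignalPeak] = []
    pol2: List[SignalPeak] = []
    covered_to = 0
    group_labels: List[Optional[str]] = []
    all_states = [s for ss in STATE_GROUPS.values() for s in ss]
    for i, m in enumerate(bound_motifs):
        if m.strand != "+":
            group_labels.append(None)
            continue
        g = groups[i]
        group_labels.append(g)
        w_start = m.center
        w_end = min(m.center + cfg.region_window, L)
        own = STATE_GROUPS[g]
        others = [s for s in all_states if s not in own]
        t0 = max(w_start, covered_to)
        tiles = np.arange(t0, w_end, cfg.seg_tile)
        if len(tiles):
            dom = rng.random(len(tiles)) < cfg.dominant_state_prob
            pick_own = rng.integers(0, len(own), len(tiles))
            pick_oth = rng.integers(0, len(others), len(tiles))
            for t, isdom, po, pf in zip(tiles, dom, pick_own, pick_oth):
                state = own[po] if isdom else others[pf]
                seg_rows.append((cfg.chrom, int(t),
                                 int(min(t + cfg.seg_tile, w_end)), state))
            covered_to = max(covered_to, w_end)
        for rate, store, width, tag in (
            (cfg.k27ac_rate[g], k27, 1000, "k27ac"),
            (cfg.pol2_rate[g], pol2, 300, "pol2"),
        ):
            n_p = rng.poisson(rate)
            if n_p:
                starts = rng.integers(w_start, max(w_end - width, w_start + 1), n_p)
                for j, st in enumerate(np.sort(starts)):
                    store.append(SignalPeak(
                        GenomicInterval(cfg.chrom, int(st), int(st) + width),
                        signal_value=float(rng.uniform(1, 10)),
                        name=f"{tag}_{i}_{j}",
                    ))

    segmentation = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "state"]
    )
    truth = TruthSet(
        bound_motifs=bound_motifs,
        decoy_motifs=decoy_motifs,
        partner_minus_motifs=partner_minus,
        rad21_peaks=rad21,
        k27ac_peaks=k27,
        pol2_peaks=pol2,
        segmentation=segmentation,
        cohesin_flags=cohesin,
        groups=group_labels,
        state_to_group=dict(STATE_TO_GROUP),
        params={
            "occupancy": cfg.occupancy,
            "convergent_capture": cfg.convergent_capture,
            "group_log10_size": dict(cfg.group_log10_size),
            "class_effect_delta": cfg.class_effect_delta,
            "seed": seed,
        },
        true_lengths=true_lengths,
    )
    return SimResult(contacts=contacts, truth=truth)


def simulate_null_region(
    length: int, n_reads: int, seed: Optional[int] = None,
    chrom: str = "chrN",
) -> pd.DataFrame:
    """Structure-free contacts: uniform 5' positions, fair strands.

    ``n_reads`` observed-ligation reads (sides) are paired arbitrarily into
    ``n_reads // 2`` contacts; every read is an independent uniform draw,
    so quadrant counts at any center are exchangeable across quadrants.
    """
    rng = np.random.default_rng(seed)
    n = n_reads // 2
    if n == 0:
        return empty_contact_frame()
    frame = pd.DataFrame({
        "chrom1": chrom,
        "pos1": rng.integers(0, length, n),
        "strand1": np.where(rng.random(n) < 0.5, "+", "-"),
        "len1": rng.integers(30, 121, n), "obs1": True,
        "chrom2": chrom,
        "pos2": rng.integers(0, length, n),
        "strand2": np.where(rng.random(n) < 0.5, "+", "-"),
        "len2": rng.integers(30, 121, n), "obs2": True,
    })
    return order_contact_frame(frame)


def benchmark_config(**overrides) -> SimConfig:
    """The default peak-calling benchmark: 1,000 bound motifs at 0.8
    occupancy with ~50 fragments each, 1,000 nucleosome-occupied decoys,
    and uniform background noise at 10% of reads."""
    base = dict(n_bound=1000, n_decoy=1000, spacing=5000,
                occupancy=0.8, depth_mean=50.0, background_fraction=0.10)
    base.update(overrides)
    return SimConfig(**base)


def recovery_config(**overrides) -> SimConfig:
    """A compact configuration for parameter-recovery studies: sparse '+'
    CBS with non-overlapping 1 Mb downstream windows and deep coverage so
    every CBS clears the fully-extruded min-fragment filter."""
    base = dict(n_bound=45, n_decoy=5, spacing=1_100_000,
                bound_plus_frac=1.0, occupancy=0.8, depth_mean=160.0,
                background_fraction=0.05, convergent_capture=0.12)
    base.update(overrides)
    return SimConfig(**base)


def write_dataset(sim: SimResult, outdir) -> Dict[str, str]:
    """Write contacts, truth BEDs and planted parameters; returns paths."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "contacts.pairs"
    write_contacts(sim.contacts, p)
    paths["contacts"] = str(p)
    for name, motifs in (
        ("bound_motifs", sim.truth.bound_motifs),
        ("decoy_motifs", sim.truth.decoy_motifs),
        ("partner_minus_motifs", sim.truth.partner_minus_motifs),
    ):
        p = outdir / f"{name}.bed"
        write_motifs(motifs, p)
        paths[name] = str(p)
    for name, peaks in (
        ("rad21", sim.truth.rad21_peaks),
        ("k27ac", sim.truth.k27ac_peaks),
        ("pol2", sim.truth.pol2_peaks),
    ):
        p = outdir / f"{name}.narrowPeak"
        write_signal_peaks(peaks, p)
        paths[name] = str(p)
    p = outdir / "chromhmm.bed"
    sim.truth.segmentation.to_csv(p, sep="\t", header=False, index=False)
    paths["segmentation"] = str(p)
    p = outdir / "planted_params.json"
    p.write_text(json.dumps(sim.truth.params, indent=2) + "\n")
    paths["params"] = str(p)
    return paths
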