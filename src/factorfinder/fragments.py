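"""Fragment-level semantics: intervals, protection classes, partner labels.

MNase digestion leaves fragments whose length reflects the protecting
protein: ~30-60 bp for a bound transcription factor such as CTCF, ~147 bp
for a nucleosome. The ligation junction of a proximity-ligation pair is
observed inside a read only when the pre-ligation fragment is short enough
for both pieces to map (read length minus a minimum mappable stub), so an
"observed ligation" is a proxy for a short, TF-protected fragment; all
longer fragments are length-censored.

Classification thresholds used across the analyses are centralized in
:class:`ClassParams` rather than unified: the short-fragment proxy cutoff
(~125 bp), the TF/nucleosome boundary (115 bp), the cohesin mid-size band
(80-120 bp) and the long-range cutoff (10 kb) serve different filters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .readwrite import as_contact_frame
from .types import Contact, ContactSide, GenomicInterval, Motif

__all__ = [
    "ClassParams",
    "FragmentClass",
    "PartnerOrientation",
    "fragment_interval",
    "classify_fragment",
    "interaction_length",
    "partner_orientation",
    "side_table",
]


class FragmentClass(enum.Enum):
    TF_PROTECTED = "TF_PROTECTED"
    NUCLEOSOME = "NUCLEOSOME"
    EXCLUDED = "EXCLUDED"


class PartnerOrientation(enum.Enum):
    """Label of a motif-overlapping (focal) fragment by where its partner is.

    A focal fragment is UPSTREAM when its interaction partner lies on the
    motif-downstream side — the looping direction of a cohesin stabilized at
    CTCF's N-terminal (downstream) face. Downstream is to the right of a
    '+' motif and to the left of a '-' motif in reference coordinates.
    """

    UPSTREAM_FRAGMENT = "UPSTREAM_FRAGMENT"
    DOWNSTREAM_FRAGMENT = "DOWNSTREAM_FRAGMENT"


@dataclass(frozen=True)
class ClassParams:
    """Thresholds for fragment classification and length-based filters.

    All lengths in bp.

    tf_max_len : fragments shorter than this (with clear motif-center
        margins) approximate CTCF +/- cohesin-protected DNA.
    min_edge_dist : both fragment edges must be at least this far from the
        motif center to avoid MNase cut sites under the bound protein.
    short_proxy_max : maximum fragment length identifiable via an observed
        ligation (~read_length - 25 mappable stub).
    midsize_range : closed length band approximating CTCF+cohesin-protected
        fragments, used for the cohesin footprint.
    longrange_min : contacts farther than this are "long range".
    """

    tf_max_len: int = 115
    min_edge_dist: int = 15
    short_proxy_max: int = 125
    midsize_range: Tuple[int, int] = (80, 120)
    longrange_min: int = 10_000
    read_length: int = 150
    min_mappable: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.tf_max_len < self.read_length):
            raise ValueError("require 0 < tf_max_len < read_length")
        lo, hi = self.midsize_range
        if not (1 <= lo <= hi <= self.read_length):
            raise ValueError("midsize_range must lie within [1, read_length]")

    @property
    def observed_max_len(self) -> int:
        """Maximum fragment length an observed ligation can reveal."""
        return self.read_length - self.min_mappable


def fragment_interval(
    side: ContactSide,
    read_length: int = 150,
    nominal_censored: bool = False,
) -> Optional[GenomicInterval]:
    """Genomic interval covered by a side's pre-ligation fragment.

    The 5' read end anchors the fragment: a '+' read starts at the fragment's
    left edge, a '-' read at its right edge. Returns ``None`` for a censored
    side unless ``nominal_censored`` is set, in which case the read length is
    used as the nominal fragment length (censored fragments are known to be
    at least that long minus the mappable stub).
    """
    flen = side.frag_len
    if flen is None:
        if not nominal_censored:
            return None
        flen = read_length
    elif flen > read_length:
        raise ValueError(
            f"observed fragment length {flen} exceeds read length {read_length}"
        )
    if side.strand == "+":
        start = side.pos5
    else:
        start = side.pos5 - flen + 1
    start = max(start, 0)
    return GenomicInterval(side.chrom, start, start + flen, side.strand)


def classify_fragment(
    side: ContactSide, motif: Motif, params: ClassParams = ClassParams()
) -> FragmentClass:
    """TF/nucleosome classification of a motif-overlapping fragment.

    TF_PROTECTED: known length < ``tf_max_len`` and both fragment edges at
    least ``min_edge_dist`` bp from the motif center. NUCLEOSOME: length at
    least ``tf_max_len``, or censored (hence long). EXCLUDED: short but with
    an edge too close to the center (cut site under the protein).
    """
    if side.is_censored or side.frag_len >= params.tf_max_len:
        return FragmentClass.NUCLEOSOME
    iv = fragment_interval(side, read_length=params.read_length)
    c = motif.center
    # edges: leftmost base iv.start, rightmost base iv.end - 1
    if min(abs(iv.start - c), abs(iv.end - 1 - c)) >= params.min_edge_dist:
        return FragmentClass.TF_PROTECTED
    return FragmentClass.EXCLUDED


def interaction_length(contact: Contact) -> Optional[int]:
    """Genomic separation of a cis contact's 5' ends; ``None`` for trans.

    Defined from the two ``pos5`` values (not fragment midpoints) so that it
    exists for censored sides too. Trans contacts return ``None`` and are
    excluded from all length-based analyses.
    """
    if not contact.is_cis:
        return None
    return abs(contact.side2.pos5 - contact.side1.pos5)


def partner_orientation(
    contact: Contact,
    focal: int,
    motif: Motif,
    read_length: int = 150,
) -> Optional[PartnerOrientation]:
    """Classify the focal (motif-overlapping) fragment by partner direction.

    The focal fragment is UPSTREAM iff the partner lies on the
    motif-downstream side (higher coordinates for a '+' motif, lower for
    '-'). Returns ``None`` when the partner fragment itself overlaps the
    motif (direction ambiguous) or the contact is trans.
    """
    if focal not in (1, 2):
        raise ValueError("focal must be 1 or 2")
    if not contact.is_cis:
        return None
    partner = contact.side2 if focal == 1 else contact.side1
    piv = fragment_interval(partner, read_length=read_length, nominal_censored=True)
    if piv.overlaps(motif.interval):
        return None
    downstream_of_motif = piv.start > motif.center
    if motif.strand == "-":
        downstream_of_motif = not downstream_of_motif
    if downstream_of_motif:
        return PartnerOrientation.UPSTREAM_FRAGMENT
    return PartnerOrientation.DOWNSTREAM_FRAGMENT


def side_table(contacts, read_length: int = 150) -> pd.DataFrame:
    """Long-format per-side table for vectorized fragment analyses.

    One row per contact side, with nominal fragment intervals for censored
    sides (length = ``read_length``), partner coordinates and the cis
    interaction length (NaN for trans).

    Columns: chrom, pos5, strand, obs, flen (0 where censored), start, end,
    pchrom, ppos5, pstart, pend, cis, ilen, side.
    """
    frame = as_contact_frame(contacts)
    parts = []
    for i, j in ((1, 2), (2, 1)):
        chrom = frame[f"chrom{i}"].to_numpy()
        pos = frame[f"pos{i}"].to_numpy()
        strand = frame[f"strand{i}"].to_numpy()
        obs = frame[f"obs{i}"].to_numpy()
        flen = frame[f"len{i}"].to_numpy()
        nominal = np.where(obs, flen, read_length)
        start = np.where(strand == "+", pos, pos - nominal + 1)
        start = np.maximum(start, 0)
        pchrom = frame[f"chrom{j}"].to_numpy()
        ppos = frame[f"pos{j}"].to_numpy()
        pobs = frame[f"obs{j}"].to_numpy()
        pflen = frame[f"len{j}"].to_numpy()
        pnominal = np.where(pobs, pflen, read_length)
        pstrand = frame[f"strand{j}"].to_numpy()
        pstart = np.where(pstrand == "+", ppos, ppos - pnominal + 1)
        pstart = np.maximum(pstart, 0)
        cis = chrom == pchrom
        ilen = np.where(cis, np.abs(ppos - pos), -1)
        parts.append(pd.DataFrame({
            "chrom": chrom, "pos5": pos, "strand": strand,
            "obs": obs, "flen": flen,
            "start": start, "end": start + nominal,
            "pchrom": pchrom, "ppos5": ppos,
            "pstart": pstart, "pend": pstart + pnominal,
            "cis": cis, "ilen": ilen,
            "side": i,
        }))
    return pd.concat(parts, ignore_index=True)
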