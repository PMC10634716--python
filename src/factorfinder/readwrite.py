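"""Readers and writers for BED-family files and the extended pairs dialect.

Coordinate conventions
----------------------
* BED3 / BED6 / narrowPeak: 0-based half-open on disk, kept as-is in memory.
* Extended pairs dialect: positions are **1-based** on disk (pairs ecosystem
  convention) and converted to 0-based ``pos5`` on read; a fragment length of
  ``-1`` on disk means censored (ligation junction not observed) and becomes
  ``None`` / ``obs=False`` in memory.

The extended pairs dialect is this package's own reconstruction of a
post-``pairtools parse`` contact table carrying per-side fragment length; it
requires the header line::

    #columns: chrom1 pos1 strand1 chrom2 pos2 strand2 frag_len1 frag_len2

Bulk analyses use a pandas DataFrame "contact frame" with columns
``chrom1 pos1 strand1 len1 obs1 chrom2 pos2 strand2 len2 obs2`` (sides
ordered by ``(chrom, pos)``); converters to/from lists of
:class:`~factorfinder.types.Contact` are provided.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .types import Contact, ContactSide, GenomicInterval, Motif, SignalPeak

PAIRS_COLUMNS = (
    "chrom1 pos1 strand1 chrom2 pos2 strand2 frag_len1 frag_len2"
)
PAIRS_HEADER = f"#columns: {PAIRS_COLUMNS}"

FRAME_COLUMNS = [
    "chrom1", "pos1", "strand1", "len1", "obs1",
    "chrom2", "pos2", "strand2", "len2", "obs2",
]


def empty_contact_frame() -> pd.DataFrame:
    """A zero-row contact frame with the standard columns and dtypes."""
    return pd.DataFrame({
        "chrom1": pd.Series(dtype=str), "pos1": pd.Series(dtype=np.int64),
        "strand1": pd.Series(dtype=str), "len1": pd.Series(dtype=np.int64),
        "obs1": pd.Series(dtype=bool),
        "chrom2": pd.Series(dtype=str), "pos2": pd.Series(dtype=np.int64),
        "strand2": pd.Series(dtype=str), "len2": pd.Series(dtype=np.int64),
        "obs2": pd.Series(dtype=bool),
    })


class BedParseError(ValueError):
    """Malformed line in a BED-family file."""


class PairsParseError(ValueError):
    """Malformed line or header in an extended pairs file."""


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------

def _bed_fields(path, min_fields: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_fields} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            yield lineno, fields, start, end


def read_bed(path, with_score: bool = False) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals (file order preserved, 0-based half-open).

    With ``with_score=True`` a BED6 is required and scores/strands are kept
    on the returned intervals' companion list; for scored, stranded motif
    files prefer :func:`read_motifs`.
    """
    out = []
    for lineno, fields, start, end in _bed_fields(path, 6 if with_score else 3):
        strand = fields[5] if len(fields) >= 6 else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand))
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_motifs(path) -> List[Motif]:
    """Read a BED6 of stranded motif instances (score column 5)."""
    out = []
    for lineno, fields, start, end in _bed_fields(path, 6):
        try:
            score = float(fields[4]) if fields[4] != "." else 0.0
            out.append(
                Motif(GenomicInterval(fields[0], start, end, fields[5]),
                      score=score, name=fields[3])
            )
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_signal_peaks(path) -> List[SignalPeak]:
    """Read ChIP-seq peaks from BED5+/narrowPeak.

    Column 7 (signalValue) is used when present (narrowPeak), else column 5;
    column 10 (summit offset) is used when present and non-negative.
    """
    out = []
    for lineno, fields, start, end in _bed_fields(path, 5):
        try:
            if len(fields) >= 7:
                signal = float(fields[6])
            else:
                signal = float(fields[4])
            summit = None
            if len(fields) >= 10 and int(fields[9]) >= 0:
                summit = int(fields[9])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            out.append(
                SignalPeak(GenomicInterval(fields[0], start, end, strand),
                           signal_value=signal, summit_offset=summit,
                           name=fields[3])
            )
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_motifs(motifs: Iterable[Motif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            iv = m.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.name}\t{m.score}\t{iv.strand}\n")


def write_signal_peaks(peaks: Iterable[SignalPeak], path) -> None:
    """Write peaks in narrowPeak layout (signalValue in column 7)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                f"\t{p.signal_value}\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# Extended pairs dialect
# ---------------------------------------------------------------------------

def read_contacts_frame(path, read_length: int = 150) -> pd.DataFrame:
    """Read an extended pairs file into a contact frame.

    Positions become 0-based; ``obs`` flags are set from ``frag_len != -1``;
    sides are ordered by ``(chrom, pos)``.
    """
    header_ok = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.strip() == PAIRS_HEADER:
                header_ok = True
    if not header_ok:
        raise PairsParseError(
            f"{path}: missing required header line {PAIRS_HEADER!r}"
        )
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=PAIRS_COLUMNS.split(),
        dtype={"chrom1": str, "chrom2": str},
    )
    if df.empty:
        return empty_contact_frame()
    for col in ("pos1", "pos2", "frag_len1", "frag_len2"):
        if df[col].isna().any():
            bad = int(df[col].isna().idxmax()) + 1
            raise PairsParseError(f"{path}: missing value in column {col}, record {bad}")
    for col in ("pos1", "pos2"):
        if (df[col] <= 0).any():
            bad = int((df[col] <= 0).idxmax()) + 1
            raise PairsParseError(
                f"{path}: record {bad}: positions are 1-based on disk and must be > 0"
            )
    for col in ("frag_len1", "frag_len2"):
        fl = df[col]
        if ((fl != -1) & ((fl < 1) | (fl > read_length))).any():
            raise PairsParseError(
                f"{path}: observed fragment lengths must be in [1, {read_length}]"
            )
    out = pd.DataFrame({
        "chrom1": df["chrom1"],
        "pos1": (df["pos1"] - 1).astype(np.int64),
        "strand1": df["strand1"],
        "len1": df["frag_len1"].astype(np.int64),
        "obs1": (df["frag_len1"] != -1).to_numpy(),
        "chrom2": df["chrom2"],
        "pos2": (df["pos2"] - 1).astype(np.int64),
        "strand2": df["strand2"],
        "len2": df["frag_len2"].astype(np.int64),
        "obs2": (df["frag_len2"] != -1).to_numpy(),
    })
    out.loc[~out["obs1"], "len1"] = 0
    out.loc[~out["obs2"], "len2"] = 0
    return order_contact_frame(out)


def order_contact_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Enforce the side-ordering invariant (side1 <= side2 by chrom, pos)."""
    frame = frame.copy()
    swap = (frame["chrom2"] < frame["chrom1"]) | (
        (frame["chrom2"] == frame["chrom1"]) & (frame["pos2"] < frame["pos1"])
    )
    if swap.any():
        cols1 = ["chrom1", "pos1", "strand1", "len1", "obs1"]
        cols2 = ["chrom2", "pos2", "strand2", "len2", "obs2"]
        a = frame.loc[swap, cols1].to_numpy()
        frame.loc[swap, cols1] = frame.loc[swap, cols2].to_numpy()
        frame.loc[swap, cols2] = a
        for c in ("pos1", "len1", "pos2", "len2"):
            frame[c] = frame[c].astype(np.int64)
        for c in ("obs1", "obs2"):
            frame[c] = frame[c].astype(bool)
    return frame


def read_contacts(path, read_length: int = 150) -> List[Contact]:
    """Read an extended pairs file as a list of :class:`Contact` records."""
    return frame_to_contacts(read_contacts_frame(path, read_length=read_length))


def contacts_to_frame(contacts: Sequence[Contact]) -> pd.DataFrame:
    rows = {c: [] for c in FRAME_COLUMNS}
    for c in contacts:
        for i, s in ((1, c.side1), (2, c.side2)):
            rows[f"chrom{i}"].append(s.chrom)
            rows[f"pos{i}"].append(s.pos5)
            rows[f"strand{i}"].append(s.strand)
            rows[f"len{i}"].append(0 if s.frag_len is None else s.frag_len)
            rows[f"obs{i}"].append(s.frag_len is not None)
    df = pd.DataFrame(rows)
    for c in ("pos1", "len1", "pos2", "len2"):
        df[c] = df[c].astype(np.int64)
    return df


def frame_to_contacts(frame: pd.DataFrame) -> List[Contact]:
    out = []
    for row in frame.itertuples(index=False):
        s1 = ContactSide(row.chrom1, int(row.pos1), row.strand1,
                         int(row.len1) if row.obs1 else None)
        s2 = ContactSide(row.chrom2, int(row.pos2), row.strand2,
                         int(row.len2) if row.obs2 else None)
        out.append(Contact(s1, s2))
    return out


def as_contact_frame(contacts: Union[pd.DataFrame, Sequence[Contact]]) -> pd.DataFrame:
    if isinstance(contacts, pd.DataFrame):
        return contacts
    return contacts_to_frame(contacts)


def write_contacts(contacts: Union[pd.DataFrame, Sequence[Contact]], path) -> None:
    """Write a contact frame / contact list in the extended pairs dialect."""
    frame = as_contact_frame(contacts)
    buf = io.StringIO()
    buf.write(PAIRS_HEADER + "\n")
    if len(frame):
        disk = pd.DataFrame({
            "chrom1": frame["chrom1"],
            "pos1": frame["pos1"] + 1,
            "strand1": frame["strand1"],
            "chrom2": frame["chrom2"],
            "pos2": frame["pos2"] + 1,
            "strand2": frame["strand2"],
            "frag_len1": np.where(frame["obs1"], frame["len1"], -1),
            "frag_len2": np.where(frame["obs2"], frame["len2"], -1),
        })
        disk.to_csv(buf, sep="\t", header=False, index=False)
    Path(path).write_text(buf.getvalue())
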