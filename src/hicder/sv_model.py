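"""Structural-variant records and breakend orientation semantics.

An SV record names one junction: two genomic positions, a declared type
(DEL / DUP / INV / TRA) and an orientation code saying which side (3' or 5')
of each breakpoint is fused.  ``sv_to_derivative`` converts one record into a
single-junction derivative chromosome.

Fusion algebra
--------------
"Side 3 at p" is the segment [0, p) read in + orientation (it *ends* at p);
"side 5 at p" is [p, L) read in + orientation (it *starts* at p).  The
junction fuses side s1 of pos1 with side s2 of pos2:

====== =============================================================
3to5   [c1:0-p1 +]  +  [c2:p2-L2 +]
5to3   canonicalized to [c2:0-p2 +]  +  [c1:p1-L1 +]
3to3   [c1:0-p1 +]  +  [c2:0-p2 -]       (head-to-head fusion)
5to5   [c1:p1-L1 -] +  [c2:p2-L2 +]      (tail-to-tail fusion)
====== =============================================================

For an intra-chromosomal record, 3to5 is a deletion of [p1, p2), 5to3 a
tandem duplication of [p1, p2), and 3to3 / 5to5 the two inversion junctions.
The 5to5 form is the whole-derivative reversal of [c2:p2-L2 -, c1:p1-L1 +];
it necessarily begins with a - fragment (no orientation of a 5'-5' fusion
starts on a + fragment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome_model import (
    BinTable,
    DerivativeGenome,
    Fragment,
    HicderError,
)

__all__ = [
    "SVRecord",
    "EditOp",
    "parse_sv_table",
    "serialize_sv_table",
    "parse_bedpe",
    "sv_to_derivative",
    "validate_sv",
]

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
ORIENTATIONS = ("3to5", "5to3", "3to3", "5to5")

#: Expected orientation(s) per intra-chromosomal SV type.
_TYPE_ORIENT = {"DEL": ("3to5",), "DUP": ("5to3",), "INV": ("3to3", "5to5")}

#: BEDPE strand-pair -> orientation code.
_STRANDS_TO_ORIENT = {
    ("+", "-"): "3to5",
    ("-", "+"): "5to3",
    ("+", "+"): "3to3",
    ("-", "-"): "5to5",
}


@dataclass(frozen=True)
class SVRecord:
    """One breakend junction.  Positions are 0-based internally (the text
    dialect is 1-based and converted at parse time)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    orientation: str

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise HicderError(f"unknown SV type {self.svtype!r}")
        if self.orientation not in ORIENTATIONS:
            raise HicderError(f"unknown orientation {self.orientation!r}")

    def normalized(self) -> "SVRecord":
        """Intra-chromosomal records are normalized so pos1 <= pos2."""
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            return SVRecord(
                self.chrom2,
                self.pos2,
                self.chrom1,
                self.pos1,
                self.svtype,
                self.orientation,
            )
        return self


@dataclass(frozen=True)
class EditOp:
    """One interactive edit on the *current* derivative bin axis.

    ``kind`` is delete / invert / duplicate / join.  For the single-map kinds
    ``target`` names the derivative and ``start``/``stop`` give a 0-based
    half-open bin interval on its current axis.  For join, (``target``,
    ``start``, ``side``) and (``target2``, ``start2``, ``side2``) give the two
    cut points: side "3" keeps the prefix before the cut, side "5" the suffix
    from the cut onward.
    """

    kind: str
    target: str
    start: int = 0
    stop: int = 0
    side: str = ""
    target2: str = ""
    start2: int = 0
    side2: str = ""

    def __post_init__(self):
        if self.kind not in ("delete", "invert", "duplicate", "join"):
            raise HicderError(f"unknown edit kind {self.kind!r}")


def parse_sv_table(text: str) -> list[SVRecord]:
    """Parse the whitespace-separated SV dialect.

    One record per line: ``chrom1 pos1 chrom2 pos2 TYPE ORIENT`` with 1-based
    positions (e.g. ``chr6 75343990 chr6 125216780 DEL 3to5``).  ``#`` lines
    and blank lines are skipped.  Intra-chromosomal records are normalized so
    pos1 <= pos2.
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 6:
            raise HicderError(
                f"line {lineno}: expected 6 columns, got {len(parts)}"
            )
        c1, p1s, c2, p2s, svtype, orient = parts
        try:
            p1, p2 = int(p1s), int(p2s)
        except ValueError:
            raise HicderError(f"line {lineno}: non-integer position") from None
        if p1 < 1 or p2 < 1:
            raise HicderError(f"line {lineno}: positions must be >= 1")
        if svtype not in SV_TYPES:
            raise HicderError(f"line {lineno}: unknown SV type {svtype!r}")
        if orient not in ORIENTATIONS:
            raise HicderError(f"line {lineno}: unknown orientation {orient!r}")
        records.append(
            SVRecord(c1, p1 - 1, c2, p2 - 1, svtype, orient).normalized()
        )
    return records


def serialize_sv_table(records: Iterable[SVRecord]) -> str:
    """Serialize records back to the 1-based text dialect (round-trips)."""
    lines = [
        f"{r.chrom1} {r.pos1 + 1} {r.chrom2} {r.pos2 + 1} {r.svtype} {r.orientation}"
        for r in records
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def parse_bedpe(text: str) -> list[SVRecord]:
    """Parse a 10-column BEDPE (0-based half-open) into SV records.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2.
    Strand pairs map (+,-)->3to5, (-,+)->5to3, (+,+)->3to3, (-,-)->5to5; the
    start coordinates are taken as breakpoints.  The ``name`` column is used
    as the SV type when it is one of DEL/DUP/INV/TRA, otherwise TRA for
    inter-chromosomal and the orientation-matched type for intra-chromosomal
    records.
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        parts = stripped.split()
        if len(parts) < 10:
            raise HicderError(
                f"line {lineno}: BEDPE needs >= 10 columns, got {len(parts)}"
            )
        c1, s1, _e1, c2, s2, _e2, name, _score, st1, st2 = parts[:10]
        try:
            p1, p2 = int(s1), int(s2)
        except ValueError:
            raise HicderError(f"line {lineno}: non-integer position") from None
        try:
            orient = _STRANDS_TO_ORIENT[(st1, st2)]
        except KeyError:
            raise HicderError(
                f"line {lineno}: invalid strand pair ({st1},{st2})"
            ) from None
        if name in SV_TYPES:
            svtype = name
        elif c1 != c2:
            svtype = "TRA"
        else:
            svtype = {"3to5": "DEL", "5to3": "DUP"}.get(orient, "INV")
        records.append(SVRecord(c1, p1, c2, p2, svtype, orient).normalized())
    return records


def serialize_bedpe(records: Iterable[SVRecord], binsize: int = 1) -> str:
    """Serialize records as 10-column BEDPE (breakpoint as a 1-bp interval)."""
    _ORIENT_TO_STRANDS = {v: k for k, v in _STRANDS_TO_ORIENT.items()}
    lines = []
    for r in records:
        st1, st2 = _ORIENT_TO_STRANDS[r.orientation]
        lines.append(
            f"{r.chrom1}\t{r.pos1}\t{r.pos1 + 1}\t{r.chrom2}\t{r.pos2}\t"
            f"{r.pos2 + 1}\t{r.svtype}\t.\t{st1}\t{st2}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def validate_sv(bt: BinTable, sv: SVRecord) -> list[str]:
    """Human-readable findings; empty when the record is clean."""
    findings = []
    for chrom, pos, which in (
        (sv.chrom1, sv.pos1, "pos1"),
        (sv.chrom2, sv.pos2, "pos2"),
    ):
        if chrom not in bt.chrom_names:
            findings.append(f"unknown chromosome {chrom!r}")
            continue
        length = bt.chrom_length(chrom)
        if not 0 <= pos < length:
            findings.append(
                f"{which}={pos + 1} out of range for {chrom} (length {length})"
            )
    if sv.chrom1 == sv.chrom2 and sv.svtype in _TYPE_ORIENT:
        expected = _TYPE_ORIENT[sv.svtype]
        if sv.orientation not in expected:
            findings.append(
                f"intra-chromosomal {sv.svtype} expects orientation "
                f"{' or '.join(expected)}, got {sv.orientation}"
            )
    return findings


def sv_to_derivative(
    bt: BinTable, sv: SVRecord, name: str = "", strict: bool = False
) -> DerivativeGenome:
    """Single-junction derivative chromosome per the fusion algebra.

    ``strict`` turns a type/orientation inconsistency (e.g. an
    intra-chromosomal DEL declared 5to3) from a tolerated annotation into an
    error; positions out of range are always errors.
    """
    sv = sv.normalized()
    findings = validate_sv(bt, sv)
    hard = [f for f in findings if "out of range" in f or "unknown chromosome" in f]
    if hard:
        raise HicderError("; ".join(hard))
    if strict and findings:
        raise HicderError("; ".join(findings))

    c1, p1, c2, p2 = sv.chrom1, sv.pos1, sv.chrom2, sv.pos2
    L1, L2 = bt.chrom_length(c1), bt.chrom_length(c2)
    o = sv.orientation
    if o == "3to5":
        spans = ((c1, 0, p1, "+"), (c2, p2, L2, "+"))
    elif o == "5to3":
        spans = ((c2, 0, p2, "+"), (c1, p1, L1, "+"))
    elif o == "3to3":
        spans = ((c1, 0, p1, "+"), (c2, 0, p2, "-"))
    else:  # 5to5: reversal of [c2:p2-L2 -, c1:p1-L1 +]
        spans = ((c1, p1, L1, "-"), (c2, p2, L2, "+"))
    # a side-3 segment at position 0 is empty and dropped
    frags = tuple(Fragment(*s) for s in spans if s[1] < s[2])
    if not frags:
        raise HicderError("junction produces an empty derivative")
    if not name:
        name = f"der_{c1}_{p1 + 1}_{c2}_{p2 + 1}_{sv.svtype}_{o}"
    return DerivativeGenome(name, frags)
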