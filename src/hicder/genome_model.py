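"""Reference and derivative coordinate systems.

A fixed-resolution binning of a reference genome (:class:`BinTable`) is the
coordinate frame everything else works in.  A rearranged ("derivative")
chromosome is an ordered list of oriented reference intervals
(:class:`Fragment` / :class:`DerivativeGenome`), and every rearrangement in the
package ultimately reduces to a :class:`BinMap`: an ordered list of
(source bin, orientation, fragment index) entries that defines one axis of a
rearranged contact matrix.

Internal coordinates are 0-based half-open throughout; text formats that use
1-based positions are converted at parse time by their parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinTable",
    "Fragment",
    "DerivativeGenome",
    "BinMap",
    "make_bintable",
    "pos_to_bin",
    "fragment_to_bins",
    "derivative_to_binmap",
    "read_chrom_sizes",
]

#: Default bin size (bp) for cancer-sample workflows (cis + trans contacts).
CANCER_BINSIZE = 40_000
#: Default bin size (bp) for normal-sample workflows (cis-only contacts).
NORMAL_BINSIZE = 5_000
#: Maximum cis distance (bp) retained in the normal-sample preset.
NORMAL_MAX_DIST = 2_000_000


class HicderError(ValueError):
    """Base class for data errors raised by this package."""


@dataclass(frozen=True)
class BinTable:
    """Fixed-resolution partition of a genome into bins.

    Bin ids are global: contiguous integers ordered by chromosome (in input
    order, never sorted) then by position.  The last bin of a chromosome may
    be partial (``ceil(length / binsize)`` bins per chromosome).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    binsize: int
    # derived, filled in __post_init__
    _offsets: np.ndarray = field(repr=False, compare=False, default=None)
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        nbins = [-(-l // self.binsize) for l in self.chrom_lengths]
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.chrom_names)}
        )

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def chrom_id(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise HicderError(f"unknown chromosome: {chrom!r}") from None

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self.chrom_id(chrom)])

    def chrom_nbins(self, chrom: str) -> int:
        c = self.chrom_id(chrom)
        return int(self._offsets[c + 1] - self._offsets[c])

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_id(chrom)]

    def bin_chrom_ids(self) -> np.ndarray:
        """Chromosome id of every global bin (length ``n_bins``)."""
        return np.repeat(
            np.arange(len(self.chrom_names)), np.diff(self._offsets)
        )

    def bin_start(self, bin_id: int) -> tuple[str, int]:
        """(chromosome name, bin start bp) for a global bin id."""
        if not 0 <= bin_id < self.n_bins:
            raise HicderError(f"bin id out of range: {bin_id}")
        c = int(np.searchsorted(self._offsets, bin_id, side="right") - 1)
        local = bin_id - int(self._offsets[c])
        return self.chrom_names[c], local * self.binsize


@dataclass(frozen=True)
class Fragment:
    """Oriented reference interval, 0-based half-open, strand ``+``/``-``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise HicderError(
                f"invalid fragment interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise HicderError(f"invalid strand {self.strand!r}")

    def reversed(self) -> "Fragment":
        return Fragment(
            self.chrom, self.start, self.end, "-" if self.strand == "+" else "+"
        )


@dataclass(frozen=True)
class DerivativeGenome:
    """A derivative chromosome: ordered oriented reference fragments.

    Fragments may repeat (duplication), overlap, and span multiple reference
    chromosomes.  Regions of the reference that appear in no fragment are
    implicitly deleted.
    """

    name: str
    fragments: tuple[Fragment, ...]

    def __post_init__(self):
        if len(self.fragments) == 0:
            raise HicderError(f"derivative {self.name!r} has no fragments")
        object.__setattr__(self, "fragments", tuple(self.fragments))

    def reversed(self) -> "DerivativeGenome":
        """Whole-derivative reversal: reverse fragment order, flip strands."""
        return DerivativeGenome(
            self.name, tuple(f.reversed() for f in reversed(self.fragments))
        )


@dataclass(frozen=True)
class BinMap:
    """One axis of a rearranged matrix.

    Parallel arrays over axis positions: ``source_bins`` (global bin ids in
    the governing BinTable), ``orientations`` (+1 / -1) and ``fragment_ids``
    (entries of one fragment form a contiguous run; + runs have strictly
    increasing source bins, - runs strictly decreasing).
    """

    source_bins: np.ndarray
    orientations: np.ndarray
    fragment_ids: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "source_bins", np.asarray(self.source_bins, dtype=np.int64)
        )
        object.__setattr__(
            self, "orientations", np.asarray(self.orientations, dtype=np.int8)
        )
        object.__setattr__(
            self, "fragment_ids", np.asarray(self.fragment_ids, dtype=np.int64)
        )
        n = len(self.source_bins)
        if len(self.orientations) != n or len(self.fragment_ids) != n:
            raise HicderError("BinMap arrays must have equal length")

    def __len__(self) -> int:
        return len(self.source_bins)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinMap):
            return NotImplemented
        return (
            np.array_equal(self.source_bins, other.source_bins)
            and np.array_equal(self.orientations, other.orientations)
            and np.array_equal(self.fragment_ids, other.fragment_ids)
        )

    def entries(self) -> list[tuple[int, int, int]]:
        return list(
            zip(
                self.source_bins.tolist(),
                self.orientations.tolist(),
                self.fragment_ids.tolist(),
            )
        )


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    """Read a UCSC-style two-column chrom.sizes file (name, length)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise HicderError(f"{path}:{lineno}: expected 'name length'")
            out.append((parts[0], int(parts[1])))
    return out


def make_bintable(
    chrom_sizes: Iterable[tuple[str, int]], binsize: int
) -> BinTable:
    """Build a BinTable from (name, length) pairs at a fixed resolution.

    Chromosome order follows the input order; bin ids are contiguous per
    chromosome with the last bin partial when ``length % binsize != 0``.
    """
    chrom_sizes = list(chrom_sizes)
    if binsize < 1:
        raise HicderError(f"binsize must be >= 1, got {binsize}")
    names = [c for c, _ in chrom_sizes]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise HicderError(f"duplicate chromosome name(s): {dup}")
    for name, length in chrom_sizes:
        if length < 1:
            raise HicderError(f"non-positive length for {name}: {length}")
    return BinTable(
        tuple(names), tuple(l for _, l in chrom_sizes), int(binsize)
    )


def pos_to_bin(bt: BinTable, chrom: str, pos: int) -> int:
    """Global bin id containing 0-based position ``pos`` (floor division)."""
    length = bt.chrom_length(chrom)
    if not 0 <= pos < length:
        raise HicderError(
            f"position {pos} out of range for {chrom} (length {length})"
        )
    return bt.chrom_offset(chrom) + pos // bt.binsize


def fragment_to_bins(bt: BinTable, f: Fragment) -> np.ndarray:
    """Ordered global bin ids overlapped by a fragment.

    Every bin overlapping ``[start, end)`` is included, so partially covered
    junction bins are kept.  ``+`` strand yields ascending order, ``-``
    descending.
    """
    length = bt.chrom_length(f.chrom)
    if f.end > length:
        raise HicderError(
            f"fragment {f.chrom}:{f.start}-{f.end} exceeds chromosome length {length}"
        )
    off = bt.chrom_offset(f.chrom)
    first = f.start // bt.binsize
    last = (f.end - 1) // bt.binsize  # end is exclusive
    bins = np.arange(off + first, off + last + 1, dtype=np.int64)
    return bins[::-1] if f.strand == "-" else bins


def derivative_to_binmap(bt: BinTable, d: DerivativeGenome) -> BinMap:
    """Reduce a derivative genome to a BinMap over the reference bins."""
    src, ori, fid = [], [], []
    for i, f in enumerate(d.fragments):
        bins = fragment_to_bins(bt, f)
        src.append(bins)
        ori.append(np.full(len(bins), 1 if f.strand == "+" else -1, dtype=np.int8))
        fid.append(np.full(len(bins), i, dtype=np.int64))
    return BinMap(np.concatenate(src), np.concatenate(ori), np.concatenate(fid))


def identity_binmap(bt: BinTable, chrom: str) -> BinMap:
    """BinMap listing one chromosome's bins in reference order."""
    off = bt.chrom_offset(chrom)
    n = bt.chrom_nbins(chrom)
    return BinMap(
        np.arange(off, off + n, dtype=np.int64),
        np.ones(n, dtype=np.int8),
        np.zeros(n, dtype=np.int64),
    )
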