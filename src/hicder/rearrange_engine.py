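"""Turn derivatives, sequential edits, or order strings into bin maps, and
materialize rearranged contact matrices.

Everything here reduces to the :class:`~hicder.genome_model.BinMap`: deletion
removes entries, inversion reverses a slice and flips orientations,
duplication inserts a tandem copy, and a join fuses two derivatives at cut
points using the same side algebra as breakend orientations.  Materializing a
bin map fills ``M'[a, b] = M[src(a), src(b)]``, scaling entries whose source
bins lie on different chromosomes by the trans-enhancement weight ``w``.

Junction continuity is quantified by :func:`junction_smoothness`: the mean
observed/expected fold change over the k x k window of pairs spanning a
junction, where the expectation is taken at the *derivative-axis* distance —
a genuinely fused junction restores the normal distance decay across the
breakpoint (score near 1), whereas a spurious one does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_store import ContactMatrix, ExpectedProfile
from .genome_model import (
    BinMap,
    BinTable,
    DerivativeGenome,
    Fragment,
    HicderError,
)
from .sv_model import EditOp

__all__ = [
    "RearrangedMatrix",
    "SmoothnessReport",
    "EditSession",
    "apply_edit",
    "apply_edit_sequence",
    "join_binmaps",
    "parse_order_spec",
    "serialize_order_spec",
    "parse_edit_script",
    "serialize_edit_script",
    "materialize",
    "expected_from_rearranged",
    "junction_smoothness",
]


def renumber_fragments(binmap: BinMap) -> BinMap:
    """Canonical fragment ids: a new run starts wherever the source-bin walk
    breaks (+ runs step +1, - runs step -1) or orientation changes."""
    src, ori = binmap.source_bins, binmap.orientations
    n = len(src)
    if n == 0:
        return BinMap(src, ori, np.zeros(0, dtype=np.int64))
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        step = np.diff(src)
        breaks[1:] = (ori[1:] != ori[:-1]) | (step != ori[1:])
    return BinMap(src, ori, np.cumsum(breaks) - 1)


def _slice(bm: BinMap, start: int, stop: int) -> tuple:
    return (
        bm.source_bins[start:stop],
        bm.orientations[start:stop],
        bm.fragment_ids[start:stop],
    )


def _reverse_piece(src, ori, fid):
    return src[::-1], -ori[::-1], fid[::-1]


def apply_edit(binmap: BinMap, edit: EditOp) -> BinMap:
    """Apply one delete / invert / duplicate edit on the current bin axis.

    Intervals are 0-based half-open positions on the derivative axis (what
    the user currently sees), not reference coordinates.  Fragment ids are
    renumbered canonically afterwards.
    """
    if edit.kind == "join":
        raise HicderError("join edits need two bin maps; use join_binmaps")
    n = len(binmap)
    if not (0 <= edit.start < edit.stop <= n):
        raise HicderError(
            f"edit interval [{edit.start}, {edit.stop}) out of range for axis "
            f"of length {n}"
        )
    a, b = edit.start, edit.stop
    src, ori, fid = binmap.source_bins, binmap.orientations, binmap.fragment_ids
    mid = _slice(binmap, a, b)
    if edit.kind == "delete":
        pieces = [_slice(binmap, 0, a), _slice(binmap, b, n)]
    elif edit.kind == "invert":
        pieces = [_slice(binmap, 0, a), _reverse_piece(*mid), _slice(binmap, b, n)]
    elif edit.kind == "duplicate":
        pieces = [_slice(binmap, 0, a), mid, mid, _slice(binmap, b, n)]
    else:  # pragma: no cover - guarded in EditOp
        raise HicderError(f"unknown edit kind {edit.kind!r}")
    out = BinMap(
        np.concatenate([p[0] for p in pieces]),
        np.concatenate([p[1] for p in pieces]),
        np.concatenate([p[2] for p in pieces]),
    )
    if len(out) == 0:
        raise HicderError("edit would delete the entire derivative")
    return renumber_fragments(out)


def join_binmaps(
    bm1: BinMap, cut1: int, side1: str, bm2: BinMap, cut2: int, side2: str
) -> BinMap:
    """Fuse two derivatives at cut points with breakend side semantics.

    A cut index c splits an axis into prefix [0, c) and suffix [c, n); side
    "3" keeps the prefix (the part *ending* at the cut), side "5" the suffix
    (the part *starting* at it).  The kept pieces fuse with the same algebra
    as SV orientations: 3+5 concatenates directly, 3+3 reverses the second
    piece, 5+5 reverses the first, 5+3 concatenates in swapped order.
    """
    for cut, bm, label in ((cut1, bm1, "first"), (cut2, bm2, "second")):
        if not 0 <= cut <= len(bm):
            raise HicderError(f"join cut {cut} outside {label} derivative")
    if side1 not in ("3", "5") or side2 not in ("3", "5"):
        raise HicderError("join sides must be '3' or '5'")
    p1 = _slice(bm1, 0, cut1) if side1 == "3" else _slice(bm1, cut1, len(bm1))
    p2 = _slice(bm2, 0, cut2) if side2 == "3" else _slice(bm2, cut2, len(bm2))
    key = side1 + side2
    if key == "35":
        pieces = [p1, p2]
    elif key == "53":
        pieces = [p2, p1]
    elif key == "33":
        pieces = [p1, _reverse_piece(*p2)]
    else:  # 55
        pieces = [_reverse_piece(*p1), p2]
    out = BinMap(
        np.concatenate([p[0] for p in pieces]),
        np.concatenate([p[1] for p in pieces]),
        np.concatenate([p[2] for p in pieces]),
    )
    if len(out) == 0:
        raise HicderError("join produces an empty derivative")
    return renumber_fragments(out)


class EditSession:
    """Sequential edits over named derivatives with an undo stack.

    ``state`` maps derivative name -> BinMap.  Each applied edit pushes a
    snapshot, so ``undo`` reverts the most recent edit (stack discipline: k
    edits followed by k undos restore the original state exactly).
    """

    def __init__(self, state: dict[str, BinMap]):
        self.state = dict(state)
        self._undo: list[dict[str, BinMap]] = []

    def apply(self, edit: EditOp) -> None:
        if edit.target not in self.state:
            raise HicderError(f"unknown derivative {edit.target!r}")
        snapshot = dict(self.state)
        if edit.kind == "join":
            if edit.target2 not in self.state:
                raise HicderError(f"unknown derivative {edit.target2!r}")
            if edit.target2 == edit.target:
                raise HicderError("cannot join a derivative to itself")
            joined = join_binmaps(
                self.state[edit.target],
                edit.start,
                edit.side,
                self.state[edit.target2],
                edit.start2,
                edit.side2,
            )
            self.state[edit.target] = joined
            del self.state[edit.target2]
        else:
            self.state[edit.target] = apply_edit(self.state[edit.target], edit)
        self._undo.append(snapshot)

    def undo(self) -> None:
        if not self._undo:
            raise HicderError("nothing to undo")
        self.state = self._undo.pop()

    @property
    def n_applied(self) -> int:
        return len(self._undo)


def apply_edit_sequence(
    state: dict[str, BinMap], edits: list[EditOp]
) -> EditSession:
    """Left-fold of ``apply_edit`` over named derivatives.

    Returns the session (holding the final state and the undo log).  The
    first invalid edit aborts with its index in the error message.
    """
    session = EditSession(state)
    for k, edit in enumerate(edits):
        try:
            session.apply(edit)
        except HicderError as e:
            raise HicderError(f"edit {k}: {e}") from None
    return session


# ---------------------------------------------------------------------------
# Text formats: order spec and edit scripts
# ---------------------------------------------------------------------------

_MINUS = {"-", "−"}  # ASCII hyphen and unicode minus both accepted


def parse_order_spec(text: str, bt: BinTable) -> list[DerivativeGenome]:
    """Parse the fragment-order grammar into derivative genomes.

    One derivative per line: ``name<TAB>frag(;frag)*`` with
    ``frag := chrom ":" start "-" end ("+"|"-")?`` in 1-based inclusive
    coordinates (default strand +).  Reference regions that appear in no
    fragment are implicitly deleted — omission needs no explicit action.
    """
    derivatives = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "\t" in stripped:
            name, _, spec = stripped.partition("\t")
        else:
            name, _, spec = stripped.partition(" ")
        name, spec = name.strip(), spec.strip()
        if not name or not spec:
            raise HicderError(f"line {lineno}: expected 'name<TAB>fragments'")
        frags = []
        for col, token in enumerate(spec.split(";"), 1):
            token = token.strip()
            if not token:
                raise HicderError(f"line {lineno}, fragment {col}: empty fragment")
            strand = "+"
            if token[-1] in _MINUS or token[-1] == "+":
                strand = "-" if token[-1] in _MINUS else "+"
                token = token[:-1]
            chrom, colon, rng = token.partition(":")
            parts = rng.split("-") if colon else []
            if len(parts) != 2:
                raise HicderError(
                    f"line {lineno}, fragment {col}: expected chrom:start-end"
                )
            try:
                start1, end1 = int(parts[0]), int(parts[1])
            except ValueError:
                raise HicderError(
                    f"line {lineno}, fragment {col}: non-integer coordinate"
                ) from None
            if chrom not in bt.chrom_names:
                raise HicderError(
                    f"line {lineno}, fragment {col}: unknown chromosome {chrom!r}"
                )
            if start1 < 1 or start1 > end1:
                raise HicderError(
                    f"line {lineno}, fragment {col}: invalid range "
                    f"{start1}-{end1} (1-based inclusive, start <= end)"
                )
            if end1 > bt.chrom_length(chrom):
                raise HicderError(
                    f"line {lineno}, fragment {col}: end {end1} beyond "
                    f"{chrom} length {bt.chrom_length(chrom)}"
                )
            frags.append(Fragment(chrom, start1 - 1, end1, strand))
        derivatives.append(DerivativeGenome(name, tuple(frags)))
    if not derivatives:
        raise HicderError("order spec contains no derivatives")
    return derivatives


def serialize_order_spec(derivatives: list[DerivativeGenome]) -> str:
    lines = []
    for d in derivatives:
        frags = ";".join(
            f"{f.chrom}:{f.start + 1}-{f.end}{f.strand}" for f in d.fragments
        )
        lines.append(f"{d.name}\t{frags}")
    return "\n".join(lines) + "\n"


_EDIT_KINDS = {"DEL": "delete", "INV": "invert", "DUP": "duplicate"}


def parse_edit_script(text: str) -> list[EditOp]:
    """Parse an edit script: one edit per line.

    ``DEL der1:12-40`` / ``INV der1:5-9`` / ``DUP der1:20-24`` address
    1-based inclusive bin intervals on the named derivative's current axis;
    ``JOIN der1:15/3 der2:0/5`` gives (cut index, side code) pairs, where the
    cut index is a 0-based boundary position on the axis.
    """
    edits = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        op = parts[0].upper()
        if op in _EDIT_KINDS:
            if len(parts) != 2:
                raise HicderError(f"line {lineno}: expected '{op} name:a-b'")
            target, colon, rng = parts[1].partition(":")
            ab = rng.split("-")
            if not colon or len(ab) != 2:
                raise HicderError(f"line {lineno}: expected '{op} name:a-b'")
            try:
                a, b = int(ab[0]), int(ab[1])
            except ValueError:
                raise HicderError(f"line {lineno}: non-integer interval") from None
            if a < 1 or a > b:
                raise HicderError(
                    f"line {lineno}: invalid interval {a}-{b} "
                    "(1-based inclusive, a <= b)"
                )
            edits.append(EditOp(_EDIT_KINDS[op], target, a - 1, b))
        elif op == "JOIN":
            if len(parts) != 3:
                raise HicderError(
                    f"line {lineno}: expected 'JOIN name:cut/side name:cut/side'"
                )
            specs = []
            for tok in parts[1:]:
                target, colon, cs = tok.partition(":")
                cut_side = cs.split("/")
                if not colon or len(cut_side) != 2:
                    raise HicderError(
                        f"line {lineno}: expected 'name:cut/side', got {tok!r}"
                    )
                try:
                    cut = int(cut_side[0])
                except ValueError:
                    raise HicderError(f"line {lineno}: non-integer cut") from None
                if cut_side[1] not in ("3", "5"):
                    raise HicderError(f"line {lineno}: side must be 3 or 5")
                specs.append((target, cut, cut_side[1]))
            (t1, c1, s1), (t2, c2, s2) = specs
            edits.append(
                EditOp("join", t1, c1, 0, s1, t2, c2, s2)
            )
        else:
            raise HicderError(f"line {lineno}: unknown edit {parts[0]!r}")
    return edits


def serialize_edit_script(edits: list[EditOp]) -> str:
    _REV = {v: k for k, v in _EDIT_KINDS.items()}
    lines = []
    for e in edits:
        if e.kind == "join":
            lines.append(
                f"JOIN {e.target}:{e.start}/{e.side} {e.target2}:{e.start2}/{e.side2}"
            )
        else:
            lines.append(f"{_REV[e.kind]} {e.target}:{e.start + 1}-{e.stop}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------

@dataclass
class RearrangedMatrix:
    """Dense symmetric matrix over one or more concatenated derivative axes.

    ``boundaries`` holds the cumulative axis length after each derivative
    (the last equals the axis length); ``junctions`` lists interior axis cut
    positions where the fragment or derivative changes.  Provenance arrays
    give, per axis position, the source chromosome, source bin start (bp),
    orientation (+1/-1) and fragment index.
    """

    values: np.ndarray
    binmaps: list[BinMap]
    names: list[str]
    boundaries: list[int]
    weight: float
    bintable: BinTable
    source_chroms: np.ndarray = field(repr=False, default=None)
    source_starts: np.ndarray = field(repr=False, default=None)
    orientations: np.ndarray = field(repr=False, default=None)
    fragment_ids: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def junctions(self) -> list[int]:
        cuts = []
        offset = 0
        for bm in self.binmaps:
            fid = bm.fragment_ids
            interior = np.where(fid[1:] != fid[:-1])[0] + 1
            cuts.extend((offset + interior).tolist())
            offset += len(bm)
            if offset < self.boundaries[-1]:
                cuts.append(offset)
        return cuts


def materialize(
    cm: ContactMatrix,
    binmaps,
    w: float = 1.0,
    use_values: bool = False,
) -> RearrangedMatrix:
    """Fill the rearranged matrix ``M'[a,b] = M[src(a), src(b)]``.

    Entries whose two source bins lie on different chromosomes are scaled by
    the trans-enhancement weight ``w`` (w = 1 reproduces source values
    exactly).  Duplicated source bins replicate their rows/columns, including
    the duplicate-vs-duplicate block, which equals the source self-block.
    """
    if w < 0:
        raise HicderError(f"weight must be >= 0, got {w}")
    if isinstance(binmaps, BinMap):
        named = [("der1", binmaps)]
    elif isinstance(binmaps, dict):
        named = list(binmaps.items())
    else:
        named = [
            bm if isinstance(bm, tuple) else (f"der{k + 1}", bm)
            for k, bm in enumerate(binmaps)
        ]
    bt = cm.bintable
    src = np.concatenate([bm.source_bins for bm in (b for _, b in named)])
    if len(src) and (src.min() < 0 or src.max() >= bt.n_bins):
        raise HicderError("bin map references bins outside the matrix")
    sym = cm.symmetric(use_values)
    dense = np.asarray(sym[src][:, src].todense(), dtype=float)
    chrom_of = bt.bin_chrom_ids()[src]
    if w != 1.0:
        trans = chrom_of[:, None] != chrom_of[None, :]
        dense[trans] *= w
    boundaries = np.cumsum([len(bm) for _, bm in named]).tolist()
    starts = np.array([bt.bin_start(int(b))[1] for b in src], dtype=np.int64)
    chrom_names = np.array(
        [bt.chrom_names[c] for c in chrom_of], dtype=object
    )
    return RearrangedMatrix(
        values=dense,
        binmaps=[bm for _, bm in named],
        names=[n for n, _ in named],
        boundaries=boundaries,
        weight=w,
        bintable=bt,
        source_chroms=chrom_names,
        source_starts=starts,
        orientations=np.concatenate(
            [bm.orientations for _, bm in named]
        ),
        fragment_ids=np.concatenate(
            [bm.fragment_ids for _, bm in named]
        ),
    )


def expected_from_rearranged(
    rm: "RearrangedMatrix", smooth_window: int = 1
) -> ExpectedProfile:
    """Pooled distance-decay expectation estimated on the derivative axis.

    Each derivative block is treated as one chromosome: the expectation at
    distance d is the mean of the d-th diagonal over all blocks (structural
    zeros included), and inter-derivative entries feed the trans mean.  This
    is the right background for junction scoring — on a correctly rearranged
    axis the decay is uncontaminated by the deletion gaps and breakpoint
    bowties that distort a reference-coordinate profile of the same sample.
    """
    from .contact_store import EPSILON, _smooth_log

    lengths = [len(bm) for bm in rm.binmaps]
    max_d = max(lengths) - 1
    sums = np.zeros(max_d + 1)
    npairs = np.zeros(max_d + 1)
    off = 0
    for n in lengths:
        block = rm.values[off : off + n, off : off + n]
        for d in range(n):
            sums[d] += np.diagonal(block, d).sum()
            npairs[d] += n - d
        off += n
    pooled = np.divide(sums, npairs, out=np.zeros_like(sums), where=npairs > 0)
    total = rm.n
    n_cis = sum(n * (n + 1) // 2 for n in lengths)
    n_trans = total * (total + 1) // 2 - n_cis
    if n_trans:
        iu, ju = np.triu_indices(total)
        der_of = np.repeat(np.arange(len(lengths)), lengths)
        trans_sum = rm.values[iu, ju][der_of[iu] != der_of[ju]].sum()
        trans_mean = float(trans_sum) / n_trans
    else:
        trans_mean = 0.0
    return ExpectedProfile(
        pooled=_smooth_log(pooled, smooth_window, EPSILON),
        per_chrom={},
        scope="pooled",
        smooth_window=smooth_window,
        trans_mean=max(trans_mean, EPSILON),
    )


# ---------------------------------------------------------------------------
# Junction smoothness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothnessReport:
    """Continuity score for one junction.

    ``score`` is the mean observed/expected fold change over cross-junction
    pairs at derivative-axis distance; near 1 means the junction restores the
    normal distance decay (de novo contacts consistent with physical
    adjacency), near 0 means the two sides do not interact like neighbours.
    """

    junction: int
    k: int
    score: float
    n_pairs: int
    n_excluded: int


def junction_smoothness(
    rm: RearrangedMatrix,
    profile: ExpectedProfile,
    junction: int,
    k: int,
) -> SmoothnessReport:
    """Score continuity across an axis cut using k bins per side.

    Pairs (a, b) with a in the k bins left of the cut and b in the k bins to
    the right contribute ``M'[a,b] / expected(b - a)``; the expectation is
    the pooled distance-decay curve evaluated at the derivative-axis
    distance.  Pairs whose expected value is at the floor (effectively zero)
    are excluded and counted.  Windows truncate at axis ends, but at least
    one bin is required on each side.
    """
    if k < 1:
        raise HicderError(f"window k must be >= 1, got {k}")
    n = rm.n
    if not 0 < junction < n:
        raise HicderError(
            f"junction {junction} at or beyond axis end (axis length {n})"
        )
    left = np.arange(max(0, junction - k), junction)
    right = np.arange(junction, min(n, junction + k))
    ratios = []
    n_excluded = 0
    max_d = profile.max_distance()
    for a in left:
        for b in right:
            d = int(b - a)
            if d > max_d:
                raise HicderError(f"no expected value at distance {d}")
            e = profile.expected(d)
            if e <= 2 * profile.eps:
                n_excluded += 1
                continue
            ratios.append(rm.values[a, b] / e)
    score = float(np.mean(ratios)) if ratios else 0.0
    return SmoothnessReport(
        junction=int(junction),
        k=int(k),
        score=score,
        n_pairs=len(ratios),
        n_excluded=n_excluded,
    )
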