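"""Sparse symmetric contact matrices: I/O and normalization.

Counts are stored upper-triangular (i <= j); querying (j, i) returns the
(i, j) value.  Two normalizations are provided:

* **coverage normalization** — a marginal-product scaling
  ``value(i,j) = counts(i,j) / (m_i * m_j) * S`` with ``m`` the per-bin
  marginals and ``S`` a global factor preserving total mass.  This is a
  deliberately simple stand-in for regression-based coverage correction; an
  alternative normalizer can be plugged in via the ``normalizer`` hook.
* **distance normalization** — observed/expected fold change, dividing each
  cis count by the mean contact value at its bin distance (structural zeros
  included in the mean) and each trans count by the pooled trans mean.

Supported on-disk forms: sparse text triples (``chrom1 start1 chrom2 start2
count``, 0-based bin starts), a single-resolution cooler-layout HDF5 store,
and a BED-pair style 7-column interaction table for normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from .genome_model import BinTable, HicderError, make_bintable

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_contacts",
    "write_triples",
    "read_cooler",
    "write_cooler",
    "write_interaction_table",
    "coverage_profile",
    "coverage_normalize",
    "expected_by_distance",
    "distance_normalize",
]

#: Floor applied to expected values and trans means to avoid division by zero.
EPSILON = 1e-8


class ContactMatrix:
    """Symmetric sparse contact matrix over a :class:`BinTable`.

    ``counts`` is kept upper-triangular; duplicate and mirrored entries are
    summed on construction.  ``values`` optionally carries normalized values
    on the same sparsity pattern, and ``expected`` an attached
    :class:`ExpectedProfile`.
    """

    def __init__(self, bintable: BinTable, counts, values=None):
        n = bintable.n_bins
        coo = sp.coo_matrix(counts, shape=(n, n))
        if coo.shape != (n, n):
            raise HicderError(
                f"matrix shape {coo.shape} does not match bin table ({n} bins)"
            )
        if len(coo.data) and coo.data.min() < 0:
            raise HicderError("negative contact count")
        # fold onto the upper triangle, summing duplicates
        i = np.minimum(coo.row, coo.col)
        j = np.maximum(coo.row, coo.col)
        upper = sp.coo_matrix((coo.data, (i, j)), shape=(n, n))
        upper.sum_duplicates()
        self.bintable = bintable
        self.counts = upper.tocsr()
        self.counts.eliminate_zeros()
        self.values = None if values is None else sp.csr_matrix(values)
        self.expected: "ExpectedProfile | None" = None

    @property
    def n_bins(self) -> int:
        return self.bintable.n_bins

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.counts[i, j]

    def symmetric(self, use_values: bool = False) -> sp.csr_matrix:
        """Full symmetric CSR (upper + mirrored lower, diagonal once)."""
        m = self.values if use_values else self.counts
        if m is None:
            raise HicderError("matrix has no normalized values")
        n = m.shape[0]
        idx = np.arange(n)
        d = sp.csr_matrix((m.diagonal(), (idx, idx)), shape=m.shape)
        return (m + m.T - d).tocsr()

    def dense(self, use_values: bool = False) -> np.ndarray:
        return self.symmetric(use_values).toarray()

    def total(self) -> float:
        """Total mass with the diagonal counted once."""
        return float(self.counts.sum())

    def copy_with_values(self, values: sp.spmatrix) -> "ContactMatrix":
        out = ContactMatrix(self.bintable, self.counts)
        out.values = sp.csr_matrix(values)
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_contacts(path, format: str, bintable: BinTable | None = None) -> ContactMatrix:
    """Read a contact matrix from ``cooler`` or ``triples`` format.

    Triples need an explicit ``bintable`` (the text carries no chromosome
    sizes); cooler files are self-describing.
    """
    if format == "cooler":
        return read_cooler(path)
    if format == "triples":
        if bintable is None:
            raise HicderError("triples format requires a BinTable")
        return _read_triples(path, bintable)
    raise HicderError(f"unknown contact format {format!r}")


def _read_triples(path, bt: BinTable) -> ContactMatrix:
    rows, cols, data = [], [], []
    r = bt.binsize
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise HicderError(
                    f"{path}:{lineno}: expected 5 columns, got {len(parts)}"
                )
            c1, s1, c2, s2, cnt = parts
            try:
                s1, s2 = int(s1), int(s2)
                count = float(cnt)
            except ValueError:
                raise HicderError(f"{path}:{lineno}: non-numeric field") from None
            if count < 0:
                raise HicderError(f"{path}:{lineno}: negative count")
            for c, s in ((c1, s1), (c2, s2)):
                if c not in bt.chrom_names:
                    raise HicderError(f"{path}:{lineno}: unknown chromosome {c!r}")
                if s % r != 0:
                    raise HicderError(
                        f"{path}:{lineno}: start {s} not a multiple of binsize {r}"
                    )
            rows.append(bt.chrom_offset(c1) + s1 // r)
            cols.append(bt.chrom_offset(c2) + s2 // r)
            data.append(count)
    n = bt.n_bins
    if rows and (max(rows) >= n or max(cols) >= n):
        raise HicderError(f"{path}: bin start beyond chromosome end")
    return ContactMatrix(bt, sp.coo_matrix((data, (rows, cols)), shape=(n, n)))


def write_triples(cm: ContactMatrix, path, use_values: bool = False) -> None:
    """Write the upper triangle as sparse text triples (0-based bin starts)."""
    m = (cm.values if use_values else cm.counts).tocoo()
    bt = cm.bintable
    with open(path, "w") as fh:
        for i, j, v in zip(m.row, m.col, m.data):
            c1, s1 = bt.bin_start(int(i))
            c2, s2 = bt.bin_start(int(j))
            val = int(v) if float(v).is_integer() else repr(float(v))
            fh.write(f"{c1}\t{s1}\t{c2}\t{s2}\t{val}\n")


def write_cooler(cm: ContactMatrix, path) -> None:
    """Write a single-resolution cooler-layout HDF5 file (schema v3)."""
    bt = cm.bintable
    m = cm.counts.tocoo()
    order = np.lexsort((m.col, m.row))
    bin1, bin2, data = m.row[order], m.col[order], m.data[order]
    chrom_ids = bt.bin_chrom_ids()
    starts = np.concatenate(
        [np.arange(bt.chrom_nbins(c)) * bt.binsize for c in bt.chrom_names]
    ).astype(np.int64)
    ends = np.minimum(
        starts + bt.binsize,
        np.asarray(bt.chrom_lengths, dtype=np.int64)[chrom_ids],
    )
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = bt.binsize
        f.attrs["nbins"] = bt.n_bins
        f.attrs["nchroms"] = len(bt.chrom_names)
        f.attrs["nnz"] = len(data)
        g = f.create_group("chroms")
        g.create_dataset(
            "name", data=np.array(bt.chrom_names, dtype=h5py.string_dtype())
        )
        g.create_dataset("length", data=np.asarray(bt.chrom_lengths, dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=chrom_ids.astype(np.int32))
        g.create_dataset("start", data=starts)
        g.create_dataset("end", data=ends)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=bin1.astype(np.int64))
        g.create_dataset("bin2_id", data=bin2.astype(np.int64))
        g.create_dataset("count", data=data)
        g = f.create_group("indexes")
        g.create_dataset(
            "chrom_offset", data=np.asarray(bt._offsets, dtype=np.int64)
        )
        g.create_dataset(
            "bin1_offset",
            data=np.searchsorted(bin1, np.arange(bt.n_bins + 1)).astype(np.int64),
        )


def read_cooler(path) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f["chroms/name"][:]
        ]
        lengths = f["chroms/length"][:].tolist()
        binsize = int(f.attrs["bin-size"])
        bt = make_bintable(list(zip(names, lengths)), binsize)
        bin1 = f["pixels/bin1_id"][:]
        bin2 = f["pixels/bin2_id"][:]
        data = f["pixels/count"][:]
    n = bt.n_bins
    return ContactMatrix(bt, sp.coo_matrix((data, (bin1, bin2)), shape=(n, n)))


def write_interaction_table(cm: ContactMatrix, path, use_values: bool = True) -> None:
    """7-column BED-pair export: chrom1 start1 end1 chrom2 start2 end2 value."""
    m = (cm.values if use_values and cm.values is not None else cm.counts).tocoo()
    bt = cm.bintable
    r = bt.binsize
    with open(path, "w") as fh:
        for i, j, v in zip(m.row, m.col, m.data):
            c1, s1 = bt.bin_start(int(i))
            c2, s2 = bt.bin_start(int(j))
            e1 = min(s1 + r, bt.chrom_length(c1))
            e2 = min(s2 + r, bt.chrom_length(c2))
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{float(v):.6g}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def coverage_profile(cm: ContactMatrix) -> np.ndarray:
    """Per-bin marginal sums, diagonal counted once."""
    sym = cm.symmetric()
    marg = np.asarray(sym.sum(axis=1)).ravel()
    return marg


def coverage_normalize(cm: ContactMatrix, normalizer=None):
    """Marginal-product coverage normalization preserving total mass.

    Returns ``(normalized ContactMatrix, zero_coverage_bins)``.  The
    normalized matrix carries ``values`` on the same sparsity pattern;
    zero-marginal bins yield zero values and are returned as the flag list.
    A custom ``normalizer`` callable ``(cm) -> sparse values`` may replace
    the built-in scaling.
    """
    if normalizer is not None:
        out = cm.copy_with_values(normalizer(cm))
        return out, np.where(coverage_profile(cm) == 0)[0]
    marg = coverage_profile(cm)
    zero_bins = np.where(marg == 0)[0]
    if len(zero_bins) == cm.n_bins or cm.total() == 0:
        raise HicderError("all-zero matrix cannot be coverage-normalized")
    coo = cm.counts.tocoo()
    safe = np.where(marg > 0, marg, 1.0)
    raw = coo.data / (safe[coo.row] * safe[coo.col])
    raw[(marg[coo.row] == 0) | (marg[coo.col] == 0)] = 0.0
    scale = cm.total() / raw.sum()
    values = sp.coo_matrix((raw * scale, (coo.row, coo.col)), shape=coo.shape)
    return cm.copy_with_values(values), zero_bins


@dataclass
class ExpectedProfile:
    """Mean cis contact value at each bin distance, optionally per chromosome.

    ``pooled`` is always available (all chromosomes combined) and is what
    distance lookups on derivative axes use; ``per_chrom`` holds
    chromosome-specific curves when the profile was built with
    per-chromosome scope.  Values are log-space moving-average smoothed over
    ``smooth_window`` bins and floored at ``eps``.
    """

    pooled: np.ndarray
    per_chrom: dict = field(default_factory=dict)
    scope: str = "per-chromosome"
    smooth_window: int = 1
    trans_mean: float = 0.0
    eps: float = EPSILON

    def expected(self, d: int, chrom: str | None = None) -> float:
        if self.scope == "per-chromosome" and chrom is not None:
            curve = self.per_chrom.get(chrom)
            if curve is None:
                raise HicderError(f"no expected profile for chromosome {chrom!r}")
        else:
            curve = self.pooled
        if not 0 <= d < len(curve):
            raise HicderError(f"no expected value at distance {d}")
        return float(curve[d])

    def max_distance(self, chrom: str | None = None) -> int:
        if self.scope == "per-chromosome" and chrom is not None:
            return len(self.per_chrom[chrom]) - 1
        return len(self.pooled) - 1


def _smooth_log(curve: np.ndarray, window: int, eps: float) -> np.ndarray:
    if window <= 1:
        return np.maximum(curve, eps)
    h = window // 2
    logc = np.log(np.maximum(curve, eps))
    out = np.empty_like(logc)
    for d in range(len(logc)):
        lo, hi = max(0, d - h), min(len(logc), d + h + 1)
        out[d] = logc[lo:hi].mean()
    return np.maximum(np.exp(out), eps)


def expected_by_distance(
    cm: ContactMatrix, scope: str = "per-chromosome", smooth_window: int = 1
) -> ExpectedProfile:
    """Distance-decay expectation: mean over all cis pairs at each distance.

    Structural zeros count in the denominator (a chromosome of n bins has
    n - d pairs at distance d).  ``scope`` selects per-chromosome curves or a
    single pooled curve; the pooled curve is computed either way.
    """
    if scope not in ("per-chromosome", "pooled"):
        raise HicderError(f"unknown scope {scope!r}")
    bt = cm.bintable
    coo = cm.counts.tocoo()
    chrom_of = bt.bin_chrom_ids()
    ci, cj = chrom_of[coo.row], chrom_of[coo.col]
    cis = ci == cj
    if not np.any(cis) and cm.total() > 0:
        raise HicderError("matrix has no cis entries")

    nbins = {c: bt.chrom_nbins(c) for c in bt.chrom_names}
    max_d = max(nbins.values()) - 1
    dist = (coo.col - coo.row)[cis]
    cis_chrom = ci[cis]

    per_chrom: dict[str, np.ndarray] = {}
    pooled_sum = np.zeros(max_d + 1)
    pooled_n = np.zeros(max_d + 1)
    for cid, name in enumerate(bt.chrom_names):
        n = nbins[name]
        mask = cis_chrom == cid
        sums = np.bincount(dist[mask], weights=coo.data[cis][mask], minlength=n)[:n]
        npairs = n - np.arange(n)
        per_chrom[name] = sums / npairs
        pooled_sum[:n] += sums
        pooled_n[:n] += npairs
    pooled = np.divide(
        pooled_sum, pooled_n, out=np.zeros_like(pooled_sum), where=pooled_n > 0
    )

    trans = ~cis
    n_total = bt.n_bins
    n_cis_pairs = sum(n * (n + 1) // 2 for n in nbins.values())
    n_trans_pairs = n_total * (n_total + 1) // 2 - n_cis_pairs
    trans_mean = (
        float(coo.data[trans].sum()) / n_trans_pairs if n_trans_pairs else 0.0
    )

    profile = ExpectedProfile(
        pooled=_smooth_log(pooled, smooth_window, EPSILON),
        per_chrom={
            c: _smooth_log(v, smooth_window, EPSILON) for c, v in per_chrom.items()
        }
        if scope == "per-chromosome"
        else {},
        scope=scope,
        smooth_window=smooth_window,
        trans_mean=max(trans_mean, EPSILON),
    )
    cm.expected = profile
    return profile


def distance_normalize(cm: ContactMatrix, profile: ExpectedProfile) -> ContactMatrix:
    """Observed/expected fold change on the stored sparsity pattern.

    Cis pairs divide by the expected value at their bin distance (chromosome
    curve under per-chromosome scope); trans pairs divide by the pooled
    trans mean.
    """
    bt = cm.bintable
    coo = cm.counts.tocoo()
    chrom_of = bt.bin_chrom_ids()
    ci, cj = chrom_of[coo.row], chrom_of[coo.col]
    fc = np.empty_like(coo.data, dtype=float)
    names = bt.chrom_names
    for k in range(len(coo.data)):
        if ci[k] == cj[k]:
            d = int(coo.col[k] - coo.row[k])
            fc[k] = coo.data[k] / profile.expected(d, names[ci[k]])
        else:
            fc[k] = coo.data[k] / profile.trans_mean
    out = cm.copy_with_values(
        sp.coo_matrix((fc, (coo.row, coo.col)), shape=coo.shape)
    )
    out.expected = profile
    return out
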