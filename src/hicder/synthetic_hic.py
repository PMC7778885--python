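"""Synthetic Hi-C generator with known ground truth.

The forward model emulates what a rearranged cancer genome looks like through
a Hi-C experiment mapped back to the reference: contacts are generated on the
*derivative* genome, where the distance decay applies to derivative-axis
distance, then projected onto reference coordinates — so a deletion produces
the characteristic "bowtie" of enriched long-range reference contacts between
its flanks, and a translocation produces a trans block even with zero
background trans level.

Cis intensity between derivative-axis bins a, b at distance d = |a - b| is

    lambda_cis = A * (1 + d)^(-alpha) * (beta if same TAD else 1)

and lambda_trans = t * A between different derivatives.  Counts are Poisson
(chosen for exact-mean properties; overdispersion would need a negative
binomial emission, an extension hook).  TADs are a property of the reference:
each reference bin carries a TAD label, a derivative bin inherits the label
of its source bin, and the boost applies only within one fragment — so a
junction splits a TAD, and fused fragments form the sharp neo-adjacency the
method is designed to reveal.

All randomness flows from the mandatory integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import yaml

from .contact_store import ContactMatrix, expected_by_distance
from .genome_model import (
    BinMap,
    BinTable,
    DerivativeGenome,
    Fragment,
    HicderError,
    derivative_to_binmap,
    identity_binmap,
    make_bintable,
)
from .sv_model import SVRecord, sv_to_derivative, validate_sv

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_reference",
    "simulate_rearranged",
    "estimate_decay_exponent",
    "load_sim_params",
]


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    ``chrom_sizes`` and ``binsize`` define the reference grid; ``amplitude``
    (A) sets the short-range contact level, ``alpha`` the power-law decay
    exponent, ``beta`` the within-TAD boost (>= 1), ``trans_level`` (t, in
    [0, 1]) the trans background as a fraction of A.  TAD boundaries may be
    given explicitly per chromosome (bin indices) or drawn randomly
    (``n_tads`` per chromosome).  ``seed`` is mandatory — no implicit
    randomness.
    """

    chrom_sizes: tuple
    binsize: int
    seed: int
    amplitude: float = 100.0
    alpha: float = 1.0
    beta: float = 2.0
    trans_level: float = 0.02
    tad_boundaries: dict | None = None
    n_tads: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chrom_sizes", tuple(map(tuple, self.chrom_sizes)))
        if self.amplitude <= 0:
            raise HicderError("amplitude must be > 0")
        if self.alpha <= 0:
            raise HicderError("alpha must be > 0")
        if self.beta < 1:
            raise HicderError("beta must be >= 1")
        if not 0 <= self.trans_level <= 1:
            raise HicderError("trans_level must be in [0, 1]")
        if self.seed is None:
            raise HicderError("seed is mandatory")

    def bintable(self) -> BinTable:
        return make_bintable(self.chrom_sizes, self.binsize)


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated matrix."""

    derivatives: list[DerivativeGenome]
    binmaps: dict
    tad_labels: np.ndarray  # per reference bin
    tad_intervals: list  # (chrom, start_bin, end_bin) per TAD


def _draw_tads(p: SimParams, bt: BinTable, rng: np.random.Generator):
    """Per-reference-bin TAD labels, unique across chromosomes."""
    labels = np.zeros(bt.n_bins, dtype=np.int64)
    intervals = []
    next_label = 0
    for chrom in bt.chrom_names:
        n = bt.chrom_nbins(chrom)
        off = bt.chrom_offset(chrom)
        if p.tad_boundaries and chrom in p.tad_boundaries:
            bounds = sorted(int(b) for b in p.tad_boundaries[chrom] if 0 < b < n)
        elif p.n_tads > 1:
            bounds = sorted(
                rng.choice(np.arange(1, n), size=min(p.n_tads - 1, n - 1), replace=False).tolist()
            )
        else:
            bounds = []
        edges = [0] + bounds + [n]
        for s, e in zip(edges[:-1], edges[1:]):
            labels[off + s : off + e] = next_label
            intervals.append((chrom, s, e))
            next_label += 1
    return labels, intervals


def _truth_binmaps(
    p: SimParams, bt: BinTable, svs: list[SVRecord]
) -> tuple[list[DerivativeGenome], dict]:
    """One derivative per SV; untouched chromosomes stay as identity.

    Each chromosome may be consumed by at most one SV record (sequential
    multi-hit rearrangements are expressed through the edit or order-spec
    interfaces instead).
    """
    used: set[str] = set()
    derivatives: list[DerivativeGenome] = []
    binmaps: dict[str, BinMap] = {}
    for sv in svs:
        for c in {sv.chrom1, sv.chrom2}:
            if c in used:
                raise HicderError(
                    f"chromosome {c} used by more than one SV record"
                )
            used.add(c)
        der = sv_to_derivative(bt, sv)
        derivatives.append(der)
        binmaps[der.name] = derivative_to_binmap(bt, der)
    for chrom in bt.chrom_names:
        if chrom not in used:
            derivatives.append(
                DerivativeGenome(
                    chrom, (Fragment(chrom, 0, bt.chrom_length(chrom), "+"),)
                )
            )
            binmaps[chrom] = identity_binmap(bt, chrom)
    return derivatives, binmaps


def _lambda_matrix(
    p: SimParams, binmaps: dict, bt: BinTable, tad_labels: np.ndarray
) -> np.ndarray:
    names = list(binmaps)
    src = np.concatenate([binmaps[n].source_bins for n in names])
    frag = np.concatenate([binmaps[n].fragment_ids for n in names])
    der = np.concatenate(
        [np.full(len(binmaps[n]), k) for k, n in enumerate(names)]
    )
    axis = np.concatenate(
        [np.arange(len(binmaps[n])) for n in names]
    )
    n = len(src)
    lam = np.full((n, n), p.trans_level * p.amplitude)
    same_der = der[:, None] == der[None, :]
    d = np.abs(axis[:, None] - axis[None, :])
    cis = p.amplitude * (1.0 + d) ** (-p.alpha)
    same_tad = (
        (tad_labels[src][:, None] == tad_labels[src][None, :])
        & (frag[:, None] == frag[None, :])
        & same_der
    )
    cis = np.where(same_tad, cis * p.beta, cis)
    return np.where(same_der, cis, lam)


def _simulate(p: SimParams, svs: list[SVRecord]):
    bt = p.bintable()
    rng = np.random.default_rng(p.seed)
    tad_labels, tad_intervals = _draw_tads(p, bt, rng)
    derivatives, binmaps = _truth_binmaps(p, bt, svs)
    lam = _lambda_matrix(p, binmaps, bt, tad_labels)
    n = lam.shape[0]
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    # project derivative-axis pairs back to reference bins (fold to upper)
    src = np.concatenate([binmaps[k].source_bins for k in binmaps])
    ri, rj = src[iu], src[ju]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    ref = ContactMatrix(
        bt,
        sp.coo_matrix((counts, (lo, hi)), shape=(bt.n_bins, bt.n_bins)),
    )
    truth = SimTruth(
        derivatives=derivatives,
        binmaps=binmaps,
        tad_labels=tad_labels,
        tad_intervals=tad_intervals,
    )
    return ref, truth


def simulate_reference(p: SimParams):
    """Simulate an unrearranged reference map; returns (matrix, truth)."""
    return _simulate(p, [])


def simulate_rearranged(p: SimParams, svs: list[SVRecord]):
    """Simulate on the derivative genome implied by ``svs`` and project back
    to reference coordinates; returns (matrix, truth).

    With an empty SV list this is exactly :func:`simulate_reference` (same
    seed gives an identical matrix).  Reference bins deleted by an SV receive
    no counts; bins duplicated by a DUP accumulate the counts of both copies,
    mimicking reads from two alleles piling onto one reference bin.  Total
    counts are conserved by the projection.
    """
    for sv in svs:
        bad = [
            f
            for f in validate_sv(p.bintable(), sv)
            if "out of range" in f or "unknown" in f
        ]
        if bad:
            raise HicderError("; ".join(bad))
    return _simulate(p, svs)


def estimate_decay_exponent(cm: ContactMatrix, min_distances: int = 50) -> float:
    """Least-squares power-law decay exponent from the pooled expectation.

    Fits log expected(d) against log(1 + d) over distances d >= 1 with a
    positive expectation and returns the negated slope.
    """
    profile = expected_by_distance(cm, scope="pooled", smooth_window=1)
    curve = profile.pooled
    d = np.arange(1, len(curve))
    keep = curve[d] > 2 * profile.eps
    d = d[keep]
    if len(d) < min_distances:
        raise HicderError(
            f"need >= {min_distances} distances with nonzero expectation, "
            f"got {len(d)}"
        )
    slope = np.polyfit(np.log1p(d), np.log(curve[d]), 1)[0]
    return float(-slope)


def load_sim_params(path, seed: int | None = None) -> SimParams:
    """Load SimParams from a YAML config; an explicit ``seed`` overrides."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if seed is not None:
        cfg["seed"] = seed
    if "chrom_sizes" in cfg and isinstance(cfg["chrom_sizes"], dict):
        cfg["chrom_sizes"] = list(cfg["chrom_sizes"].items())
    return SimParams(**cfg)
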