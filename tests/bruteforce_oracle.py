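"""Independent brute-force oracle for rearrangement semantics.

A derivative is modelled as an explicit Python list of (source_bin, orient)
tuples; edits are plain list surgery and materialization is a double loop.
Nothing here shares code with the package's engine.
"""

import numpy as np


def oracle_identity(n_bins, offset=0):
    return [(offset + i, 1) for i in range(n_bins)]


def oracle_delete(lst, a, b):
    return lst[:a] + lst[b:]


def oracle_invert(lst, a, b):
    return lst[:a] + [(s, -o) for s, o in reversed(lst[a:b])] + lst[b:]


def oracle_duplicate(lst, a, b):
    return lst[:a] + lst[a:b] + lst[a:b] + lst[b:]


def oracle_materialize(dense_source, lst, chrom_of=None, w=1.0):
    """Fill M'[x, y] = M[src(x), src(y)], scaling trans-source pairs by w."""
    n = len(lst)
    out = np.empty((n, n), dtype=float)
    for x in range(n):
        for y in range(n):
            sx, sy = lst[x][0], lst[y][0]
            v = dense_source[sx, sy]
            if chrom_of is not None and chrom_of[sx] != chrom_of[sy]:
                v = v * w
            out[x, y] = v
    return out


def random_symmetric_counts(rng, n, max_count=20):
    m = rng.integers(0, max_count + 1, size=(n, n))
    return np.triu(m) + np.triu(m, 1).T
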