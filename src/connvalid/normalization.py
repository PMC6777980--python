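"""Weight normalizations for tracer and tractography count matrices.

Two normalizations make raw counts comparable across regions:

* FLN (fraction of labeled neurons): each injected column of the
  retrograde-tracing count matrix is divided by its total labeled-neuron
  count, so nonzero columns sum to 1.
* FS (fraction of streamlines): each streamline count is divided by the
  sum of streamline counts attached to both regions of the pair,
  excluding self-connections.

Both exclude the diagonal; FS requires a symmetric input because
tractography carries no direction information.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import WeightedConnectome

__all__ = [
    "compute_fln",
    "fractional_scaling",
    "symmetrize",
    "pseudocount_log",
    "add_pseudocount",
    "log_weights",
]


def compute_fln(counts: WeightedConnectome) -> WeightedConnectome:
    """Fraction of labeled neurons: column-wise normalization.

    ``FLN[i, j] = N[i, j] / sum_i' N[i', j]`` for each injected (target)
    column *j*.  Retrograde tracing semantics: the tracer is injected in
    the target, labeled cell bodies sit in the sources (rows).

    Raises
    ------
    ValueError
        If a column has zero total -- an injection that labeled no
        neurons is not interpretable.
    """
    if counts.kind != "count":
        raise ValueError(f"compute_fln expects kind='count', got {counts.kind!r}")
    W = counts.W
    col_totals = W.sum(axis=0)
    zero_cols = np.flatnonzero(col_totals == 0)
    if zero_cols.size:
        names = [counts.regions.labels[j] for j in zero_cols]
        raise ValueError(f"injection site(s) with zero labeled neurons: {names}")
    fln = W / col_totals[None, :]
    return WeightedConnectome(
        regions=counts.regions, W=fln, directed=counts.directed, kind="fln",
        meta=dict(counts.meta),
    )


def fractional_scaling(
    counts: WeightedConnectome, *, subtract_shared: bool = False
) -> WeightedConnectome:
    """Fraction of streamlines for a symmetric streamline-count matrix.

    ``FS[i, j] = S[i, j] / (sum_k S[i, k] + sum_k S[j, k])`` with both
    sums excluding self-connections.  The shared count ``S[i, j]`` thus
    appears in both totals; ``subtract_shared=True`` switches to the
    variant that removes it once from the denominator.  FS is symmetric
    and invariant under ``S -> c*S`` for any ``c > 0``.
    """
    if counts.directed:
        raise ValueError("fractional scaling requires a symmetric (undirected) matrix")
    S = counts.W
    strength = S.sum(axis=1)  # diagonal is zero, so self-connections are excluded
    denom = strength[:, None] + strength[None, :]
    if subtract_shared:
        denom = denom - S
    with np.errstate(invalid="ignore", divide="ignore"):
        fs = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(fs, 0.0)
    isolated = (denom == 0) & ~np.eye(S.shape[0], dtype=bool)
    if np.any(isolated):
        warnings.warn(
            "isolated region pair(s) with zero denominator; FS set to 0",
            stacklevel=2,
        )
    return WeightedConnectome(
        regions=counts.regions, W=fs, directed=False, kind="fs",
        meta=dict(counts.meta),
    )


def symmetrize(conn: WeightedConnectome) -> WeightedConnectome:
    """Average weights in both directions: ``(W + W.T) / 2``. Idempotent."""
    W = (conn.W + conn.W.T) / 2.0
    if conn.kind == "count" and not np.array_equal(W, np.rint(W)):
        raise ValueError(
            "symmetrizing these counts yields non-integers; "
            "normalize before symmetrizing"
        )
    return WeightedConnectome(
        regions=conn.regions, W=W, directed=False, kind=conn.kind,
        meta=dict(conn.meta),
    )


def add_pseudocount(counts: WeightedConnectome) -> WeightedConnectome:
    """Increment every off-diagonal raw count by 1 (diagonal stays 0)."""
    if counts.kind != "count":
        raise ValueError(f"add_pseudocount expects kind='count', got {counts.kind!r}")
    off = ~np.eye(counts.n, dtype=bool)
    W1 = counts.W.copy()
    W1[off] += 1.0
    return WeightedConnectome(
        regions=counts.regions, W=W1, directed=counts.directed, kind="count",
        meta=dict(counts.meta),
    )


def log_weights(conn: WeightedConnectome) -> WeightedConnectome:
    """Natural log of all off-diagonal weights (which must be positive)."""
    off = ~np.eye(conn.n, dtype=bool)
    if np.any(conn.W[off] <= 0):
        raise ValueError(
            "log transform needs strictly positive off-diagonal weights; "
            "apply a pseudocount first"
        )
    logW = np.zeros_like(conn.W)
    logW[off] = np.log(conn.W[off])
    return WeightedConnectome(
        regions=conn.regions, W=logW, directed=conn.directed, kind="log",
        meta=dict(conn.meta),
    )


def pseudocount_log(
    counts: WeightedConnectome,
    normalizer: str,
    *,
    subtract_shared: bool = False,
) -> WeightedConnectome:
    """Pseudocount, normalize, then natural log.

    Every off-diagonal raw count is incremented by 1 (so absent
    connections survive the log), the chosen normalization (``'fln'`` or
    ``'fs'``) is applied, and the natural logarithm is taken.  All
    outputs are finite.
    """
    bumped = add_pseudocount(counts)
    if normalizer == "fln":
        if not counts.directed:
            raise ValueError(
                "FLN needs a directed count matrix (injection columns); "
                "this matrix is symmetric-only"
            )
        norm = compute_fln(bumped)
    elif normalizer == "fs":
        if counts.directed:
            raise ValueError("FS needs a symmetric count matrix")
        norm = fractional_scaling(bumped, subtract_shared=subtract_shared)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}; use 'fln' or 'fs'")
    return log_weights(norm)
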