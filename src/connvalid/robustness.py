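"""Robustness of the tracing/tractography association to edge removal.

Strong connections are short-range and easy to reconstruct, weak ones
are noise-prone; if either group drove the correlation, removing it
would change the coefficient sharply.  The removal curve recomputes the
association after progressively dropping the strongest (or weakest)
tract-tracing connections from *both* weight vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import EdgeTable, _METHODS

__all__ = ["RemovalCurve", "removal_curve", "DEFAULT_FRACTIONS"]

#: removal grid from 0 to one half in steps of 0.05
DEFAULT_FRACTIONS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.501, 0.05), 2))


@dataclass
class RemovalCurve:
    direction: str
    fractions: np.ndarray
    coefficients: np.ndarray
    p_values: np.ndarray
    n_remaining: np.ndarray
    method: str = "spearman"

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.n_remaining = np.asarray(self.n_remaining, dtype=int)


def _removal_order(table: EdgeTable, direction: str) -> np.ndarray:
    """Edge indices in removal order, ties broken by table position.

    Tables are built in (row, column) index order, so this realizes a
    stable (row, column) tie-break.  Ranking uses the tracing weight
    ``x`` only, so permuting ``y`` never changes which edges drop.
    """
    if direction == "strongest":
        key = -table.x
    elif direction == "weakest":
        key = table.x
    else:
        raise ValueError(f"direction must be 'strongest' or 'weakest', got {direction!r}")
    return np.argsort(key, kind="stable")


def removal_curve(
    table: EdgeTable,
    direction: str = "strongest",
    fractions: tuple[float, ...] | np.ndarray = DEFAULT_FRACTIONS,
    method: str = "spearman",
) -> RemovalCurve:
    """Association coefficient after removing a fraction of edges.

    For each fraction *f* the ``ceil(f * E)`` strongest (or weakest)
    tract-tracing edges are dropped from both weight vectors and the
    chosen association is recomputed.  ``f = 0`` reproduces the
    full-table coefficient exactly.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions[0] != 0.0 or np.any(np.diff(fractions) <= 0):
        raise ValueError("fractions must be strictly increasing and start at 0")
    if np.any(fractions < 0) or np.any(fractions >= 1):
        raise ValueError("fractions must lie in [0, 1)")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    fit = _METHODS[method]
    E = table.n_edges
    order = _removal_order(table, direction)
    coefs, pvals, remaining = [], [], []
    for f in fractions:
        k = int(np.ceil(f * E))
        if E - k < 3:
            raise ValueError(
                f"fraction {f} leaves {E - k} edges; need at least 3"
            )
        keep = np.ones(E, dtype=bool)
        keep[order[:k]] = False
        res = fit(table.subset(keep))
        coefs.append(res.coefficient)
        pvals.append(res.p_value)
        remaining.append(E - k)
    return RemovalCurve(
        direction=direction, fractions=fractions,
        coefficients=np.array(coefs), p_values=np.array(pvals),
        n_remaining=np.array(remaining), method=method,
    )
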