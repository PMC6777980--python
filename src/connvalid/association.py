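"""Association between tract-tracing and tractography weights.

The central object is the :class:`EdgeTable`: one row per region pair,
carrying the tracing weight ``x``, the tractography weight ``y`` and
optionally the Euclidean distance between the pair's centroids.  Absent
connections are kept as zeros -- they enter rank correlations as tied
minimal ranks, which is exactly how undetected connections should count.

Methods: midrank Spearman, Pearson on log-transformed weights, percentile
bootstrap confidence intervals (resampling edges with replacement), and a
distance-partialed Spearman (OLS of each log-weight on distance, then
Spearman of the residuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTable",
    "AssociationResult",
    "build_edge_table",
    "spearman",
    "pearson_log",
    "bootstrap_ci",
    "partial_spearman_distance",
]


@dataclass
class EdgeTable:
    """Aligned per-edge records for association analyses.

    ``i``/``j`` are region indices (``i < j`` in symmetric mode, all
    ordered pairs ``i != j`` in directed mode), ``x`` the tracing weight,
    ``y`` the tractography weight, ``dist`` the centroid distance (mm).
    """

    i: np.ndarray
    j: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dist: np.ndarray | None = None
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.dist is not None:
            self.dist = np.asarray(self.dist, dtype=float)
        lengths = {len(self.i), len(self.j), len(self.x), len(self.y)}
        if self.dist is not None:
            lengths.add(len(self.dist))
        if len(lengths) != 1:
            raise ValueError("edge-table columns have mismatched lengths")
        if np.any(self.i == self.j):
            raise ValueError("diagonal pairs are not edges")

    @property
    def n_edges(self) -> int:
        return len(self.x)

    def subset(self, keep: np.ndarray) -> "EdgeTable":
        return EdgeTable(
            i=self.i[keep], j=self.j[keep], x=self.x[keep], y=self.y[keep],
            dist=None if self.dist is None else self.dist[keep], mode=self.mode,
        )


@dataclass
class AssociationResult:
    method: str
    coefficient: float
    p_value: float
    n_edges: int
    ci_low: float | None = None
    ci_high: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.coefficient <= self.ci_high):
                raise ValueError(
                    f"coefficient {self.coefficient} outside CI "
                    f"[{self.ci_low}, {self.ci_high}]"
                )


def build_edge_table(
    tracing: WeightedConnectome,
    tract: WeightedConnectome,
    dists: np.ndarray | None = None,
    mode: str = "symmetric",
) -> EdgeTable:
    """Align two connectomes into per-edge records.

    Symmetric mode yields one row per unordered pair (``n(n-1)/2`` edges)
    and requires a symmetrized tracing matrix.  Directed mode yields all
    ``n(n-1)`` ordered pairs, pairing the directed tracing weight
    ``x[i->j]`` with the symmetric tractography weight of the pair.
    """
    if tracing.regions != tract.regions:
        raise ValueError("tracing and tractography connectomes use different regions")
    n = tracing.n
    if mode == "symmetric":
        if tracing.directed:
            raise ValueError("symmetric mode requires a symmetrized tracing matrix")
        ii, jj = np.triu_indices(n, k=1)
    elif mode == "directed":
        ii, jj = np.where(~np.eye(n, dtype=bool))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if tract.directed:
        raise ValueError("tractography matrix must be symmetric (no directionality)")
    return EdgeTable(
        i=ii, j=jj,
        x=tracing.W[ii, jj], y=tract.W[ii, jj],
        dist=None if dists is None else np.asarray(dists)[ii, jj],
        mode=mode,
    )


def sort_by_labels(table: EdgeTable, regions) -> EdgeTable:
    """Reorder edges lexicographically by region labels.

    Downstream order-sensitive steps (bootstrap resampling, tie-breaks
    in removal ranking) then give bit-identical results no matter how
    the input files ordered the regions.
    """
    li = np.array([regions.labels[k] for k in table.i])
    lj = np.array([regions.labels[k] for k in table.j])
    if table.mode == "symmetric":
        # orient each unordered pair with the smaller label first
        swap = li > lj
        ii = np.where(swap, table.j, table.i)
        jj = np.where(swap, table.i, table.j)
        table = EdgeTable(i=ii, j=jj, x=table.x, y=table.y,
                          dist=table.dist, mode=table.mode)
        li, lj = np.where(swap, lj, li), np.where(swap, li, lj)
    return table.subset(np.lexsort((lj, li)))


def _check_nonconstant(v: np.ndarray, name: str) -> None:
    if np.all(v == v[0]):
        raise ValueError(f"{name} is constant; correlation undefined")


def spearman(table: EdgeTable) -> AssociationResult:
    """Midrank-tied Spearman rho with t-approximation p-value.

    Absent connections (zeros) enter as tied minimal ranks.
    """
    if table.n_edges < 3:
        raise ValueError("need at least 3 edges for a rank correlation")
    _check_nonconstant(table.x, "x (tracing weights)")
    _check_nonconstant(table.y, "y (tractography weights)")
    rho, p = stats.spearmanr(table.x, table.y)
    return AssociationResult(
        method="spearman", coefficient=float(rho), p_value=float(p),
        n_edges=table.n_edges,
    )


def spearman_exact(table: EdgeTable) -> AssociationResult:
    """Spearman rho with an exact permutation p-value (n_edges <= 10)."""
    if table.n_edges > 10:
        raise ValueError("exact permutation p-value only for n_edges <= 10")
    _check_nonconstant(table.x, "x")
    _check_nonconstant(table.y, "y")
    res = stats.permutation_test(
        (table.x, table.y),
        lambda a, b: stats.spearmanr(a, b).statistic,
        permutation_type="pairings",
        n_resamples=np.inf,
    )
    rho = float(stats.spearmanr(table.x, table.y).statistic)
    return AssociationResult(
        method="spearman_exact", coefficient=rho, p_value=float(res.pvalue),
        n_edges=table.n_edges,
    )


def pearson_log(table: EdgeTable) -> AssociationResult:
    """Product-moment correlation on pseudocount-logged weights.

    The table must already hold log-transformed values (finite by
    construction of the pseudocount pathway).
    """
    if table.n_edges < 3:
        raise ValueError("need at least 3 edges")
    _check_nonconstant(table.x, "x (log tracing weights)")
    _check_nonconstant(table.y, "y (log tractography weights)")
    r, p = stats.pearsonr(table.x, table.y)
    return AssociationResult(
        method="pearson_log", coefficient=float(r), p_value=float(p),
        n_edges=table.n_edges,
    )


_METHODS = {"spearman": spearman, "pearson_log": pearson_log}


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    out = np.full(len(num), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _batch_coefficients(xr: np.ndarray, yr: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        xr = stats.rankdata(xr, axis=1)
        yr = stats.rankdata(yr, axis=1)
    return _rowwise_pearson(xr, yr)


def bootstrap_ci(
    table: EdgeTable,
    method: str = "spearman",
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    unit: str = "edge",
) -> AssociationResult:
    """Percentile bootstrap CI by resampling edges with replacement.

    Paired ``(x, y)`` records are the resampling unit by default;
    ``unit='region'`` instead resamples regions (node bootstrap), keeping
    edges whose both endpoints were drawn.  Resamples with an undefined
    coefficient (a constant vector) are redrawn and logged.  Deterministic
    under a fixed seed.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    point = _METHODS[method](table)
    rng = np.random.default_rng(seed)
    n = table.n_edges
    coefs = np.empty(n_boot)
    filled = 0
    n_redrawn = 0
    while filled < n_boot:
        todo = n_boot - filled
        if unit == "edge":
            idx = rng.integers(0, n, size=(todo, n))
            xr, yr = table.x[idx], table.y[idx]
        elif unit == "region":
            # node bootstrap: ragged samples, so compute one at a time
            regions = np.unique(np.concatenate([table.i, table.j]))
            vals = np.empty(todo)
            for k in range(todo):
                drawn = rng.choice(regions, size=len(regions), replace=True)
                keep = np.isin(table.i, drawn) & np.isin(table.j, drawn)
                xa, ya = table.x[keep], table.y[keep]
                if len(xa) < 3 or np.all(xa == xa[0]) or np.all(ya == ya[0]):
                    vals[k] = np.nan
                elif method == "spearman":
                    vals[k] = stats.spearmanr(xa, ya).statistic
                else:
                    vals[k] = stats.pearsonr(xa, ya).statistic
            ok = ~np.isnan(vals)
            n_redrawn += int((~ok).sum())
            coefs[filled : filled + ok.sum()] = vals[ok]
            filled += int(ok.sum())
            continue
        else:
            raise ValueError(f"unknown resampling unit {unit!r}")
        vals = _batch_coefficients(xr, yr, method)
        ok = ~np.isnan(vals)
        n_redrawn += int((~ok).sum())
        coefs[filled : filled + ok.sum()] = vals[ok]
        filled += int(ok.sum())
    if n_redrawn:
        logger.info("bootstrap: redrew %d degenerate resamples", n_redrawn)
    alpha = 1.0 - level
    lo, hi = np.quantile(coefs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AssociationResult(
        method=point.method, coefficient=point.coefficient, p_value=point.p_value,
        n_edges=point.n_edges,
        ci_low=float(min(lo, point.coefficient)),
        ci_high=float(max(hi, point.coefficient)),
        meta={"n_boot": n_boot, "level": level, "unit": unit,
              "n_redrawn": n_redrawn},
    )


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of an intercept+slope least-squares fit of y on x."""
    if np.all(x == x[0]):
        return y - y.mean()  # constant predictor: slope unidentified, fit the mean
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_spearman_distance(table: EdgeTable) -> AssociationResult:
    """Spearman of log-weight residuals after regressing out distance.

    Both (pseudocount-logged) weight vectors are regressed on the
    Euclidean centroid distance by ordinary least squares; the two
    residual vectors are then rank-correlated.  With constant distances
    this reduces to the plain Spearman of the weights.
    """
    if table.dist is None:
        raise ValueError("edge table has no distances; provide region centroids")
    if table.n_edges < 4:
        raise ValueError("need at least 4 edges for distance-partialed correlation")
    rx = _ols_residuals(table.x, table.dist)
    ry = _ols_residuals(table.y, table.dist)
    if np.allclose(rx, rx[0]):
        raise ValueError("tracing residuals are constant; correlation undefined")
    if np.allclose(ry, ry[0]):
        raise ValueError("tractography residuals are constant; correlation undefined")
    rho, p = stats.spearmanr(rx, ry)
    return AssociationResult(
        method="partial_spearman", coefficient=float(rho), p_value=float(p),
        n_edges=table.n_edges,
    )
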