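"""Core containers for region sets and weighted connectivity matrices.

A :class:`RegionSet` fixes the ordering of cortical areas; every matrix in
the package is indexed by that order (rows = source region, columns =
target/injected region).  A :class:`WeightedConnectome` couples a matrix
with its region set, its directedness, and the *kind* of weight it holds:

``count``
    raw integer counts (streamlines or retrograde-labeled neurons)
``fln``
    fraction of labeled neurons -- each injected column normalized to 1
``fs``
    fraction of streamlines -- fractional scaling of a symmetric matrix
``log``
    natural log of pseudocounted, normalized weights (may be negative)
``weight``
    latent nonnegative real weights, e.g. a simulated ground truth
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_KINDS = ("count", "fln", "fs", "log", "weight")

#: kinds whose entries must be nonnegative
_NONNEG_KINDS = ("count", "fln", "fs", "weight")


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of region labels with optional 3-D centroids (mm).

    Parameters
    ----------
    labels
        Unique, non-empty region names.  Order defines matrix indexing.
    centroids
        Optional ``(n, 3)`` array of centroid coordinates in millimetres,
        in an arbitrary but shared space (only relative distances matter).
    """

    labels: tuple[str, ...]
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValueError("RegionSet requires at least one label")
        if any(l == "" for l in labels):
            raise ValueError("empty region label")
        seen: set[str] = set()
        for l in labels:
            if l in seen:
                raise ValueError(f"duplicate region label: {l!r}")
            seen.add(l)
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (len(labels), 3):
                raise ValueError(
                    f"centroids must have shape ({len(labels)}, 3), got {c.shape}"
                )
            if not np.all(np.isfinite(c)):
                raise ValueError("centroids must be finite")
            c.setflags(write=False)
            object.__setattr__(self, "centroids", c)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if self.labels != other.labels:
            return False
        if (self.centroids is None) != (other.centroids is None):
            return False
        if self.centroids is None:
            return True
        return bool(np.array_equal(self.centroids, other.centroids))


@dataclass
class WeightedConnectome:
    """An ``n x n`` weight matrix over a :class:`RegionSet`.

    Rows index the source region and columns the target (injected) region;
    for an undirected matrix the distinction is immaterial and ``W`` must
    equal its transpose.  The diagonal (self-connections) is always zero.
    """

    regions: RegionSet
    W: np.ndarray
    directed: bool
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}; expected one of {VALID_KINDS}")
        W = np.asarray(self.W, dtype=float)
        n = self.regions.n
        if W.shape != (n, n):
            raise ValueError(f"matrix shape {W.shape} does not match {n} regions")
        if not np.all(np.isfinite(W)):
            raise ValueError("matrix entries must be finite")
        if self.kind in _NONNEG_KINDS and np.any(W < 0):
            raise ValueError(f"negative entries not allowed for kind={self.kind!r}")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero (self-connections are excluded)")
        if self.kind == "count":
            if not np.array_equal(W, np.rint(W)):
                raise ValueError("kind='count' requires integer entries")
        if not self.directed and not np.array_equal(W, W.T):
            raise ValueError("undirected connectome must be symmetric")
        self.W = W

    @property
    def n(self) -> int:
        return self.regions.n

    def copy_with(self, **kwargs) -> "WeightedConnectome":
        params = dict(
            regions=self.regions, W=self.W.copy(), directed=self.directed,
            kind=self.kind, meta=dict(self.meta),
        )
        params.update(kwargs)
        return WeightedConnectome(**params)
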