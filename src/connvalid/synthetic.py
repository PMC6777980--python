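"""Simulator of paired tract-tracing / tractography experiments.

The generator emulates the statistical structure of inter-areal cortical
connectivity: lognormally distributed connection weights attenuated by
an exponential distance rule, observed twice --

* by retrograde tracing: for each injected region, a fixed number of
  labeled neurons is allocated multinomially across source regions in
  proportion to the true incoming weights;
* by tractography: a fixed streamline budget is allocated multinomially
  across unordered region pairs in proportion to the symmetrized true
  weight, attenuated by a distance-dependent dropout ``exp(-gamma * d)``
  and lifted by a false-positive floor ``epsilon`` (expressed relative
  to the mean true weight, so it is unit-free).

Defaults live in ``defaults.yaml`` and describe an eight-region,
million-streamline experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import yaml

from .core import RegionSet, WeightedConnectome

__all__ = [
    "SyntheticConfig",
    "generate_ground_truth",
    "sample_tracer",
    "sample_tractography",
    "simulate_experiment",
    "load_defaults",
]


def load_defaults() -> dict:
    """Package-level default parameters (simulator and analysis)."""
    text = resources.files("connvalid").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEF = load_defaults()["synthetic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated paired experiment.

    Distances are in mm; ``lambda_decay`` and ``gamma`` are per-mm rates.
    ``epsilon`` is the false-positive floor as a fraction of the mean
    true (symmetrized) weight.
    """

    n_regions: int = _DEF["n_regions"]
    edge_density: float = _DEF["edge_density"]
    reciprocity: float = _DEF["reciprocity"]
    mu: float = _DEF["mu"]
    sigma: float = _DEF["sigma"]
    lambda_decay: float = _DEF["lambda_decay"]
    box_size: float = _DEF["box_size"]
    tracer_neurons: int = _DEF["tracer_neurons"]
    streamlines: int = _DEF["streamlines"]
    gamma: float = _DEF["gamma"]
    epsilon: float = _DEF["epsilon"]
    allocation: str = _DEF["allocation"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must be in (0, 1]")
        if not (0.0 <= self.reciprocity <= 1.0):
            raise ValueError("reciprocity must be in [0, 1]")
        for name in ("lambda_decay", "gamma", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tracer_neurons < 1 or self.streamlines < 1:
            raise ValueError("tracer_neurons and streamlines must be positive")
        if self.allocation not in ("multinomial", "poisson"):
            raise ValueError("allocation must be 'multinomial' or 'poisson'")


def generate_ground_truth(
    cfg: SyntheticConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[RegionSet, WeightedConnectome]:
    """Draw centroids and a directed lognormal/distance-decay weight matrix.

    Each ordered pair (i, j) is connected with probability
    ``edge_density``; whenever (i, j) connects, its reciprocal is forced
    with probability ``reciprocity``.  Connected pairs get the true
    weight ``exp(N(mu, sigma^2)) * exp(-lambda * d_ij)``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_regions
    centroids = rng.uniform(0.0, cfg.box_size, size=(n, 3))
    regions = RegionSet(
        labels=tuple(f"R{k + 1}" for k in range(n)), centroids=centroids
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    adj = rng.random((n, n)) < cfg.edge_density
    np.fill_diagonal(adj, False)
    # force reciprocals: where (i,j) connects and the coin says so, connect (j,i)
    force = rng.random((n, n)) < cfg.reciprocity
    adj |= (adj & force).T
    logw = rng.normal(cfg.mu, cfg.sigma, size=(n, n))
    W = np.where(adj, np.exp(logw) * np.exp(-cfg.lambda_decay * d), 0.0)
    np.fill_diagonal(W, 0.0)
    truth = WeightedConnectome(
        regions=regions, W=W, directed=True, kind="weight",
        meta={"seed": cfg.seed if seed is None else None},
    )
    return regions, truth


def sample_tracer(
    truth: WeightedConnectome,
    M: int,
    seed: int | np.random.SeedSequence | None = None,
) -> WeightedConnectome:
    """Simulate retrograde tracer injections: M labeled neurons per site.

    For each injected (target) column j, counts across source regions
    are drawn from a multinomial with size ``M`` and probabilities
    proportional to the true incoming weights, so every column sums to
    exactly ``M`` and zero-weight pairs get zero counts.
    """
    if M < 1:
        raise ValueError("need at least one labeled neuron per injection")
    rng = np.random.default_rng(seed)
    n = truth.n
    counts = np.zeros((n, n))
    for j in range(n):
        w = truth.W[:, j]
        total = w.sum()
        if total == 0:
            raise ValueError(
                f"region {truth.regions.labels[j]!r} has no incoming connections; "
                "its injection cannot label any neurons"
            )
        counts[:, j] = rng.multinomial(M, w / total)
    return WeightedConnectome(
        regions=truth.regions, W=counts, directed=True, kind="count",
    )


def sample_tractography(
    truth: WeightedConnectome,
    cfg: SyntheticConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> WeightedConnectome:
    """Simulate a streamline experiment with a fixed streamline budget.

    The streamline intensity of an unordered pair is
    ``q_ij = wbar_ij * exp(-gamma * d_ij) + epsilon * mean(wbar)`` where
    ``wbar`` is the symmetrized true weight and the mean runs over
    connected pairs.  ``streamlines`` counts are allocated multinomially
    over unordered pairs (or independently Poisson with matching means
    when ``allocation='poisson'``).
    """
    rng = np.random.default_rng(seed)
    n = truth.n
    c = truth.regions.centroids
    diff = c[:, None, :] - c[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    wbar = (truth.W + truth.W.T) / 2.0
    ii, jj = np.triu_indices(n, k=1)
    w_pairs = wbar[ii, jj]
    connected = w_pairs > 0
    floor = cfg.epsilon * (w_pairs[connected].mean() if connected.any() else 0.0)
    q = w_pairs * np.exp(-cfg.gamma * d[ii, jj]) + floor
    if q.sum() == 0:
        raise ValueError("all streamline intensities are zero; nothing to track")
    if cfg.allocation == "multinomial":
        counts = rng.multinomial(cfg.streamlines, q / q.sum())
    else:
        counts = rng.poisson(cfg.streamlines * q / q.sum())
    S = np.zeros((n, n))
    S[ii, jj] = counts
    S[jj, ii] = counts
    return WeightedConnectome(
        regions=truth.regions, W=S, directed=False, kind="count",
    )


def simulate_experiment(
    cfg: SyntheticConfig, seed: int | np.random.SeedSequence | None = None
) -> dict:
    """Generate truth and both observation processes with one seed.

    Sub-stage seeds are fanned out deterministically from the top-level
    seed via ``SeedSequence.spawn``.
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_truth, s_tracer, s_tract = ss.spawn(3)
    regions, truth = generate_ground_truth(cfg, seed=s_truth)
    tracer = sample_tracer(truth, cfg.tracer_neurons, seed=s_tracer)
    tract = sample_tractography(truth, cfg, seed=s_tract)
    return {
        "config": asdict(cfg),
        "regions": regions,
        "truth": truth,
        "tracer_counts": tracer,
        "tract_counts": tract,
    }
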