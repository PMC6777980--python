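"""Edge tables, rank/log correlations, bootstrap CIs, distance partialing."""

import numpy as np
import pytest

from connvalid import (
    EdgeTable,
    bootstrap_ci,
    build_edge_table,
    compute_fln,
    fractional_scaling,
    partial_spearman_distance,
    pearson_log,
    spearman,
    symmetrize,
)
from connvalid.io import euclidean_distances

from conftest import make_counts


def table_from(x, y, dist=None):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return EdgeTable(i=np.zeros(n, dtype=int), j=np.arange(1, n + 1),
                     x=x, y=np.asarray(y, dtype=float),
                     dist=None if dist is None else np.asarray(dist, dtype=float))


def brute_force_midranks(v):
    """Midrank computation from the definition, element by element."""
    v = np.asarray(v, dtype=float)
    ranks = np.empty(len(v))
    for k, val in enumerate(v):
        below = np.sum(v < val)
        ties = np.sum(v == val)
        ranks[k] = below + (ties + 1) / 2.0
    return ranks


class TestEdgeTable:
    def test_symmetric_mode_edge_count(self, rng):
        tracing = symmetrize(compute_fln(make_counts(8, rng)))
        tract = fractional_scaling(make_counts(8, rng, symmetric=True))
        tract = tract.copy_with(regions=tracing.regions)
        table = build_edge_table(tracing, tract, mode="symmetric")
        assert table.n_edges == 28

    def test_directed_mode_edge_count(self, rng):
        tracing = compute_fln(make_counts(8, rng))
        tract = fractional_scaling(make_counts(8, rng, symmetric=True))
        tract = tract.copy_with(regions=tracing.regions)
        table = build_edge_table(tracing, tract, mode="directed")
        assert table.n_edges == 56

    def test_region_mismatch_rejected(self, rng):
        tracing = symmetrize(compute_fln(make_counts(8, rng)))
        tract = fractional_scaling(make_counts(8, rng, symmetric=True))
        with pytest.raises(ValueError, match="regions"):
            build_edge_table(tracing, tract, mode="symmetric")

    def test_permutation_equivariance(self, rng):
        """Reordering regions leaves the multiset of (x, y) pairs unchanged."""
        tracing = symmetrize(compute_fln(make_counts(8, rng)))
        tract = fractional_scaling(
            make_counts(8, rng, symmetric=True)).copy_with(regions=tracing.regions)
        table = build_edge_table(tracing, tract, mode="symmetric")
        perm = rng.permutation(8)
        regions_p = type(tracing.regions)(
            labels=tuple(tracing.regions.labels[k] for k in perm),
            centroids=tracing.regions.centroids[perm],
        )
        tracing_p = tracing.copy_with(regions=regions_p, W=tracing.W[np.ix_(perm, perm)])
        tract_p = tract.copy_with(regions=regions_p, W=tract.W[np.ix_(perm, perm)])
        table_p = build_edge_table(tracing_p, tract_p, mode="symmetric")
        pairs = sorted(zip(table.x, table.y))
        pairs_p = sorted(zip(table_p.x, table_p.y))
        assert pairs == pairs_p


class TestSpearman:
    def test_perfect_monotone(self):
        t = table_from([1, 2, 3, 4], [10, 20, 40, 80])
        assert spearman(t).coefficient == pytest.approx(1.0)

    def test_perfect_antitone(self):
        t = table_from([1, 2, 3, 4], [8, 4, 2, 1])
        assert spearman(t).coefficient == pytest.approx(-1.0)

    def test_midrank_ties_oracle(self):
        # zeros tie at the minimal rank; identical rank vectors give rho = 1
        t = table_from([0, 0, 1, 2], [0, 0, 2, 3])
        assert spearman(t).coefficient == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_midrank_pearson(self, rng):
        x = rng.integers(0, 5, size=28).astype(float)
        y = rng.integers(0, 5, size=28).astype(float)
        t = table_from(x, y)
        rx, ry = brute_force_midranks(x), brute_force_midranks(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert spearman(t).coefficient == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(table_from([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        base = spearman(table_from(x, y)).coefficient
        warped = spearman(table_from(np.exp(5 * x), y ** 3)).coefficient
        assert warped == pytest.approx(base, abs=1e-12)


class TestPearsonLog:
    def test_identity(self):
        x = np.array([0.1, 0.5, 1.2, 3.0])
        assert pearson_log(table_from(x, x)).coefficient == pytest.approx(1.0)

    def test_affine_antitone(self):
        x = np.array([0.1, 0.5, 1.2, 3.0])
        assert pearson_log(table_from(x, 2 - 3 * x)).coefficient == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r = pearson_log(table_from(x, y)).coefficient
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(expect, abs=1e-12)


class TestBootstrap:
    def test_perfectly_monotone_ci_is_degenerate(self):
        t = table_from(np.arange(10.0), np.arange(10.0) ** 2)
        res = bootstrap_ci(t, "spearman", n_boot=200, seed=0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_same_seed_reproducible(self, rng):
        t = table_from(rng.random(28), rng.random(28))
        a = bootstrap_ci(t, "spearman", n_boot=500, seed=42)
        b = bootstrap_ci(t, "spearman", n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_level_validation(self, rng):
        t = table_from(rng.random(10), rng.random(10))
        with pytest.raises(ValueError, match="level"):
            bootstrap_ci(t, "spearman", n_boot=200, level=1.5, seed=0)

    def test_ci_brackets_point_estimate(self, rng):
        t = table_from(rng.random(28), rng.random(28))
        res = bootstrap_ci(t, "pearson_log", n_boot=500, seed=3)
        assert res.ci_low <= res.coefficient <= res.ci_high

    def test_ci_width_shrinks_with_more_edges(self):
        """Expected interval width decreases as the table grows."""
        widths = []
        for n in (15, 60, 240):
            ws = []
            for s in range(20):
                rng = np.random.default_rng(1000 + s)
                z = rng.normal(size=n)
                x = z + rng.normal(size=n)
                y = z + rng.normal(size=n)
                res = bootstrap_ci(table_from(x, y), "spearman", n_boot=300, seed=s)
                ws.append(res.ci_high - res.ci_low)
            widths.append(np.mean(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_region_unit_runs(self, rng):
        tracing = symmetrize(compute_fln(make_counts(8, rng)))
        tract = fractional_scaling(
            make_counts(8, rng, symmetric=True)).copy_with(regions=tracing.regions)
        t = build_edge_table(tracing, tract, mode="symmetric")
        res = bootstrap_ci(t, "spearman", n_boot=100, seed=5, unit="region")
        assert res.ci_low <= res.coefficient <= res.ci_high


class TestPartialSpearman:
    def test_constant_distance_equals_plain_spearman(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        t = table_from(x, y, dist=np.full(20, 7.0))
        plain = spearman(table_from(x, y)).coefficient
        assert partial_spearman_distance(t).coefficient == pytest.approx(plain, abs=1e-12)

    def test_hand_solved_normal_equations(self):
        """4-edge OLS residuals from the normal equations, solved by hand."""
        d = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([2.0, 3.0, 5.0, 4.0])
        # slope = cov(d,x)/var(d) = 0.8, intercept = 3.5 - 0.8*2.5 = 1.5
        resid_expect = x - (1.5 + 0.8 * d)
        from connvalid.association import _ols_residuals

        np.testing.assert_allclose(_ols_residuals(x, d), resid_expect, atol=1e-10)

    def test_distance_explains_shared_signal(self):
        """When both modalities are exponential in distance and only
        independent noise remains, the partial coefficient is near zero."""
        rhos = []
        for s in range(100):
            rng = np.random.default_rng(s)
            d = rng.uniform(1, 30, size=56)
            x = -0.3 * d + 1.0  # log-weights, exactly linear in distance
            y = -0.3 * d + rng.normal(scale=0.5, size=56)
            res = partial_spearman_distance(table_from(x + rng.normal(scale=0.5, size=56), y, dist=d))
            rhos.append(res.coefficient)
        assert abs(np.mean(rhos)) < 0.2

    def test_requires_distances(self, rng):
        t = table_from(rng.random(10), rng.random(10))
        with pytest.raises(ValueError, match="distance"):
            partial_spearman_distance(t)
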