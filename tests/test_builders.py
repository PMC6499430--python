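import numpy as np
import pytest

from connsync import (VariantSpec, add_top_residual_fraction,
                      build_power_law_network, build_variant,
                      compute_residuals, fit_distance_model, predict_baseline,
                      relocate_longest_fraction, relocate_residuals_window,
                      shuffle_residuals, LONGEST_EDGE_CUTOFFS_UM)
from connsync.distance_model import ResidualField


def _field(residuals):
    residuals = np.asarray(residuals, dtype=float)
    return ResidualField(residuals, residuals > 0, {})


@pytest.fixture
def setting(default_synth):
    conn, _ = default_synth
    fit = fit_distance_model(conn)
    res = compute_residuals(conn, fit)
    K = build_power_law_network(predict_baseline(fit, conn.distances))
    return conn, K, res


class TestPowerLawNetwork:
    def test_equals_predicted_baseline_with_zero_diagonal(self, setting):
        conn, K, _ = setting
        fit = fit_distance_model(conn)
        assert np.allclose(K, predict_baseline(fit, conn.distances))
        assert np.all(np.diag(K) == 0)

    def test_weaker_than_data_when_net_residual_mass_positive(self, setting):
        conn, K, res = setting
        assert res.residuals.sum() > 0
        assert K.sum() < conn.weights.sum()


class TestTopResidualFraction:
    def test_full_restoration_of_all_positive_residuals(self):
        K = np.zeros((3, 3))
        eps = np.array([[0, 0.2, 0.1], [0.05, 0, 0.3], [0.15, 0.25, 0]])
        out = add_top_residual_fraction(K, _field(eps), 1.0)
        assert np.allclose(out, eps)

    def test_full_restoration_reproduces_data_network(self, setting):
        # where residuals are negative the baseline is kept as-is, so the
        # restored network dominates the data network and matches it on
        # every positive-residual edge
        conn, K, res = setting
        out = add_top_residual_fraction(K, res, 1.0)
        pos = res.positive_mask
        assert np.allclose(out[pos], conn.weights[pos], atol=1e-12)
        assert np.all(out >= conn.weights - 1e-12)

    def test_counting_oracle_fraction_selects_exact_count(self):
        K = np.zeros((4, 4))
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        eps = np.zeros((4, 4))
        eps[~np.eye(4, dtype=bool)] = np.array(vals + [0.0, 0.0])
        out = add_top_residual_fraction(K, _field(eps), 0.2)
        assert (out > 0).sum() == 2  # top 2 of 10 positive residuals
        assert out.sum() == pytest.approx(0.9 + 1.0)

    def test_smallest_fraction_changes_single_edge(self, setting):
        _, K, res = setting
        n_pos = int(res.positive_mask.sum())
        out = add_top_residual_fraction(K, res, 1.0 / n_pos)
        assert (out != K).sum() == 1

    def test_invalid_fraction_rejected(self, setting):
        _, K, res = setting
        for p in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError, match="fraction"):
                add_top_residual_fraction(K, res, p)


class TestShuffledResiduals:
    def test_mass_conserved_exactly(self, setting):
        _, K, res = setting
        out = shuffle_residuals(K, res, seed=1)
        assert out.sum() == pytest.approx(K.sum() + res.positive_mass(),
                                          rel=1e-12)

    def test_deterministic_given_seed(self, setting):
        _, K, res = setting
        assert np.array_equal(shuffle_residuals(K, res, seed=9),
                              shuffle_residuals(K, res, seed=9))
        assert not np.array_equal(shuffle_residuals(K, res, seed=9),
                                  shuffle_residuals(K, res, seed=10))

    def test_destination_edges_uniform_over_offdiagonal(self):
        # one residual value shuffled on a 10-node graph: each of the 90
        # off-diagonal edges should be hit ~uniformly over many shuffles
        K = np.zeros((10, 10))
        eps = np.zeros((10, 10))
        eps[0, 1] = 0.7
        field = _field(eps)
        counts = np.zeros((10, 10))
        n_shuffles = 1000
        for s in range(n_shuffles):
            out = shuffle_residuals(K, field, seed=s)
            counts[out > 0] += 1
        off = ~np.eye(10, dtype=bool)
        p = 1.0 / 90.0
        se = np.sqrt(p * (1 - p) / n_shuffles)
        freqs = counts[off] / n_shuffles
        assert np.all(np.abs(freqs - p) <= 3 * se + 1e-12)

    def test_too_many_residuals_rejected(self):
        K = np.zeros((2, 2))
        eps = np.array([[0.0, 0.1], [0.2, 0.0]])
        field = _field(eps)
        field.residuals = np.ones((2, 2)) * 0.1  # 4 values incl. diagonal
        field.positive_mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="off-diagonal"):
            shuffle_residuals(K, field, seed=0)


class TestRelocationWindow:
    def test_equal_split_within_window(self):
        K = np.zeros((3, 3))
        d = np.array([[0, 100.0, 300], [100, 0, 500], [300, 500, 0]])
        eps = np.zeros((3, 3))
        eps[0, 1] = 0.6
        out = relocate_residuals_window(K, _field(eps), d, (50.0, 350.0))
        # edges with d in [50, 350): (0,1),(1,0),(0,2),(2,0) -> 0.15 each
        assert out[0, 1] == pytest.approx(0.15)
        assert out[2, 0] == pytest.approx(0.15)
        assert out[1, 2] == 0.0
        assert out.sum() == pytest.approx(0.6)

    def test_full_range_window_spreads_everywhere(self, setting):
        conn, K, res = setting
        out = relocate_residuals_window(K, res, conn.distances, (0.0, np.inf))
        off = ~np.eye(conn.n_regions, dtype=bool)
        incr = out - K
        assert np.allclose(incr[off], incr[off][0])
        assert out.sum() == pytest.approx(K.sum() + res.positive_mass(),
                                          rel=1e-12)

    def test_proximal_window_touches_only_short_edges(self, setting):
        conn, K, res = setting
        d = conn.distances
        off = ~np.eye(conn.n_regions, dtype=bool)
        cut = float(np.quantile(d[off], 0.002))
        out = relocate_residuals_window(K, res, d, (0.0, cut))
        changed = (out != K) & off
        assert changed.any()
        assert np.all(d[changed] < cut)

    def test_empty_window_names_the_window(self, setting):
        conn, K, res = setting
        with pytest.raises(ValueError, match="1.0, 2.0"):
            relocate_residuals_window(K, res, conn.distances, (1.0, 2.0))


class TestRelocateLongest:
    def test_cutoff_near_max_modifies_single_longest_edge_pair(self, setting):
        conn, K, res = setting
        d = conn.distances
        off = ~np.eye(conn.n_regions, dtype=bool)
        dmax = d[off].max()
        out = relocate_longest_fraction(K, res, d, dmax - 1e-9)
        changed = (out != K) & off
        # the longest separation is shared by one node pair (two directed
        # edges)
        assert changed.sum() == 2
        assert np.all(d[changed] >= dmax - 1e-9)

    def test_modified_edge_count_grows_as_cutoff_decreases(self, setting):
        conn, K, res = setting
        d = conn.distances
        off = ~np.eye(conn.n_regions, dtype=bool)
        lo, hi = d[off].min(), d[off].max()
        # map the published whole-brain cutoffs onto this network's range
        cutoffs = [lo + (c - 2147.0) / (9404.0 - 2147.0) * (hi - lo) * 0.6
                   for c in LONGEST_EDGE_CUTOFFS_UM]
        counts = []
        for c in cutoffs:  # cutoffs are listed in decreasing order
            out = relocate_longest_fraction(K, res, d, c)
            counts.append(int(((out != K) & off).sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]

    def test_mass_conserved_for_every_published_cutoff(self, setting):
        conn, K, res = setting
        d = conn.distances
        off = ~np.eye(conn.n_regions, dtype=bool)
        total = K.sum() + res.positive_mass()
        lo, hi = d[off].min(), d[off].max()
        for c in np.linspace(lo, hi * 0.95, 10):
            out = relocate_longest_fraction(K, res, d, c)
            assert out.sum() == pytest.approx(total, rel=1e-12)

    def test_cutoff_outside_range_rejected(self, setting):
        conn, K, res = setting
        with pytest.raises(ValueError, match="outside"):
            relocate_longest_fraction(K, res, conn.distances, 1e9)


class TestVariantSpecDispatch:
    def test_all_kinds_dispatch(self, setting):
        conn, K, res = setting
        d = conn.distances
        off = ~np.eye(conn.n_regions, dtype=bool)
        specs = [
            VariantSpec("power_law_only"),
            VariantSpec("top_residual_fraction", fraction_or_percentile=0.2),
            VariantSpec("shuffled_residuals", seed=3),
            VariantSpec("relocate_window",
                        distance_window=(0.0, float(np.median(d[off])))),
            VariantSpec("relocate_longest_fraction",
                        cutoff_length=float(np.median(d[off]))),
        ]
        for spec in specs:
            out = build_variant(spec, K, res, d)
            assert out.shape == K.shape
            assert np.all(out >= 0)
            assert np.all(np.diag(out) == 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            VariantSpec("rewired")
        with pytest.raises(ValueError, match="fraction"):
            VariantSpec("top_residual_fraction", fraction_or_percentile=1.5)
        with pytest.raises(ValueError, match="window"):
            VariantSpec("relocate_window", distance_window=(5.0, 1.0))
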