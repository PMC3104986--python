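"""Unit and property tests for the change-point scan."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from npcps.changepoint import (
    GeneSequence,
    NpcpsResult,
    ReferenceDistribution,
    TestConfig,
    detect_matrix,
    empirical_cdf,
    empirical_quantile,
    npcps_profile,
    npcps_scan,
    scan_matrix,
    true_change_fraction,
)


def brute_force_scan(normal, cancer, grid_size, min_tail=2):
    """Exhaustive enumeration of every (r, y_j) pair — the oracle.

    Uses only the two elementary ECDF operations and plain Python loops,
    independent of the vectorized scan.
    """
    z = list(normal) + list(cancer)
    n = len(z)
    grid = [j / (grid_size + 1) for j in range(1, grid_size + 1)]
    best = None
    for r in range(1, n - min_tail + 1):
        tail = z[r:]
        m = len(tail)
        dev = None
        for y in grid:
            q = empirical_quantile(normal, y)
            d = empirical_cdf(tail, q) - y
            if dev is None or abs(d) > abs(dev):
                dev = d
        d_r = math.sqrt(m) * dev
        if best is None or abs(d_r) > abs(best[0]):
            best = (d_r, r)
    return best


class TestEmpiricalCdf:
    @pytest.mark.parametrize(
        "values,x,expected",
        [
            ([1, 2, 3], 3, 1.0),
            ([1, 2, 3], 0.5, 0.0),
            ([1, 2, 2, 5], 2, 0.75),  # ties counted with the weak inequality
            ([1, 2, 2, 5], 1.99, 0.25),
        ],
    )
    def test_step_function_values(self, values, x, expected):
        assert empirical_cdf(values, x) == expected

    def test_vectorized_and_unsorted_input(self):
        out = empirical_cdf([3, 1, 2], np.array([0.0, 1.5, 10.0]))
        assert np.array_equal(out, [0.0, 1 / 3, 1.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_cdf([], 1.0)


class TestEmpiricalQuantile:
    @pytest.mark.parametrize(
        "values,y,expected",
        [
            ([1, 2, 3, 4], 0.5, 2),
            ([1, 2, 3, 4], 0.51, 3),  # F(2)=0.5 < 0.51 so the next value
            ([7], 0.99, 7),
            ([1, 2, 3, 4], 0.25, 1),
        ],
    )
    def test_left_continuous_inverse(self, values, y, expected):
        assert empirical_quantile(values, y) == expected

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.2, 1.5])
    def test_probability_domain_enforced(self, y):
        with pytest.raises(ValueError, match="strictly inside"):
            empirical_quantile([1, 2, 3], y)

    @given(
        values=hnp.arrays(
            float,
            st.integers(1, 30),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        ),
        y=st.floats(0.001, 0.999),
    )
    def test_galois_connection_with_cdf(self, values, y):
        """F(F^-1(y)) >= y, and F^-1 returns an actual sample value."""
        q = empirical_quantile(values, y)
        assert empirical_cdf(values, q) >= y
        assert q in np.asarray(values, dtype=float)


class TestReferenceDistribution:
    def test_grid_and_quantile_invariants(self, rng):
        ref = ReferenceDistribution.from_sample(rng.standard_normal(25), 100)
        assert ref.grid_size == 100
        assert np.all(np.diff(ref.grid) > 0)
        assert 0 < ref.grid[0] and ref.grid[-1] < 1
        assert np.all(np.diff(ref.quantiles) >= 0)
        assert np.all(ref.cdf(ref.quantiles) >= ref.grid)

    def test_constant_reference_warns(self):
        with pytest.warns(RuntimeWarning, match="point mass"):
            ReferenceDistribution.from_sample([2.0, 2.0, 2.0])


class TestConfigAndTypes:
    def test_default_critical_values(self):
        assert TestConfig(alpha=0.05).critical == 1.358
        assert TestConfig(alpha=0.01).critical == 1.628

    def test_unknown_alpha_needs_explicit_critical(self):
        with pytest.raises(ValueError, match="critical"):
            TestConfig(alpha=0.2)
        assert TestConfig(alpha=0.2, critical=1.0).critical == 1.0

    @pytest.mark.parametrize(
        "kwargs", [dict(alpha=0.0), dict(alpha=1.5), dict(critical=-1.0),
                   dict(grid_size=5), dict(min_tail=0)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TestConfig(**kwargs)

    @pytest.mark.parametrize(
        "normal,cancer",
        [([1.0], [1.0, 2.0]), ([1.0, 2.0], [3.0]), ([1.0, np.nan], [1.0, 2.0])],
    )
    def test_degenerate_sequences_rejected(self, normal, cancer):
        with pytest.raises(ValueError):
            GeneSequence(normal, cancer)


class TestTrueChangeFraction:
    def test_reproduces_actual_change_point_row(self):
        # (50-k)/50 for the whole published grid of DGE subset sizes
        expected = {1: 0.98, 3: 0.94, 5: 0.90, 7: 0.86, 9: 0.82,
                    12: 0.76, 15: 0.70, 20: 0.60, 25: 0.50}
        for k, frac in expected.items():
            assert true_change_fraction(25, 25, k) == pytest.approx(frac)

    @pytest.mark.parametrize("k", [0, 26, 50, -3])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            true_change_fraction(25, 25, k)


class TestScan:
    def test_identical_groups_stay_within_grid_discretization(self, rng):
        """With the cancer block an exact copy of the normal block, the
        deviation at the group boundary is pure grid discretization: the
        ECDF at its own quantiles satisfies F(F^-1(y)) in [y, y + 1/m), so
        0 <= D(n1) < 1/sqrt(m), and the test does not reject."""
        x = rng.standard_normal(10)
        seq = GeneSequence(x, x.copy())
        rs, D = npcps_profile(seq, TestConfig(grid_size=20))
        boundary = float(D[rs == 10][0])
        assert 0.0 <= boundary < 1.0 / math.sqrt(10)
        res = npcps_scan(seq, TestConfig(grid_size=20))
        assert not res.reject  # at the default critical value

    def test_overexpressed_gene_is_negative_and_matches_oracle(self):
        seq = GeneSequence([1, 2, 3, 4, 5], [2, 3, 100, 101])
        cfg = TestConfig(grid_size=20)
        res = npcps_scan(seq, cfg)
        assert res.statistic < 0
        d, r = brute_force_scan(seq.normal, seq.cancer, 20)
        assert res.statistic == d
        assert res.changepoint == r
        # at a permissive critical value the sign is reported as direction
        lenient = npcps_scan(seq, TestConfig(alpha=0.3, critical=0.5))
        assert lenient.reject and lenient.direction == "over"

    @pytest.mark.parametrize("seed", range(8))
    def test_scan_equals_exhaustive_enumeration(self, seed):
        """The optimized scan must reproduce the brute-force (r, y) loop
        exactly, including on tied (integer-valued) data."""
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(3, 12))
        n2 = int(rng.integers(2, 9))
        grid_size = int(rng.integers(10, 26))
        if seed % 2:
            x = rng.integers(0, 5, n1).astype(float)  # forces ties
            y = rng.integers(0, 7, n2).astype(float)
        else:
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.normal()
        res = npcps_scan(GeneSequence(x, y), TestConfig(grid_size=grid_size))
        d, r = brute_force_scan(x, y, grid_size)
        assert res.statistic == d
        assert res.changepoint == r
        assert res.tau_hat == r / (n1 + n2)

    def test_result_invariants(self, rng):
        cfg = TestConfig(alpha=0.05)
        for _ in range(20):
            seq = GeneSequence(rng.standard_normal(12),
                               rng.standard_normal(8) + rng.normal())
            res = npcps_scan(seq, cfg)
            assert 1 <= res.changepoint <= seq.n - 2
            assert res.tau_hat == res.changepoint / seq.n
            assert res.reject == (abs(res.statistic) > cfg.critical)
            if res.reject:
                assert res.direction == ("over" if res.statistic < 0 else "under")
            else:
                assert res.direction == "none"

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: 3.0 * v + 7.0,
                      lambda v: v ** 3, np.arctan],
        ids=["exp", "affine", "cube", "arctan"],
    )
    def test_strictly_increasing_transform_invariance(self, rng, transform):
        """The statistic depends only on relative order, so any strictly
        increasing transform leaves D_n, r* and tau_hat exactly unchanged."""
        cfg = TestConfig(grid_size=50)
        for _ in range(10):
            x = rng.standard_normal(15)
            y = rng.standard_normal(10) + rng.normal()
            a = npcps_scan(GeneSequence(x, y), cfg)
            b = npcps_scan(GeneSequence(transform(x), transform(y)), cfg)
            assert (a.statistic, a.changepoint) == (b.statistic, b.changepoint)

    def test_antisymmetry_of_magnitudes_in_cancer_block(self, rng):
        """Negating continuous data mirrors |D(r)| (to round-off) for
        candidate change points inside the cancer block, where the tail is
        disjoint from the reference sample.  Candidates reaching into the
        normal block carry reference-atom corrections under the weak
        inequality, and the attained sign can differ when two grid points
        tie in magnitude, so the exact statement is about |D(r)| on
        r >= n1."""
        cfg = TestConfig(grid_size=100)
        for _ in range(10):
            x = rng.standard_normal(15)
            y = rng.standard_normal(10) + rng.normal()
            rs, D = npcps_profile(GeneSequence(x, y), cfg)
            _, D2 = npcps_profile(GeneSequence(-x, -y), cfg)
            inside = rs >= 15
            np.testing.assert_allclose(
                np.abs(D2[inside]), np.abs(D[inside]), rtol=0, atol=1e-12
            )


class TestDetectMatrix:
    @staticmethod
    def _fake_matrix(rng, g=12, n1=10, n2=8):
        class M:
            genes = np.array([f"g{i:02d}" for i in range(g)], dtype=object)
            normal_values = rng.standard_normal((g, n1))
            cancer_values = rng.standard_normal((g, n2))
        return M()

    def test_rows_equal_per_gene_scan(self, rng):
        mat = self._fake_matrix(rng)
        cfg = TestConfig(alpha=0.05, grid_size=40)
        table, summary = detect_matrix(mat, cfg)
        assert summary["n_scanned"] == 12
        for _, row in table.iterrows():
            i = int(row.gene_id[1:])
            res = npcps_scan(
                GeneSequence(mat.normal_values[i], mat.cancer_values[i]), cfg
            )
            assert row.d_n == res.statistic
            assert row.cp_index == res.changepoint
            assert row.direction == res.direction

    def test_dominant_effect_ranks_first_by_magnitude(self, rng):
        mat = self._fake_matrix(rng)
        mat.cancer_values[5] += 10.0  # shift every cancer sample of one gene
        table, _ = detect_matrix(mat, TestConfig(alpha=0.01))
        top = table.loc[table.d_n.abs().idxmax()]
        assert top.gene_id == "g05"
        assert top.direction == "over"
        assert table.iloc[-1].gene_id == "g05"  # most negative d_n ranks last

    def test_missing_values_skipped_with_warning(self, rng):
        mat = self._fake_matrix(rng)
        mat.normal_values[3, 0] = np.nan
        with pytest.warns(RuntimeWarning, match="g03"):
            table, summary = detect_matrix(mat, TestConfig())
        assert summary["n_skipped"] == 1
        assert "g03" not in set(table.gene_id)
        assert summary["n_scanned"] == len(table) == 11

    def test_ranking_is_descending_with_id_tiebreak(self, rng):
        mat = self._fake_matrix(rng)
        table, _ = detect_matrix(mat, TestConfig())
        assert np.all(np.diff(table.d_n.to_numpy()) <= 0)
        assert list(table["rank"]) == list(range(1, len(table) + 1))

    def test_scan_matrix_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="same number of genes"):
            scan_matrix(rng.standard_normal((3, 10)), rng.standard_normal((4, 8)))
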