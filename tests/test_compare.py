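import itertools
import math

import numpy as np
import pytest

from seqsector import (
    ContingencyTable,
    MutationalDataset,
    call_functional_sites,
    chi2_compare_tables,
    contingency,
    fisher_one_tailed,
    mannwhitney_effects,
    regress_phenotypes_on_eigenvectors,
    sweep_sector_size,
)
from seqsector.compare import ComparisonError
from seqsector.conservation import ConservationProfile
from seqsector.sca import SpectralResult
from _oracles import enumerate_fisher_tail, enumerate_mannwhitney


@pytest.fixture
def laci_style_data():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 13, size=40)
    return MutationalDataset(
        position=np.arange(1, 41),
        effect=counts.astype(float),
        counts=np.column_stack([counts, np.full(40, 13)]),
    )


class TestCallFunctionalSites:
    def test_count_threshold(self, laci_style_data):
        out = call_functional_sites(laci_style_data, "count_threshold", 8)
        assert out.rule == {"rule": "count_threshold", "threshold": 8}
        np.testing.assert_array_equal(
            out.functional, laci_style_data.counts[:, 0] >= 8
        )

    def test_effect_threshold_boundary(self):
        data = MutationalDataset(
            position=np.array([1, 2]), effect=np.array([0.99, -1.0])
        )
        out = call_functional_sites(data, "effect_threshold", 1.0)
        assert list(out.functional) == [False, True]

    def test_raising_threshold_is_monotone(self, laci_style_data):
        prev = None
        for t in range(1, 11):
            cur = set(
                call_functional_sites(laci_style_data, "count_threshold", t)
                .position[
                    call_functional_sites(
                        laci_style_data, "count_threshold", t
                    ).functional
                ]
            )
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_unknown_rule(self, laci_style_data):
        with pytest.raises(ComparisonError):
            call_functional_sites(laci_style_data, "nope", 1)


class TestContingency:
    def _pdz_like_data(self):
        """80 scored positions, 20 functional; a 21-position set holding
        14 of them."""
        functional = np.zeros(80, dtype=bool)
        functional[:20] = True
        return MutationalDataset(
            position=np.arange(1, 81),
            effect=np.zeros(80),
            functional=functional,
        )

    def test_published_style_table(self):
        data = self._pdz_like_data()
        set_a = list(range(1, 15)) + list(range(21, 28))  # 14 func + 7 not
        table = contingency(set_a, data)
        np.testing.assert_array_equal(table.counts, [[14, 7], [6, 53]])

    def test_empty_set(self):
        table = contingency([], self._pdz_like_data())
        np.testing.assert_array_equal(table.counts[0], [0, 0])

    def test_full_universe_set(self):
        data = self._pdz_like_data()
        table = contingency(list(range(1, 81)), data)
        np.testing.assert_array_equal(table.counts[1], [0, 0])
        assert table.total == 80

    def test_unscored_position_errors(self):
        with pytest.raises(ComparisonError):
            contingency([999], self._pdz_like_data())


class TestFisher:
    def test_pdz_printed_table(self):
        table = ContingencyTable(counts=[[14, 7], [6, 53]])
        p = fisher_one_tailed(table)
        assert p == pytest.approx(1.5615e-6, rel=1e-3)

    def test_balanced_small_table(self):
        # enumeration of the hypergeometric support M=4, K=2, n=2
        assert fisher_one_tailed(
            ContingencyTable(counts=[[1, 1], [1, 1]])
        ) == pytest.approx(5 / 6)

    def test_zero_observed_is_one(self):
        table = ContingencyTable(counts=[[0, 5], [7, 9]])
        assert fisher_one_tailed(table) == pytest.approx(1.0)

    def test_degenerate_margins(self):
        assert fisher_one_tailed(ContingencyTable(counts=[[0, 0], [3, 4]])) == 1.0
        assert fisher_one_tailed(ContingencyTable(counts=[[0, 3], [0, 4]])) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_enumeration_oracle_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 8, size=(2, 2))
        counts[0, 0] = max(counts[0, 0], 1)
        table = ContingencyTable(counts=counts)
        if counts.sum() > 30:
            pytest.skip("outside enumerated range")
        expected = enumerate_fisher_tail(table.counts.tolist())
        if table.counts[:, 0].sum() in (0, table.total) or \
           table.counts[0].sum() in (0, table.total):
            return  # degenerate margin handled separately
        assert fisher_one_tailed(table) == pytest.approx(expected, rel=1e-10)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            table = ContingencyTable(counts=rng.integers(1, 30, size=(2, 2)))
            p = fisher_one_tailed(table)
            assert 0 < p <= 1


class TestChi2:
    def test_identical_tables_give_one(self):
        t = ContingencyTable(counts=[[14, 7], [6, 53]])
        assert chi2_compare_tables(t, t) == 1.0

    def test_identical_in_set_rows(self):
        a = ContingencyTable(counts=[[14, 7], [6, 53]])
        b = ContingencyTable(counts=[[14, 7], [9, 50]])
        assert chi2_compare_tables(a, b) == 1.0

    def test_maximally_different_rows(self):
        # hand evaluation: all four expected cells equal 10, statistic 40
        a = ContingencyTable(counts=[[20, 0], [0, 0]])
        b = ContingencyTable(counts=[[0, 20], [0, 0]])
        p = chi2_compare_tables(a, b)
        assert p < 1e-9

    def test_zero_expected_cell_is_missing(self):
        a = ContingencyTable(counts=[[0, 5], [1, 1]])
        b = ContingencyTable(counts=[[0, 7], [1, 1]])
        assert math.isnan(chi2_compare_tables(a, b))

    def test_yates_option_is_more_conservative(self):
        a = ContingencyTable(counts=[[12, 9], [6, 53]])
        b = ContingencyTable(counts=[[16, 5], [6, 53]])
        assert chi2_compare_tables(a, b, yates=True) > chi2_compare_tables(a, b)


class TestMannWhitney:
    def _data(self, effects):
        return MutationalDataset(
            position=np.arange(1, len(effects) + 1),
            effect=np.asarray(effects, float),
        )

    def test_separated_samples_exact(self):
        data = self._data([1, 2, 3, 10, 11, 12])
        p = mannwhitney_effects(data, [1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_sets_give_one(self):
        data = self._data([5, 1, 3, 2])
        assert mannwhitney_effects(data, [1, 2, 3], [1, 2, 3]) == 1.0

    def test_monotone_transform_invariance(self):
        data1 = self._data([1, 4, 2, 9, 7, 6, 3, 8])
        data2 = self._data(np.exp([1, 4, 2, 9, 7, 6, 3, 8]))
        a, b = [1, 3, 5, 7], [2, 4, 6, 8]
        assert mannwhitney_effects(data1, a, b) == pytest.approx(
            mannwhitney_effects(data2, a, b)
        )

    def test_empty_set_errors(self):
        with pytest.raises(ComparisonError):
            mannwhitney_effects(self._data([1, 2]), [], [1])

    @pytest.mark.parametrize("seed", range(10))
    def test_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 7), rng.integers(2, 7)
        effects = rng.permutation(np.arange(1.0, nx + ny + 1))
        data = self._data(effects)
        a = list(range(1, nx + 1))
        b = list(range(nx + 1, nx + ny + 1))
        expected = enumerate_mannwhitney(data.effect_at(a), data.effect_at(b))
        assert mannwhitney_effects(data, a, b) == pytest.approx(expected, rel=1e-9)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        data = self._data(rng.normal(size=40))
        for _ in range(20):
            a = list(rng.choice(np.arange(1, 41), size=12, replace=False))
            b = list(rng.choice(np.arange(1, 41), size=15, replace=False))
            p = mannwhitney_effects(data, a, b)
            assert 0 < p <= 1


class TestSweep:
    def _spec_and_profile(self, n, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.random(n)
        v /= np.linalg.norm(v)
        spec = SpectralResult(
            eigenvalues=np.array([1.0]), eigenvectors=v[:, None]
        )
        D = ConservationProfile(D=rng.random(n))
        return spec, D

    def test_full_size_is_trivial(self):
        n = 12
        spec, D = self._spec_and_profile(n)
        data = MutationalDataset(
            position=np.arange(1, n + 1),
            effect=np.random.default_rng(0).normal(size=n),
        )
        out = sweep_sector_size(spec, D, data, [n])
        assert out.loc[0, "p_mannwhitney"] == 1.0
        assert out.loc[0, "overlap"] == 1.0

    def test_identical_rankings_have_full_overlap(self):
        n = 10
        scores = np.linspace(1, 2, n)
        spec = SpectralResult(
            eigenvalues=np.array([1.0]),
            eigenvectors=(scores / np.linalg.norm(scores))[:, None],
        )
        D = ConservationProfile(D=scores)
        data = MutationalDataset(
            position=np.arange(1, n + 1),
            effect=np.random.default_rng(1).normal(size=n),
        )
        out = sweep_sector_size(spec, D, data, [3, 5, 7])
        assert (out["overlap"] == 1.0).all()
        assert (out["p_mannwhitney"] == 1.0).all()

    def test_overlap_bounds(self):
        spec, D = self._spec_and_profile(20, seed=4)
        data = MutationalDataset(
            position=np.arange(1, 21),
            effect=np.random.default_rng(2).normal(size=20),
        )
        out = sweep_sector_size(spec, D, data, [2, 5, 10, 20])
        assert ((out["overlap"] >= 0) & (out["overlap"] <= 1)).all()

    def test_size_out_of_range(self):
        spec, D = self._spec_and_profile(5)
        data = MutationalDataset(
            position=np.arange(1, 6), effect=np.zeros(5)
        )
        with pytest.raises(ComparisonError):
            sweep_sector_size(spec, D, data, [6])


class TestEigenvectorRegression:
    def _spectrum(self, n, m, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n, n))
        _, V = np.linalg.eigh(A + A.T)
        return SpectralResult(
            eigenvalues=np.arange(m, 0, -1.0), eigenvectors=V[:, :m]
        )

    def test_exact_linear_recovery(self):
        n = 30
        spec = self._spectrum(n, 2)
        phen = 2 * spec.eigenvectors[:, 0] - spec.eigenvectors[:, 1]
        data = MutationalDataset(
            position=np.arange(1, n + 1), effect=phen
        )
        fit = regress_phenotypes_on_eigenvectors(data, spec, m=2)
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.coefficients[1:], [2.0, -1.0], atol=1e-10)

    def test_zero_modes_fits_mean(self):
        n = 10
        spec = self._spectrum(n, 1)
        data = MutationalDataset(
            position=np.arange(1, n + 1),
            effect=np.random.default_rng(0).normal(size=n),
        )
        fit = regress_phenotypes_on_eigenvectors(data, spec, m=0)
        assert fit.r_squared == 0.0
        np.testing.assert_allclose(fit.fitted, data.effect.mean())

    def test_noise_r2_matches_null_expectation(self):
        """Pure-noise phenotypes give R^2 near m/(n_obs - 1)."""
        n, m = 100, 3
        spec = self._spectrum(n, m, seed=1)
        r2s = []
        for seed in range(40):
            data = MutationalDataset(
                position=np.arange(1, n + 1),
                effect=np.random.default_rng(seed).normal(size=n),
            )
            r2s.append(
                regress_phenotypes_on_eigenvectors(data, spec, m=m).r_squared
            )
        assert np.mean(r2s) == pytest.approx(m / (n - 1), abs=0.02)

    def test_underdetermined_errors(self):
        spec = self._spectrum(10, 4)
        data = MutationalDataset(
            position=np.arange(1, 5), effect=np.zeros(4)
        )
        with pytest.raises(ComparisonError):
            regress_phenotypes_on_eigenvectors(data, spec, m=4)
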