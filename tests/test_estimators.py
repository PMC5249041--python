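import math

import numpy as np
import pytest

from mirdirect import (
    EstimationError,
    MiConfig,
    ScoreMatrix,
    ShrinkageConfig,
    SpaceConfig,
    mind,
    mutual_information_matrix,
    network_deconvolution,
    pearson_matrix,
    shrinkage_partial_correlation,
    space_partial_correlation,
    standardize,
)
from mirdirect.data_model import MIRNA, MRNA
from mirdirect.estimators import (
    load_scores,
    space_full_shrinkage_penalty,
)

from conftest import chain_precision, make_expression, sample_ggm


def _score(values, n_mirna=1, role="OBSERVED"):
    values = np.asarray(values, dtype=float)
    p = values.shape[0]
    ids = [f"f{i}" for i in range(p)]
    kinds = [MIRNA] * n_mirna + [MRNA] * (p - n_mirna)
    return ScoreMatrix(values, ids, kinds, role)


class TestPearson:
    def test_identical_and_negated_rows(self):
        row = np.random.default_rng(0).normal(size=20)
        x = make_expression([row, row, -row])
        r = pearson_matrix(x).values
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(r), 1.0)

    def test_matches_sum_formula_oracle(self):
        x = make_expression(np.random.default_rng(1).normal(size=(5, 50)))
        r = pearson_matrix(x).values
        v = x.values
        for i in range(5):
            for j in range(5):
                xi, xj = v[i] - v[i].mean(), v[j] - v[j].mean()
                oracle = (xi * xj).sum() / math.sqrt((xi**2).sum() * (xj**2).sum())
                assert r[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(EstimationError):
            pearson_matrix(make_expression(np.ones((2, 2)) + np.eye(2)))


class TestShrinkagePartialCorrelation:
    def test_p2_equals_shrunk_pairwise_correlation(self):
        x = make_expression(np.random.default_rng(2).normal(size=(2, 40)))
        r = np.corrcoef(x.values)[0, 1]
        for lam in (0.0, 0.3, 0.7):
            est = shrinkage_partial_correlation(x, ShrinkageConfig(lam))
            assert est.values[0, 1] == pytest.approx((1 - lam) * r, abs=1e-12)

    def test_independent_features_near_zero(self):
        x = make_expression(np.random.default_rng(3).normal(size=(4, 500)))
        est = shrinkage_partial_correlation(x)
        off = est.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_lambda_zero_matches_inversion_oracle(self):
        x = make_expression(np.random.default_rng(4).normal(size=(4, 200)))
        est = shrinkage_partial_correlation(x, ShrinkageConfig(0.0)).values
        omega = np.linalg.inv(np.corrcoef(x.values))
        d = np.sqrt(np.diag(omega))
        oracle = -omega / np.outer(d, d)
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(est, oracle, atol=1e-10)

    def test_auto_lambda_in_unit_interval_and_logged(self):
        x = make_expression(np.random.default_rng(5).normal(size=(8, 10)))
        est = shrinkage_partial_correlation(x)
        lam = est.metadata["shrinkage_intensity"]
        assert 0.0 <= lam <= 1.0

    def test_larger_lambda_shrinks_partial_correlations(self):
        omega = chain_precision(0.5, 0.5)
        x = sample_ggm(omega, n=200, seed=6)
        mean_abs = []
        for lam in (0.0, 0.2, 0.5, 0.8, 1.0):
            v = shrinkage_partial_correlation(x, ShrinkageConfig(lam)).values
            mean_abs.append(np.abs(v[~np.eye(3, dtype=bool)]).mean())
        assert all(a >= b - 1e-12 for a, b in zip(mean_abs, mean_abs[1:]))
        assert mean_abs[-1] == pytest.approx(0.0, abs=1e-12)

    def test_singular_unshrunk_matrix_advises_auto(self):
        # n <= p with lam forced to 0 makes the correlation matrix singular
        x = make_expression(np.random.default_rng(7).normal(size=(10, 5)))
        with pytest.raises(EstimationError, match="auto"):
            shrinkage_partial_correlation(x, ShrinkageConfig(0.0))

    def test_manual_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ShrinkageConfig(1.5)

    def test_output_symmetric_and_bounded(self):
        x = make_expression(np.random.default_rng(8).normal(size=(6, 30)))
        v = shrinkage_partial_correlation(x).values
        assert np.abs(v - v.T).max() < 1e-10
        assert np.abs(v).max() <= 1.0


class TestSpace:
    def test_full_shrinkage_gives_exact_zero_matrix(self):
        x = standardize(make_expression(
            np.random.default_rng(9).normal(size=(5, 60))))
        lam = space_full_shrinkage_penalty(x) + 1.0
        v = space_partial_correlation(x, SpaceConfig(l1_penalty=lam)).values
        off = v[~np.eye(5, dtype=bool)]
        assert (off == 0.0).all()
        np.testing.assert_array_equal(np.diag(v), 1.0)

    def test_unpenalized_matches_shrinkage_lambda_zero(self):
        x = standardize(sample_ggm(chain_precision(0.4, 0.35), n=300, seed=10))
        sp = space_partial_correlation(
            x, SpaceConfig(l1_penalty=0.0, max_outer_iterations=10)
        ).values
        sh = shrinkage_partial_correlation(x, ShrinkageConfig(0.0)).values
        np.testing.assert_allclose(sp, sh, atol=1e-4)

    def test_chain_conditional_independence_is_exact_zero(self, chain_expression):
        v = space_partial_correlation(chain_expression).values
        assert v[0, 2] == 0.0
        assert v[0, 1] != 0.0 and v[1, 2] != 0.0

    def test_support_shrinks_with_penalty(self):
        x = standardize(make_expression(
            np.random.default_rng(11).normal(size=(8, 100))))
        cfg = lambda lam: SpaceConfig(l1_penalty=lam, max_outer_iterations=1)
        sizes = []
        for lam in (0.0, 5.0, 20.0, 80.0, 1e6):
            v = space_partial_correlation(x, cfg(lam)).values
            sizes.append(int((np.triu(v, 1) != 0).sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0

    def test_nonconvergence_warns_and_flags_metadata(self):
        x = standardize(make_expression(
            np.random.default_rng(12).normal(size=(6, 80))))
        cfg = SpaceConfig(l1_penalty=0.0, max_outer_iterations=1,
                          convergence_tolerance=1e-12, max_sweeps=1)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out = space_partial_correlation(x, cfg)
        assert out.metadata["converged"] is False


class TestMutualInformation:
    def test_duplicated_feature_pair_reaches_log_bins(self):
        # n divisible by B makes the equal-frequency self-MI exactly log B
        row = np.random.default_rng(13).normal(size=16)
        x = make_expression([row, row.copy(), row + 100.0])
        out = mutual_information_matrix(x, MiConfig(bin_count=4))
        assert out.values[0, 1] == pytest.approx(math.log(4), abs=1e-12)
        assert out.values[0, 2] == pytest.approx(math.log(4), abs=1e-12)
        np.testing.assert_array_equal(np.diag(out.values), 0.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(14)
        x = make_expression(rng.uniform(size=(2, 1000)))
        out = mutual_information_matrix(x)
        assert out.values[0, 1] < 0.05

    def test_four_sample_contingency_oracle(self):
        # B=2 bins; joint histogram enumerated by hand below
        x = make_expression([[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]])
        out = mutual_information_matrix(x, MiConfig(bin_count=2))
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 0, 1, 1])
        joint = np.zeros((2, 2))
        for i, j in zip(a, b):
            joint[i, j] += 0.25
        oracle = 0.0
        for i in range(2):
            for j in range(2):
                if joint[i, j] > 0:
                    oracle += joint[i, j] * math.log(
                        joint[i, j] / (joint[i].sum() * joint[:, j].sum())
                    )
        assert out.values[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_bin_count_exceeding_samples_rejected(self):
        x = make_expression(np.random.default_rng(15).normal(size=(2, 4)))
        with pytest.raises(EstimationError, match="bin_count"):
            mutual_information_matrix(x, MiConfig(bin_count=8))

    def test_all_entries_nonnegative(self):
        x = make_expression(np.random.default_rng(16).normal(size=(6, 50)))
        assert (mutual_information_matrix(x).values >= 0).all()


class TestNetworkDeconvolution:
    def test_zero_matrix_is_fixed_point(self):
        out = network_deconvolution(_score(np.zeros((4, 4))))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_edge_eigenvalue_closed_form(self):
        # the one-edge matrix has eigenvalues ±a = ±0.5, mapping per
        # eigenvalue to a/(1+a) = 1/3 and -a/(1-a) = -1; the resulting
        # off-diagonal entry is (1/3 - (-1))/2 = 2/3 and the output
        # diagonal is forced to 0
        g = _score([[0.0, 0.5], [0.5, 0.0]])
        out = network_deconvolution(g, rescale=False)
        assert out.values[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert out.values[0, 0] == 0.0
        # matrix-inverse oracle for the same quantity, before diag zeroing
        oracle = g.values @ np.linalg.inv(np.eye(2) + g.values)
        assert oracle[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_forward_model_round_trip(self):
        rng = np.random.default_rng(17)
        g = rng.normal(size=(8, 8))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        vals, vecs = np.linalg.eigh(g)
        g = (vecs * (vals / np.abs(vals).max() * 0.6)) @ vecs.T
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        g_obs = g @ np.linalg.inv(np.eye(8) - g)
        rec = network_deconvolution(_score(g_obs), rescale=False)
        np.testing.assert_allclose(rec.values, g, atol=1e-8)

    def test_matches_matrix_function_oracle(self):
        # applying f(x) = x/(1+x) in the eigenbasis must agree with an
        # independent matrix-function route (scipy funm), up to the
        # diagonal that the estimator zeroes
        from scipy.linalg import funm

        rng = np.random.default_rng(18)
        g = rng.normal(size=(6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        out = network_deconvolution(_score(g), spectral_bound=0.9)
        scaled = g * out.metadata["scaling_factor"]
        oracle = np.real(funm(scaled, lambda x: x / (1 + x)))
        np.fill_diagonal(oracle, 0.0)
        np.testing.assert_allclose(out.values, oracle, atol=1e-8)

    def test_eigenvalue_map_strictly_increasing(self):
        lam = np.linspace(-0.99, 5.0, 200)
        mapped = lam / (1 + lam)
        assert (np.diff(mapped) > 0).all()

    def test_rescaling_caps_spectral_radius(self):
        rng = np.random.default_rng(19)
        g = rng.normal(size=(5, 5)) * 3
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        out = network_deconvolution(_score(g), spectral_bound=0.9)
        assert out.metadata["scaling_factor"] < 1.0

    def test_asymmetric_input_rejected(self):
        sm = _score(np.zeros((3, 3)))
        sm.values[0, 1] = 1e-4  # corrupt after construction
        with pytest.raises(EstimationError, match="asymmetric"):
            network_deconvolution(sm)


class TestMind:
    def test_independent_features_near_zero(self):
        x = make_expression(np.random.default_rng(20).normal(size=(4, 1000)))
        out = mind(x)
        assert np.abs(out.values).max() < 0.1

    def test_chain_downweights_transitive_pair(self):
        x = sample_ggm(chain_precision(0.6, 0.6), n=500, seed=21)
        v = np.abs(mind(x).values)
        assert v[0, 2] < v[0, 1]
        assert v[0, 2] < v[1, 2]

    def test_isolated_correlated_pair_ranks_first(self):
        rng = np.random.default_rng(22)
        base = rng.normal(size=(5, 400))
        base[1] = base[0] * 0.8 + 0.4 * rng.normal(size=400)  # one real pair
        v = np.abs(mind(make_expression(base)).values)
        iu = np.triu_indices(5, 1)
        best = np.argmax(v[iu])
        assert (iu[0][best], iu[1][best]) == (0, 1)


class TestScoreMatrixSerialization:
    def test_save_load_round_trip(self, tmp_path):
        x = make_expression(np.random.default_rng(23).normal(size=(4, 30)))
        s = shrinkage_partial_correlation(x)
        path = tmp_path / "scores.tsv"
        s.save(path)
        loaded = load_scores(path)
        np.testing.assert_allclose(loaded.values, s.values, atol=1e-12)
        assert loaded.role == s.role
        assert loaded.metadata["estimator"] == "corpcor"

    def test_asymmetry_rejected_at_construction(self):
        v = np.eye(3)
        v[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            _score(v)
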