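import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid
from scipy.special import expit

from likertnorm.data import ItemResponseMatrix
from likertnorm.grm import (
    GRMParameters,
    category_probabilities,
    eap_score,
    eap_scores,
    fit_grm_multigroup,
    polychoric_correlation,
    polychoric_eigen_screen,
    theta_to_t,
)
from likertnorm.synthetic_mansa import (
    POPULATION,
    SimulationConfig,
    default_mansa_params,
    generate_grm_responses,
)


class TestThetaToT:
    def test_center(self):
        assert theta_to_t(0.0) == 50.0

    def test_affine(self):
        assert theta_to_t(1.5) == 65.0
        assert round(float(theta_to_t(-2.81)), 1) == 21.9


def _single_item_params(a, b, n_categories):
    return GRMParameters(
        item_names=["i1", "i2"][: len(np.atleast_1d(a))],
        a=np.atleast_1d(a),
        b=np.atleast_2d(b),
        n_categories=n_categories,
        group_means={"g": 0.0},
        group_sds={"g": 1.0},
        reference_group="g",
    )


class TestEAP:
    def test_dichotomous_brute_force_oracle(self):
        # 1 item, 2 categories, a=1, b=0, response=2, prior N(0,1):
        # posterior mean = int theta*logistic(theta)*phi / int logistic*phi
        params = _single_item_params([1.0], [[0.0]], 2)
        grid = np.linspace(-8, 8, 20_001)
        f = expit(grid) * stats.norm.pdf(grid)
        oracle = trapezoid(grid * f, grid) / trapezoid(f, grid)
        est = eap_score([2], params, "g", n_quadrature=10_001, quad_range=(-8, 8))
        assert est.theta == pytest.approx(oracle, abs=1e-6)

    def test_fine_grid_oracle_random_patterns(self, default_params):
        params = default_params
        rng = np.random.default_rng(4)
        grid = np.linspace(-8, 8, 10_001)
        logpdf = stats.norm.logpdf(grid)
        for _ in range(5):
            pattern = rng.integers(1, 8, params.n_items)
            logf = logpdf.copy()
            for i, k in enumerate(pattern):
                p = category_probabilities(params.a[i], params.b[i], grid)[:, k - 1]
                logf += np.log(np.clip(p, 1e-300, None))
            f = np.exp(logf - logf.max())
            oracle = trapezoid(grid * f, grid) / trapezoid(f, grid)
            est = eap_score(pattern, params, POPULATION, n_quadrature=10_001, quad_range=(-8, 8))
            assert est.theta == pytest.approx(oracle, abs=1e-6)

    def test_zero_information_limit(self):
        params = _single_item_params([1e-9], [[0.0]], 2)
        est = eap_score([1], params, "g", n_quadrature=4001, quad_range=(-8, 8))
        assert est.theta == pytest.approx(0.0, abs=1e-6)
        assert est.se == pytest.approx(1.0, abs=1e-6)

    def test_dominating_pattern_larger_theta(self, default_params):
        lo = np.full(12, 3)
        hi = lo.copy()
        hi[[0, 4, 7]] = 6  # dominates category-wise
        t_lo = eap_score(lo, default_params, POPULATION).theta
        t_hi = eap_score(hi, default_params, POPULATION).theta
        assert t_hi > t_lo

    def test_all_missing_errors(self, default_params):
        with pytest.raises(ValueError):
            eap_score([np.nan] * 12, default_params, POPULATION)

    def test_t_irt_identity(self, default_params):
        est = eap_score([4] * 12, default_params, POPULATION)
        assert est.t_irt == 10.0 * est.theta + 50.0

    def test_batch_matches_single(self, small_matrix, pipeline_result):
        params = pipeline_result.params
        batch = eap_scores(small_matrix, params)
        j = 17
        single = eap_score(
            small_matrix.responses[j], params, str(small_matrix.group[j])
        )
        assert batch[j, 0] == pytest.approx(single.theta, abs=1e-10)
        assert batch[j, 1] == pytest.approx(single.se, abs=1e-10)


class TestFit:
    def test_parameter_recovery(self, pipeline_result):
        """n=2000/group simulated from the default fixture; the pipeline's
        fitted model must recover it."""
        truth = default_mansa_params()
        fitted = pipeline_result.params
        a_rmse = float(np.sqrt(((fitted.a - truth.a) ** 2).mean()))
        b_rmse = float(np.sqrt(((fitted.b - truth.b) ** 2).mean()))
        assert a_rmse < 0.15
        assert b_rmse < 0.15
        assert abs(
            fitted.group_means["clinical"] - truth.group_means["clinical"]
        ) < 0.1

    def test_discrimination_bias(self, pipeline_result):
        truth = default_mansa_params()
        bias = float((pipeline_result.params.a - truth.a).mean())
        assert abs(bias) < 0.1

    def test_loglik_monotone(self):
        m = generate_grm_responses(SimulationConfig(n_per_group=300, seed=2, covariates=False))
        with warnings.catch_warnings():
            # a monotonicity violation beyond 1e-8 raises via this filter
            warnings.simplefilter("error", RuntimeWarning)
            params = fit_grm_multigroup(m, max_iter=60)
        assert params.log_likelihood is not None

    def test_single_category_item_errors(self):
        resp = np.column_stack(
            [np.full(30, 3.0), np.tile([1.0, 2, 3, 4, 5, 6], 5)]
        )
        m = ItemResponseMatrix(resp, ["flat", "ok"], np.array(["g"] * 30, dtype=object))
        with pytest.raises(ValueError, match="flat"):
            fit_grm_multigroup(m)

    def test_reference_relabel_invariance(self):
        """Swapping the reference anchors the scale differently but the
        group-mean difference is invariant."""
        m = generate_grm_responses(SimulationConfig(n_per_group=500, seed=6, covariates=False))
        p1 = fit_grm_multigroup(m, reference_group="population")
        p2 = fit_grm_multigroup(m, reference_group="clinical")
        gap1 = p1.group_means["population"] - p1.group_means["clinical"]
        gap2 = (p2.group_means["population"] - p2.group_means["clinical"]) * p1.group_sds[
            "clinical"
        ]
        # p2's scale unit is the clinical SD of p1's scale; rescale to compare
        assert gap1 == pytest.approx(gap2, abs=0.05)

    def test_reference_moments_exact(self, pipeline_result):
        p = pipeline_result.params
        assert p.group_means[p.reference_group] == 0.0
        assert p.group_sds[p.reference_group] == 1.0

    def test_reference_tirt_calibration(self, pipeline_result):
        sc = pipeline_result.scores
        ref = sc[sc.group == POPULATION]
        assert abs(ref.t_irt.mean() - 50.0) < 0.2
        # shrinkage keeps the EAP SD at or below the prior SD
        assert ref.t_irt.std(ddof=1) <= 10.0 + 0.1
        assert ref.t_irt.std(ddof=1) > 10.0 - 3.0

    def test_serialization_roundtrip(self, pipeline_result, tmp_path):
        import yaml

        d = pipeline_result.params.to_dict()
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        back = GRMParameters.from_dict(yaml.safe_load(path.read_text()))
        # bit-stable at the 12-significant-digit precision written
        np.testing.assert_array_equal(
            back.a, np.array([float(f"{v:.12g}") for v in pipeline_result.params.a])
        )
        assert back.group_sds == {
            g: float(f"{v:.12g}") for g, v in pipeline_result.params.group_sds.items()
        }


class TestPolychoric:
    def test_independent_items_null(self):
        rng = np.random.default_rng(8)
        resp = rng.integers(1, 8, size=(5000, 6)).astype(float)
        m = ItemResponseMatrix(resp, [f"i{k}" for k in range(6)],
                               np.array(["g"] * 5000, dtype=object))
        ev = polychoric_eigen_screen(m)
        assert np.all(np.abs(ev - 1.0) < 0.15)

    def test_single_factor_spike(self, small_matrix):
        ev = polychoric_eigen_screen(small_matrix)
        assert ev[0] > 3 * ev[1]
        assert np.all(np.diff(ev) <= 1e-12)

    def test_perfect_monotone_pair(self):
        x = np.tile(np.arange(1, 8), 30).astype(float)
        r = polychoric_correlation(x, x, 7)
        assert r > 0.98

    def test_degenerate_pair_falls_back(self):
        x = np.full(40, 3.0)
        y = np.tile(np.arange(1, 5), 10).astype(float)
        with pytest.warns(RuntimeWarning):
            polychoric_correlation(x, y, 7)

    def test_known_rho_recovery(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 5000)
        cuts = [-1.5, -0.5, 0.5, 1.5]
        x = 1.0 + np.digitize(z[:, 0], cuts)
        y = 1.0 + np.digitize(z[:, 1], cuts)
        assert polychoric_correlation(x, y, 5) == pytest.approx(0.6, abs=0.05)

    def test_too_few_items(self, toy_matrix):
        m = toy_matrix.subset(np.array([True] * 6))
        m2 = ItemResponseMatrix(m.responses[:, :2], m.item_names[:2], m.group)
        with pytest.raises(ValueError):
            polychoric_eigen_screen(m2)
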