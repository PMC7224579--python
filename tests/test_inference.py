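"""Inversion, free energy, Bayesian model reduction, classification."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal
from sklearn.base import clone

from scalesym.inference import (
    GaussianDensity,
    ModelSpec,
    ScaleSymmetryClassifier,
    VariationalLaplace,
    bayesian_model_reduction,
    classify_symmetry,
    free_energy,
    invert,
    model_probabilities,
    noether_parameter_map,
)
from scalesym.simulate import integrate_eom, make_fixture


@pytest.fixture(scope="module")
def spiral_data():
    b = make_fixture("spiral_2d", seed=2)
    return b.observed.times, b.observed.y


@pytest.fixture(scope="module")
def ellipse_data():
    b = make_fixture("ellipse_2d", seed=2)
    return b.observed.times, b.observed.y


@pytest.fixture(scope="module")
def spiral_report(spiral_data):
    return classify_symmetry(*spiral_data)


@pytest.fixture(scope="module")
def ellipse_report(ellipse_data):
    return classify_symmetry(*ellipse_data)


class TestGaussianDensity:
    def test_validation(self):
        with pytest.raises(ValueError):
            GaussianDensity(("a",), [0.0, 1.0], [[1.0]])
        with pytest.raises(ValueError):
            GaussianDensity(("a", "b"), [0.0, 0.0], [[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            GaussianDensity(("a",), [0.0], [[-1.0]])

    def test_entry_replacement(self):
        g = GaussianDensity.from_moments(("a", "b"), [1.0, 2.0], [1.0, 4.0])
        r = g.with_entry("b", 0.0, 1e-8)
        assert r["b"] == 0.0
        assert r.sd("b") == pytest.approx(1e-4)
        assert r["a"] == 1.0

    def test_round_trip(self):
        g = GaussianDensity.from_moments(("a", "b"), [1.0, -2.0], [0.5, 2.0])
        assert GaussianDensity.from_dict(g.to_dict()).mean == pytest.approx(g.mean)


class TestFreeEnergy:
    def test_complexity_vanishes_at_prior(self, inverse_cube_family):
        import dataclasses

        t = np.arange(100) * 0.05
        y = integrate_eom(inverse_cube_family, 1.0, 1.5, t).positions
        base = ModelSpec.default(dt=0.05, data=y)
        names = base.param_prior.names
        # prior centred on an integrable member, so KL(prior || prior) = 0
        centre = {"alpha": 1.0, "delta": 0.2, "C0": 0.8, "C2": 0.5, "C3": 0.0,
                  "C4": 0.0, "log_q0": 0.0, "v0": 1.5}
        prior = GaussianDensity.from_moments(
            names, [centre[n] for n in names], np.ones(len(names))
        )
        model = dataclasses.replace(base, param_prior=prior)
        F = free_energy(model, t, y, prior, model.hyper_prior)
        from scalesym.inference import _safe_predict

        pred = _safe_predict(model, names, prior.mean, t)
        lam = math.exp(model.hyper_prior["log_prec_obs"])
        r = y - pred
        acc = (
            -0.5 * lam * float(r @ r)
            + 0.5 * len(y) * model.hyper_prior["log_prec_obs"]
            - 0.5 * len(y) * math.log(2 * math.pi)
        )
        assert F == pytest.approx(acc, rel=1e-12)

    def test_true_parameters_beat_perturbed_on_clean_data(self, inverse_cube_family):
        t = np.arange(150) * 0.05
        y = integrate_eom(inverse_cube_family, 1.0, 1.5, t).positions
        model = ModelSpec.default(dt=0.05, data=y)
        names = model.param_prior.names
        truth = {"alpha": 2.0, "delta": 0.0, "C0": 1.0, "C2": 0.5, "C3": 0.0,
                 "C4": 0.0, "log_q0": 0.0, "v0": 1.5}
        mu_true = np.array([truth[n] for n in names])
        cov = 1e-6 * np.eye(len(names))
        hyper = model.hyper_prior
        F_true = free_energy(model, t, y, GaussianDensity(names, mu_true, cov), hyper)
        mu_pert = mu_true.copy()
        mu_pert[names.index("delta")] += 0.3
        F_pert = free_energy(model, t, y, GaussianDensity(names, mu_pert, cov), hyper)
        assert F_true > F_pert

    def test_integration_failure_is_rejected_not_raised(self, inverse_cube_family):
        t = np.arange(50) * 0.05
        y = integrate_eom(inverse_cube_family, 1.0, 1.5, t).positions
        model = ModelSpec.default(dt=0.05, data=y)
        names = model.param_prior.names
        bad = {"alpha": 2.0, "delta": 0.0, "C0": 1.0, "C2": 0.0, "C3": 0.0,
               "C4": 0.0, "log_q0": 0.0, "v0": 1.5}  # C2 = 0: singular dynamics
        F = free_energy(
            model, t, y,
            GaussianDensity(names, np.array([bad[n] for n in names]), np.eye(len(names))),
            model.hyper_prior,
        )
        assert F == -np.inf


class TestInvert:
    def test_spiral_recovery(self, spiral_report):
        """Posterior from the inverse-cube spiral covers the generating
        parameters: alpha = 2 and delta = 0 within two posterior sd."""
        p = spiral_report.posterior_full
        assert abs(p["alpha"] - 2.0) <= 2 * p.sd("alpha")
        assert abs(p["delta"]) <= 2 * p.sd("delta")

    def test_ellipse_recovery_excludes_symmetry(self, ellipse_report):
        """The Kepler orbit is scale-free with delta = 1/2; zero is excluded."""
        p = ellipse_report.posterior_full
        assert p["delta"] == pytest.approx(0.5, abs=0.05)
        assert abs(p["delta"]) > 2 * p.sd("delta")

    def test_free_energy_trace_monotone(self, spiral_report):
        trace = np.array(spiral_report.inversion.free_energy_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_posterior_covariance_spd(self, spiral_report):
        cov = spiral_report.posterior_full.cov
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_noise_level_recovered(self, spiral_data):
        times, y = spiral_data
        b = make_fixture("spiral_2d", seed=2)
        res = invert(times, y, ModelSpec.default(dt=times[1] - times[0], data=y))
        lam = math.exp(res.hyper_posterior["log_prec_obs"])
        assert 1.0 / math.sqrt(lam) == pytest.approx(b.metadata["obs_noise_sd"], rel=0.2)

    def test_pathological_inputs_rejected(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ValueError):
            invert(t, np.ones(10), ModelSpec.default(dt=0.1))
        with pytest.raises(ValueError):
            invert(t[:3], np.array([1.0, 2.0, 3.0]), ModelSpec.default(dt=0.1))


class TestBayesianModelReduction:
    def test_no_reduction_is_neutral(self):
        prior = GaussianDensity.from_moments(("a", "b"), [0.0, 0.0], [1.0, 1.0])
        post = GaussianDensity(
            ("a", "b"), np.array([0.3, -0.2]),
            np.array([[0.05, 0.01], [0.01, 0.08]]),
        )
        reduced, dF = bayesian_model_reduction(prior, post, prior)
        assert dF == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(reduced.mean, post.mean)
        np.testing.assert_allclose(reduced.cov, post.cov)

    def test_matches_quadrature_one_parameter(self):
        """dF from the Gaussian identity vs brute-force evidence integrals.

        Likelihood implied by (prior, posterior): l(x) ∝ q(x)/p(x); the
        evidence under any prior p~ is  ∫ l(x) p~(x) dx.
        """
        prior = GaussianDensity.from_moments(("d",), [0.0], [1.0])
        post = GaussianDensity.from_moments(("d",), [0.4], [0.09])
        reduced_prior = GaussianDensity.from_moments(("d",), [0.0], [1e-6])

        def likelihood(x):
            return multivariate_normal.pdf(x, 0.4, 0.09) / multivariate_normal.pdf(x, 0.0, 1.0)

        z_full, _ = quad(lambda x: likelihood(x) * multivariate_normal.pdf(x, 0.0, 1.0), -10, 10)
        z_red, _ = quad(
            lambda x: likelihood(x) * multivariate_normal.pdf(x, 0.0, 1e-6), -0.05, 0.05
        )
        _, dF = bayesian_model_reduction(prior, post, reduced_prior)
        assert dF == pytest.approx(math.log(z_red / z_full), abs=1e-6)

    def test_matches_quadrature_two_parameters(self):
        names = ("a", "d")
        prior = GaussianDensity.from_moments(names, [0.0, 0.0], [1.0, 1.0])
        post = GaussianDensity(
            names, np.array([0.5, 0.3]), np.array([[0.04, 0.015], [0.015, 0.06]])
        )
        reduced_prior = prior.with_entry("d", 0.0, 1e-6)

        p0 = multivariate_normal(prior.mean, prior.cov)
        q = multivariate_normal(post.mean, post.cov)
        pr = multivariate_normal(reduced_prior.mean, reduced_prior.cov)

        from scipy.integrate import dblquad

        # dblquad(f, xa, xb, ya, yb) with f(y, x): x = a, y = d
        def integrand(maker):
            return lambda d, a: q.pdf([a, d]) / p0.pdf([a, d]) * maker.pdf([a, d])

        z_full, _ = dblquad(integrand(p0), -6, 6, -6, 6, epsabs=1e-10)
        z_red, _ = dblquad(integrand(pr), -6, 6, -0.02, 0.02, epsabs=1e-12)
        _, dF = bayesian_model_reduction(prior, post, reduced_prior)
        assert dF == pytest.approx(math.log(z_red / z_full), abs=1e-6)

    def test_pinning_a_null_parameter_gains_evidence(self):
        prior = GaussianDensity.from_moments(("d",), [0.0], [1.0])
        post = GaussianDensity.from_moments(("d",), [0.0], [0.01])
        reduced = prior.with_entry("d", 0.0, 1e-8)
        _, dF = bayesian_model_reduction(prior, post, reduced)
        assert dF > 0

    def test_dimension_mismatch(self):
        a = GaussianDensity.from_moments(("x",), [0.0], [1.0])
        b = GaussianDensity.from_moments(("y",), [0.0], [1.0])
        with pytest.raises(ValueError):
            bayesian_model_reduction(a, a, b)


class TestModelProbabilities:
    def test_equal_evidence_is_even_odds(self):
        assert model_probabilities(3.0, 3.0) == pytest.approx((0.5, 0.5))
        assert model_probabilities(3.0, 3.0, "paper_norm") == pytest.approx((0.5, 0.5))

    def test_softmax_closed_form(self):
        p = model_probabilities(math.log(3.0), 0.0)
        assert p == pytest.approx((0.75, 0.25))
        assert sum(p) == pytest.approx(1.0)

    def test_printed_normalisation_inverts_for_negative_values(self):
        """F/(F_r + F_f) prefers the LESS probable model when F < 0."""
        p = model_probabilities(-10.0, -30.0, "paper_norm")
        assert p == pytest.approx((0.25, 0.75))

    def test_mixed_signs_rejected(self):
        with pytest.raises(ValueError):
            model_probabilities(1.0, -1.0, "paper_norm")


class TestClassifySymmetry:
    def test_spiral_is_symmetric(self, spiral_report):
        assert spiral_report.label == "scale-symmetric"
        assert spiral_report.p_reduced > 0.5
        assert spiral_report.noether_drift_reduced <= 1e-2

    def test_ellipse_is_scale_free(self, ellipse_report):
        assert ellipse_report.label == "scale-free"
        assert ellipse_report.p_reduced < 0.5
        assert ellipse_report.noether_drift_full > 1e-1

    def test_probabilities_sum_to_one(self, spiral_report, ellipse_report):
        for r in (spiral_report, ellipse_report):
            assert r.p_reduced + r.p_full == pytest.approx(1.0)

    def test_decision_invariant_under_rescaling(self, spiral_data, spiral_report):
        """Rescaling data by lambda and times by lambda**alpha (alpha = 2)
        must not change the symmetric-vs-free call."""
        times, y = spiral_data
        lam = 2.0
        rep = classify_symmetry(lam**2 * times, lam * y)
        assert rep.label == spiral_report.label

    def test_1d_fixture_posterior_is_symmetric_compatible(self):
        """On a single 1D series, delta is weakly identified; the posterior
        must still be compatible with the generating delta = 0."""
        b = make_fixture("symmetric_1d", seed=1)
        res = invert(b.observed.times, b.observed.y,
                     ModelSpec.default(dt=0.05, data=b.observed.y))
        p = res.posterior
        assert abs(p["delta"]) <= 2 * p.sd("delta")
        resid_sd = float(np.std(b.observed.y - res.predicted))
        assert resid_sd <= 3 * b.metadata["obs_noise_sd"]


class TestNoetherParameterMap:
    def test_single_node_reproduces_free_particle_charge(self, free_particle_family):
        axes, values = noether_parameter_map(
            free_particle_family, {"C2": np.array([0.5])}, state=(3.0, 2.0, 0.0)
        )
        assert values.shape == (1,)
        assert values[0] == pytest.approx(6.0)  # m qdot (q - qdot t)

    def test_charge_independent_of_quartic_coefficient_at_rest(self, inverse_cube_family):
        axes, values = noether_parameter_map(
            inverse_cube_family,
            {"C4": np.linspace(-1, 1, 7), "alpha": np.array([2.0])},
            state=(1.5, 0.0, 0.0),
        )
        assert np.ptp(values) == pytest.approx(0.0, abs=1e-12)

    def test_normalised_map_peaks_at_one(self, inverse_cube_family):
        _, values = noether_parameter_map(
            inverse_cube_family,
            {"alpha": np.linspace(1, 3, 5), "C0": np.linspace(-1, 1, 5)},
            state=(1.2, 0.7, 1.0),
            normalise=True,
        )
        assert np.nanmax(np.abs(values)) == pytest.approx(1.0)

    def test_grid_arity_enforced(self, inverse_cube_family):
        with pytest.raises(ValueError):
            noether_parameter_map(inverse_cube_family, {}, state=(1, 1, 0))
        with pytest.raises(ValueError):
            noether_parameter_map(
                inverse_cube_family, {"delta": np.array([0.0])}, state=(1, 1, 0)
            )


class TestEstimators:
    def test_variational_laplace_estimator(self, spiral_data):
        times, y = spiral_data
        est = VariationalLaplace(max_iter=16)
        est.fit(times, y)
        assert hasattr(est, "posterior_")
        assert np.isfinite(est.free_energy_)
        pred = est.predict(times)
        assert pred.shape == y.shape
        # sklearn protocol
        cloned = clone(est)
        assert cloned.get_params()["max_iter"] == 16

    def test_classifier_estimator(self, spiral_data):
        times, y = spiral_data
        est = ScaleSymmetryClassifier()
        est.fit(times, y)
        assert est.predict() == est.label_
        assert est.label_ in ("scale-symmetric", "scale-free", "undetermined")
        assert 0.0 <= est.p_symmetric_ <= 1.0
        params = est.get_params()
        assert "method" in params and params["method"] == "softmax"
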