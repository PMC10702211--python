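"""VB-HMM fitting, model selection, likelihood evaluation and sampling."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazehmm import GazeHMM, GaussianROI, VBConfig
from gazehmm.vbhmm import (
    DegenerateDataError,
    fit_vbhmm,
    select_model,
    log_likelihood,
    sample_sequence,
)


def brute_force_loglik(model: GazeHMM, X: np.ndarray) -> float:
    """Path-enumeration oracle: log-sum over all K^T state paths,
    accumulated in log space so distant observations cannot underflow."""
    from scipy.special import logsumexp

    K, T = model.n_states, len(X)
    logdens = np.array([
        multivariate_normal.logpdf(X, r.mean, r.cov) for r in model.emissions
    ]).reshape(K, T)
    log_terms = []
    with np.errstate(divide="ignore"):
        logpriors = np.log(model.priors)
        logtrans = np.log(model.transitions)
    for path in itertools.product(range(K), repeat=T):
        lp = logpriors[path[0]]
        for a, b in zip(path, path[1:]):
            lp += logtrans[a, b]
        for t, k in enumerate(path):
            lp += logdens[k, t]
        log_terms.append(lp)
    return float(logsumexp(log_terms))


def random_model(rng, K):
    priors = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    rois = []
    for _ in range(K):
        mean = rng.uniform([500, 100], [1400, 1000])
        L = rng.uniform(20, 120, size=2)
        rho = rng.uniform(-0.5, 0.5)
        cov = np.array([[L[0] ** 2, rho * L[0] * L[1]],
                        [rho * L[0] * L[1], L[1] ** 2]])
        rois.append(GaussianROI(mean, cov))
    return GazeHMM(priors, A, rois)


class TestLogLikelihood:
    def test_single_state_collapses_to_gaussian_sum(self, single_state_model, rng):
        X = rng.normal([960, 540], 100, size=(7, 2))
        expected = multivariate_normal.logpdf(
            X, single_state_model.emissions[0].mean,
            single_state_model.emissions[0].cov).sum()
        assert log_likelihood(single_state_model, X) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("K,T", [(2, 3), (2, 6), (3, 4)])
    def test_matches_path_enumeration(self, rng, K, T):
        for _ in range(5):
            model = random_model(rng, K)
            X = rng.uniform([500, 100], [1400, 1000], size=(T, 2))
            assert log_likelihood(model, X) == pytest.approx(
                brute_force_loglik(model, X), abs=1e-8)

    def test_matches_hmmlearn_forward(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(rng, 3)
        X = rng.uniform([500, 100], [1400, 1000], size=(40, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = model.priors
        ref.transmat_ = model.transitions
        ref.means_ = np.stack([r.mean for r in model.emissions])
        ref.covars_ = np.stack([r.cov for r in model.emissions])
        assert log_likelihood(model, X) == pytest.approx(ref.score(X), abs=1e-7)

    def test_appending_a_fixation_never_increases_loglik(self, rng):
        model = random_model(rng, 2)
        X = rng.uniform([500, 100], [1400, 1000], size=(10, 2))
        lls = [log_likelihood(model, X[:T]) for T in range(1, 11)]
        assert all(b <= a for a, b in zip(lls, lls[1:]))


class TestFitVBHMM:
    def test_recovers_single_gaussian_mean(self, rng):
        true_mean = np.array([900.0, 500.0])
        X = rng.normal(true_mean, 80.0, size=(200, 2))
        cfg = VBConfig(n_restarts=5)
        model, _ = fit_vbhmm([X], 1, cfg, rng)
        se = 80.0 / np.sqrt(200)
        assert model.n_states == 1
        np.testing.assert_allclose(model.emissions[0].mean, X.mean(axis=0), atol=3 * se)

    def test_two_state_alternating_chain_recovered(self, rng):
        # two well-separated clusters visited in strict alternation
        means = np.array([[700.0, 300.0], [1200.0, 800.0]])
        seqs = []
        for _ in range(20):
            states = np.arange(20) % 2
            X = means[states] + rng.normal(0, 30, size=(20, 2))
            seqs.append(X)
        cfg = VBConfig(n_restarts=5)
        model, _ = fit_vbhmm(seqs, 2, cfg, rng)
        assert model.n_states == 2
        A = model.transitions
        assert A[0, 1] > A[0, 0] and A[1, 0] > A[1, 1]  # off-diagonal dominant

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal([960, 540], 100, size=(30, 2))
        cfg = VBConfig(n_restarts=3, rng_seed=99)
        m1, b1 = fit_vbhmm([X], 2, cfg)
        m2, b2 = fit_vbhmm([X], 2, cfg)
        assert b1 == b2
        np.testing.assert_array_equal(m1.priors, m2.priors)
        np.testing.assert_array_equal(m1.transitions, m2.transitions)
        for r1, r2 in zip(m1.emissions, m2.emissions):
            np.testing.assert_array_equal(r1.mean, r2.mean)
            np.testing.assert_array_equal(r1.cov, r2.cov)

    def test_too_few_fixations_raise(self, rng):
        X = rng.normal([960, 540], 50, size=(2, 2))
        with pytest.raises(DegenerateDataError):
            fit_vbhmm([X], 4, VBConfig(n_restarts=1), rng)

    def test_elbo_trace_nondecreasing(self, rng, archetypes):
        seq = sample_sequence(archetypes[1].hmm, 30, rng)
        model, _ = fit_vbhmm([seq], 3, VBConfig(n_restarts=1), rng)
        trace = np.array(model.elbo_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))


class TestSelectModel:
    def test_single_state_data_selects_one_roi(self, single_state_model, rng):
        seq = sample_sequence(single_state_model, 30, rng)
        cfg = VBConfig(K_range=(1, 4), n_restarts=5)
        model = select_model([seq], cfg, rng)
        assert model.n_states == 1

    def test_two_roi_archetype_selects_two(self, archetypes, rng):
        seq = sample_sequence(archetypes[1].hmm, 30, rng)
        cfg = VBConfig(K_range=(1, 4), n_restarts=8)
        model = select_model([seq], cfg, rng)
        assert model.n_states == 2

    def test_empty_input_errors(self):
        with pytest.raises(DegenerateDataError):
            select_model([], VBConfig(n_restarts=1))

    def test_parameter_recovery_well_separated(self, rng):
        """Two-state chains with ROI means >= 6 SD apart: selected K = 2 and
        means within 10 px in >= 95% of seeded replicates."""
        gen = GazeHMM(
            [0.5, 0.5],
            [[0.7, 0.3], [0.3, 0.7]],
            [GaussianROI([800, 400], np.diag([40.0 ** 2, 40.0 ** 2])),
             GaussianROI([1120, 700], np.diag([40.0 ** 2, 40.0 ** 2]))],
        )
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            seqs = [sample_sequence(gen, 20, r) for _ in range(50)]
            cfg = VBConfig(K_range=(1, 4), n_restarts=3)
            model = select_model(seqs, cfg, r)
            if model.n_states != 2:
                continue
            fitted = np.stack([roi.mean for roi in model.emissions])
            truth = np.stack([roi.mean for roi in gen.emissions])
            d = np.linalg.norm(fitted[:, None] - truth[None], axis=2)
            best = min(d[0, 0] + d[1, 1], d[0, 1] + d[1, 0])
            if best / 2 <= 10.0:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestSampleSequence:
    def test_law_of_large_numbers_single_state(self, single_state_model, rng):
        seq = sample_sequence(single_state_model, 10_000, rng)
        se = 150.0 / np.sqrt(10_000)
        np.testing.assert_allclose(seq.positions().mean(axis=0), [960, 540], atol=3 * se)

    def test_identity_transitions_keep_start_state(self, rng):
        model = GazeHMM(
            [1.0, 0.0], np.eye(2),
            [GaussianROI([700, 400], np.diag([25.0, 25.0])),
             GaussianROI([1200, 700], np.diag([25.0, 25.0]))],
        )
        seq = sample_sequence(model, 50, rng)
        assert np.all(seq.states == 0)
        np.testing.assert_allclose(seq.positions().mean(axis=0), [700, 400], atol=5)

    def test_reproducible_with_fixed_seed(self, archetypes):
        s1 = sample_sequence(archetypes[0].hmm, 20, np.random.default_rng(5))
        s2 = sample_sequence(archetypes[0].hmm, 20, np.random.default_rng(5))
        np.testing.assert_array_equal(s1.positions(), s2.positions())
        np.testing.assert_array_equal(s1.duration_ms, s2.duration_ms)

    def test_rejects_nonpositive_length(self, single_state_model, rng):
        with pytest.raises(ValueError):
            sample_sequence(single_state_model, 0, rng)


class TestSerialization:
    def test_json_round_trip_exact(self, archetypes, tmp_path):
        model = archetypes[0].hmm
        path = tmp_path / "m.json"
        model.save(path, config_digest="abc")
        back = GazeHMM.load(path)
        np.testing.assert_allclose(back.priors, model.priors, atol=1e-12)
        np.testing.assert_allclose(back.transitions, model.transitions, atol=1e-12)
        for a, b in zip(back.emissions, model.emissions):
            np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
            np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)


class TestInvariants:
    def test_rejects_bad_probability_vectors(self):
        roi = GaussianROI([0, 0], np.eye(2))
        with pytest.raises(ValueError):
            GazeHMM([0.5, 0.6], [[0.5, 0.5], [0.5, 0.5]], [roi, roi])
        with pytest.raises(ValueError):
            GazeHMM([0.5, 0.5], [[0.9, 0.2], [0.5, 0.5]], [roi, roi])

    def test_rejects_non_positive_definite_roi(self):
        with pytest.raises(ValueError):
            GaussianROI([0, 0], [[1.0, 2.0], [2.0, 1.0]])
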