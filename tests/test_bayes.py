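"""Conditional-Gaussian evaluation network: moments, conditionals, scores."""

import numpy as np
import pytest
from scipy import stats

from posefit import bayes, synth
from posefit.bayes import (ConditionalGaussian, conditional_params,
                           fit_joint_gaussian, fit_network, standard_degree)
from posefit.body import CalibrationSet, N_SEGMENTS, NONWAIST, WAIST
from posefit.quat import canonicalize, qinv, qmul


def _clustered_quat_samples(rng, m=50, spread=0.05):
    """Unit-norm 4-vector samples in a tight bundle (no hemisphere flips)."""
    base = np.array([0.6, 0.5, -0.4, 0.48])
    base /= np.linalg.norm(base)
    X = base + spread * rng.standard_normal((m, 4))
    return X / np.linalg.norm(X, axis=1, keepdims=True)


class TestJointFit:
    def test_moments_match_two_pass_loop_oracle(self, rng):
        S = _clustered_quat_samples(rng)
        T = _clustered_quat_samples(rng)
        edge = fit_joint_gaussian(S, T, ridge=0.0)
        Z = np.concatenate([S, T], axis=1)
        mu = Z.mean(axis=0)
        cov = np.zeros((8, 8))
        for z in Z:  # naive two-pass population covariance
            cov += np.outer(z - mu, z - mu)
        cov /= len(Z)
        assert np.max(np.abs(edge.mu - mu)) < 1e-12
        assert np.max(np.abs(edge.cov - cov)) < 1e-12

    def test_identical_samples_leave_ridge_only(self, rng):
        s = _clustered_quat_samples(rng, m=1)[0]
        S = np.tile(s, (10, 1))
        edge = fit_joint_gaussian(S, S, ridge=1e-4)
        assert np.allclose(edge.mu, np.concatenate([s, s]))
        assert np.allclose(edge.cov, 1e-4 * np.eye(8))

    def test_independent_streams_have_small_cross_block(self, rng):
        m = 5000
        S = _clustered_quat_samples(rng, m=m, spread=0.05)
        T = _clustered_quat_samples(rng, m=m, spread=0.05)
        edge = fit_joint_gaussian(S, T, ridge=0.0)
        cross = edge.cov[:4, 4:]
        # 3 standard errors of a sample covariance of independent streams
        bound = 3 * 0.05 * 0.05 / np.sqrt(m)
        assert np.max(np.abs(cross)) < bound * 4

    def test_sample_count_validated(self, rng):
        S = _clustered_quat_samples(rng, m=1)
        with pytest.raises(ValueError, match="two samples"):
            fit_joint_gaussian(S, S)


class TestConditional:
    def _random_edge(self, rng):
        A = rng.standard_normal((8, 8))
        cov = A @ A.T + 0.5 * np.eye(8)
        mu = rng.standard_normal(8)
        return bayes.EdgeGaussian(child=0, parent=1, mu=mu, cov=cov)

    def test_matches_schur_complement_oracle(self, rng):
        for _ in range(100):
            edge = self._random_edge(rng)
            t_obs = rng.standard_normal(4)
            cond = conditional_params(edge, t_obs)
            S11, S12 = edge.cov[:4, :4], edge.cov[:4, 4:]
            S21, S22 = edge.cov[4:, :4], edge.cov[4:, 4:]
            mu_oracle = edge.mu[:4] + S12 @ np.linalg.solve(S22, t_obs - edge.mu[4:])
            cov_oracle = S11 - S12 @ np.linalg.solve(S22, S21)
            assert np.max(np.abs(cond.mu - mu_oracle)) < 1e-9
            assert np.max(np.abs(cond.cov - cov_oracle)) < 1e-9

    def test_independent_blocks_ignore_parent(self, rng):
        cov = np.kron(np.eye(2), np.diag([1.0, 2.0, 3.0, 4.0]))
        mu = rng.standard_normal(8)
        edge = bayes.EdgeGaussian(child=0, parent=1, mu=mu, cov=cov)
        for _ in range(5):
            cond = conditional_params(edge, rng.standard_normal(4))
            assert np.allclose(cond.mu, mu[:4])

    def test_parent_at_mean_leaves_child_mean(self, rng):
        edge = self._random_edge(rng)
        cond = conditional_params(edge, edge.mu[4:])
        assert np.allclose(cond.mu, edge.mu[:4])


class TestStandardDegree:
    def _cond(self, rng):
        A = rng.standard_normal((4, 4))
        return ConditionalGaussian(mu=rng.standard_normal(4), cov=A @ A.T + 0.3 * np.eye(4))

    def test_observation_at_mean_scores_one(self, rng):
        cond = self._cond(rng)
        assert standard_degree(cond, cond.mu) == pytest.approx(1.0)

    def test_chi_square_median_scores_half(self, rng):
        cond = ConditionalGaussian(mu=np.zeros(4), cov=np.eye(4))
        r = np.sqrt(stats.chi2.ppf(0.5, 4))
        s_obs = np.array([r, 0, 0, 0])
        assert standard_degree(cond, s_obs) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decreasing_in_mahalanobis_distance(self, rng):
        cond = self._cond(rng)
        direction = rng.standard_normal(4)
        scores = [standard_degree(cond, cond.mu + t * direction) for t in np.linspace(0, 3, 20)]
        assert np.all(np.diff(scores) <= 0)

    def test_matches_monte_carlo_exceedance_oracle(self, rng):
        # independent sampling estimate of P(d(S) > d(s)) under the
        # Mahalanobis norm, 1e5 draws
        for _ in range(3):
            cond = self._cond(rng)
            s_obs = cond.mu + rng.standard_normal(4)
            P = np.linalg.inv(cond.cov)
            draws = rng.multivariate_normal(cond.mu, cond.cov, size=100_000)
            d2 = np.einsum("ij,jk,ik->i", draws - cond.mu, P, draws - cond.mu)
            diff = s_obs - cond.mu
            mc = float(np.mean(d2 > diff @ P @ diff))
            assert standard_degree(cond, s_obs) == pytest.approx(mc, abs=0.01)

    def test_euclidean_norm_variant(self, rng):
        cond = ConditionalGaussian(mu=np.zeros(4), cov=np.eye(4))
        r = np.sqrt(stats.chi2.ppf(0.5, 4))
        s_obs = np.array([r, 0, 0, 0])
        # for an isotropic covariance both norms agree
        val = standard_degree(cond, s_obs, norm="euclidean", rng=np.random.default_rng(0))
        assert val == pytest.approx(0.5, abs=0.01)


class TestNetwork:
    def _train_instances(self, noise=0.0, n=3, seed=0):
        spec = synth.PerturbationSpec(sigma_subject=0, sigma_instance=0,
                                      sigma_sway=0, sigma_frame=noise,
                                      duration_range=(0.5, 0.5))
        tpl = synth.coaching_template()
        subj = synth.SubjectProfile.reference(1)
        rng = np.random.default_rng(seed)
        return tpl, [synth.generate_instance(tpl, subj, spec, rng) for _ in range(n)]

    def test_edge_count_and_root(self, cal):
        _, insts = self._train_instances(noise=0.01)
        net = fit_network(insts, cal)
        assert len(net.edges) == 10
        assert net.root_mu.shape == (4,)

    def test_zero_noise_conditional_means_match_template(self, cal):
        tpl, insts = self._train_instances(noise=0.0)
        net = fit_network(insts, cal)
        rel = tpl.waist_relative()
        col = {seg: k for k, seg in enumerate(NONWAIST)}
        for child, edge in net.edges.items():
            cond = conditional_params(edge, edge.mu_parent)
            expected = canonicalize(rel[child][None])[0]
            assert np.max(np.abs(np.abs(cond.mu) - np.abs(expected))) < 1e-9

    def test_json_round_trip(self, cal, tmp_path):
        _, insts = self._train_instances(noise=0.01)
        net = fit_network(insts, cal)
        net.to_json(tmp_path / "net.json")
        back = bayes.BayesNetModel.from_json(tmp_path / "net.json")
        assert back.posture == net.posture
        for child in net.edges:
            assert np.allclose(back.edges[child].mu, net.edges[child].mu)
            assert np.allclose(back.edges[child].cov, net.edges[child].cov)
        assert np.allclose(back.root_cov, net.root_cov)

    def test_mixed_postures_rejected(self, cal, templates):
        spec = synth.PerturbationSpec(duration_range=(0.2, 0.2))
        subj = synth.SubjectProfile.reference(1)
        rng = np.random.default_rng(0)
        insts = [synth.generate_instance(templates[0], subj, spec, rng),
                 synth.generate_instance(templates[1], subj, spec, rng)]
        with pytest.raises(ValueError, match="mix postures"):
            fit_network(insts, cal)

    def test_posture_mismatch_guard(self, cal):
        _, insts = self._train_instances(noise=0.01)
        net = fit_network(insts, cal)
        with pytest.raises(ValueError, match="posture"):
            bayes.evaluate_posture(net, insts[0].quats, cal, posture=7)


class TestEvaluation:
    def test_scores_lie_in_unit_interval(self, cal):
        sc = __import__("posefit.scenarios", fromlist=["build_evaluation_scenario"])
        scenario = sc.build_evaluation_scenario(
            0, spec=synth.PerturbationSpec(duration_range=(1.0, 1.0)))
        scores = bayes.score_frames(scenario.network, scenario.standard_probes[0].quats, cal)
        assert scores.shape[1] == N_SEGMENTS
        assert np.all((scores >= 0) & (scores <= 1))

    def test_injected_deviation_flagged_and_neighbours_spared(self, cal):
        from posefit.scenarios import build_evaluation_scenario
        scenario = build_evaluation_scenario(
            1, deviations=[{"RShank": ((0, 0, 1), 0.5)}],
            spec=synth.PerturbationSpec(duration_range=(1.5, 1.5)))
        inst, rec = scenario.nonstandard_probes[0]
        report = bayes.evaluate_posture(scenario.network, inst.quats, cal)
        from posefit.body import RSHANK, RTHIGH
        assert RSHANK in report.nonstandard
        assert RTHIGH not in report.nonstandard

    def test_frames_from_training_distribution_score_high(self, cal):
        from posefit.scenarios import build_evaluation_scenario
        scenario = build_evaluation_scenario(
            2, deviations=[], spec=synth.PerturbationSpec(duration_range=(1.5, 1.5)))
        scores = bayes.score_frames(scenario.network, scenario.standard_probes[0].quats, cal)
        assert np.median(scores) > 0.5
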