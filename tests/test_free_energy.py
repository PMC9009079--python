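"""TI estimator: bootstrap, quadrature, cycle combination, analyses."""

import math

import numpy as np
import pytest

from tieskit import (GradientSamples, NoiseSpec, TruthSpec, bootstrap_window,
                     ddg, estimate_transformation,
                     integrate_profile, progressive_protocol, replica_means,
                     replica_slice_estimate, simulate_transformation,
                     subsample_convergence)
from tieskit.errors import ConfigurationError
from tieskit.free_energy import FreeEnergyResult, trapezoid_weights
from tieskit.lambda_protocol import STANDARD_LAMBDAS


def _window(samples_per_replica, lam=0.0, leg="complex", tid="t"):
    return [GradientSamples(tid, leg, lam, i + 1, np.asarray(s, dtype=float))
            for i, s in enumerate(samples_per_replica)]


class TestReplicaMeans:
    def test_constant_series(self):
        assert replica_means(_window([[2, 2, 2]])).tolist() == [2.0]

    def test_discard_fraction(self):
        out = replica_means(_window([[0, 1, 2, 3]]), discard_fraction=0.5)
        assert out.tolist() == [2.5]

    def test_matches_two_pass_summation_oracle(self):
        rng = np.random.default_rng(7)
        series = rng.normal(size=1000) * 50 + 3
        expected = math.fsum(series) / len(series)  # independent oracle
        out = replica_means(_window([series]))
        assert abs(out[0] - expected) < 1e-12

    def test_empty_after_discard_rejected(self):
        with pytest.raises(ConfigurationError):
            replica_means(_window([[1.0]]), discard_fraction=1.0)


class TestBootstrapWindow:
    def test_identical_means_have_zero_se(self):
        m, se = bootstrap_window(np.array([3.0, 3.0, 3.0]), n_boot=100, seed=1)
        assert m == 3.0 and se == 0.0

    def test_two_replica_exhaustive_enumeration(self):
        # resamples of {0,2} at size 2: means {0,1,1,2}, mean 1, sd sqrt(0.5)
        m, se = bootstrap_window(np.array([0.0, 2.0]), n_boot=400_000, seed=5)
        assert m == pytest.approx(1.0, abs=5e-3)
        assert se == pytest.approx(math.sqrt(0.5), rel=5e-3)

    def test_gaussian_limit_scales_as_sd_over_sqrt_n(self):
        rng = np.random.default_rng(11)
        means = rng.normal(0.0, 2.0, size=40)
        _, se = bootstrap_window(means, n_boot=100_000, seed=2)
        expected = means.std(ddof=0) / math.sqrt(40)
        assert se == pytest.approx(expected, rel=0.02)

    def test_single_replica_warns_and_zeroes_se(self):
        with pytest.warns(UserWarning):
            m, se = bootstrap_window(np.array([1.5]), n_boot=10, seed=0)
        assert (m, se) == (1.5, 0.0)

    def test_seed_reproducibility(self):
        means = np.array([0.1, 0.9, 0.4, 0.7, 0.2])
        assert bootstrap_window(means, seed=42) == bootstrap_window(means, seed=42)


class TestIntegrateProfile:
    def test_constant_profile(self):
        pw = [(lam, 4.2, 0.0) for lam in STANDARD_LAMBDAS]
        res = integrate_profile(pw)
        assert res.delta_g == pytest.approx(4.2)
        assert res.sigma == 0.0

    def test_linear_profile_exact(self):
        pw = [(lam, lam, 0.0) for lam in STANDARD_LAMBDAS]
        assert integrate_profile(pw).delta_g == pytest.approx(0.5, abs=1e-12)

    def test_quadratic_profile_within_trapezoid_error_bound(self):
        pw = [(lam, 3 * lam ** 2, 0.0) for lam in STANDARD_LAMBDAS]
        res = integrate_profile(pw)
        h = max(np.diff(STANDARD_LAMBDAS))
        bound = h ** 2 / 4 * 6.0  # h²/4 · max|f''| for f = 3λ²
        assert abs(res.delta_g - 1.0) <= bound

    def test_sigma_propagates_through_weights(self):
        lams = (0.0, 0.5, 1.0)
        pw = [(l, 0.0, 1.0) for l in lams]
        res = integrate_profile(pw)
        w = trapezoid_weights(np.array(lams))
        assert res.sigma == pytest.approx(math.sqrt(np.sum(w ** 2)))

    def test_linearity_in_means(self):
        rng = np.random.default_rng(3)
        means = rng.normal(size=13)
        pw1 = list(zip(STANDARD_LAMBDAS, means, [0.0] * 13))
        pw3 = list(zip(STANDARD_LAMBDAS, 3 * means, [0.0] * 13))
        assert integrate_profile(pw3).delta_g == \
            pytest.approx(3 * integrate_profile(pw1).delta_g)

    def test_malformed_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            integrate_profile([(0.0, 1.0, 0.0), (0.5, 1.0, 0.0)])  # no endpoint 1
        with pytest.raises(ConfigurationError):
            integrate_profile([(0.0, 1, 0), (0.5, 1, 0), (0.5, 1, 0), (1.0, 1, 0)])


class TestThermodynamicCycle:
    def _leg(self, dg, sigma, leg="complex", tid="t"):
        pw = [(0.0, dg, 0.0), (1.0, dg, 0.0)]
        return FreeEnergyResult(leg=leg, delta_g=dg, sigma=sigma, per_window=pw,
                                ensemble_size=5, n_boot=10, seed=0,
                                transformation_id=tid)

    def test_identical_legs_cancel(self):
        res = ddg(self._leg(3.0, 0.1), self._leg(3.0, 0.1, leg="ligand"))
        assert res.ddg == 0.0

    def test_sigma_combination_3_4_5(self):
        res = ddg(self._leg(1.0, 0.3), self._leg(0.0, 0.4, leg="ligand"))
        assert res.sigma == pytest.approx(0.5)

    def test_leg_antisymmetry(self):
        c, l = self._leg(2.0, 0.1), self._leg(0.5, 0.2, leg="ligand")
        assert ddg(c, l).ddg == pytest.approx(-ddg(l, c).ddg)

    def test_mismatched_transformations_rejected(self):
        with pytest.raises(ConfigurationError):
            ddg(self._leg(1.0, 0.1, tid="t1"), self._leg(1.0, 0.1, tid="t2"))


class TestEstimateLeg:
    def test_zero_noise_recovers_trapezoid_exactly(self):
        truth = TruthSpec()
        noise = NoiseSpec(replica_offset_scale=0.0, within_replica_scale=0.0)
        c, l, true_ddg = simulate_transformation(truth, noise, n_samples=4, seed=0)
        res = estimate_transformation(c, l, n_boot=200, seed=0)
        lam = np.array(STANDARD_LAMBDAS)
        trap = (np.trapezoid(truth.profile("complex", lam), lam)
                - np.trapezoid(truth.profile("ligand", lam), lam))
        assert res.ddg == pytest.approx(trap, abs=1e-10)
        assert res.sigma == pytest.approx(0.0, abs=1e-10)

    def test_three_sigma_recovery_on_gaussian_legs(self):
        # coverage of the 3σ interval around the trapezoid of the truth,
        # under the estimator's independent-window noise model
        truth = TruthSpec()
        noise = NoiseSpec(replica_offset_scale=3.0, within_replica_scale=1.0,
                          per_window_offsets=True)
        lam = np.array(STANDARD_LAMBDAS)
        trap = (np.trapezoid(truth.profile("complex", lam), lam)
                - np.trapezoid(truth.profile("ligand", lam), lam))
        hits = 0
        n_runs = 120
        for seed in range(n_runs):
            c, l, _ = simulate_transformation(
                truth, noise, n_replicas=10, n_samples=16, seed=seed,
                transformation_id=f"cov{seed}")
            res = estimate_transformation(c, l, n_boot=400, seed=seed)
            hits += abs(res.ddg - trap) <= 3 * res.sigma
        assert hits / n_runs >= 0.96

    def test_sigma_shrinks_with_ensemble_size(self):
        truth = TruthSpec()
        noise = NoiseSpec(replica_offset_scale=4.0, within_replica_scale=0.5,
                          per_window_offsets=True)
        sigmas = []
        for n_rep in (5, 20):
            vals = []
            for seed in range(8):
                c, l, _ = simulate_transformation(
                    truth, noise, n_replicas=n_rep, n_samples=8, seed=seed,
                    transformation_id=f"s{n_rep}_{seed}")
                vals.append(estimate_transformation(c, l, n_boot=300,
                                                    seed=seed).sigma)
            sigmas.append(np.mean(vals))
        # quadrupling the ensemble should halve sigma, up to sampling noise
        assert sigmas[1] < sigmas[0] * 0.75


@pytest.fixture(scope="module")
def pair():
    truth = TruthSpec()
    noise = NoiseSpec(replica_offset_scale=3.0, per_window_offsets=True)
    c, l, _ = simulate_transformation(truth, noise, n_replicas=12,
                                      n_samples=8, seed=21)
    return c, l


class TestSubsampleConvergence:
    def test_full_size_single_subset_reproduces_direct_estimate(self, pair):
        c, l = pair
        table = subsample_convergence(c, l, sizes=[12], n_subsets=1,
                                      seed=9, n_boot=300)
        direct = estimate_transformation(c, l, n_boot=300, seed=9)
        assert table.loc[0, "mean_ddg"] == direct.ddg
        assert table.loc[0, "mean_sigma"] == direct.sigma

    def test_mean_sigma_decreases_with_size(self, pair):
        c, l = pair
        table = subsample_convergence(c, l, sizes=[3, 6, 12], n_subsets=6,
                                      seed=2, n_boot=200)
        s = table.sort_values("size")["mean_sigma"].to_numpy()
        assert s[0] > s[-1]

    def test_deterministic_for_fixed_seed(self, pair):
        c, l = pair
        t1 = subsample_convergence(c, l, sizes=[4, 8], n_subsets=3, seed=5,
                                   n_boot=100)
        t2 = subsample_convergence(c, l, sizes=[4, 8], n_subsets=3, seed=5,
                                   n_boot=100)
        assert t1.equals(t2)

    def test_oversized_request_rejected(self, pair):
        c, l = pair
        with pytest.raises(ConfigurationError):
            subsample_convergence(c, l, sizes=[13], n_subsets=1, seed=0)


class TestReplicaSlice:
    def test_zero_noise_slice_equals_ensemble_estimate(self):
        truth = TruthSpec()
        noise = NoiseSpec(replica_offset_scale=0.0, within_replica_scale=0.0)
        c, l, _ = simulate_transformation(truth, noise, n_samples=4, seed=0)
        sl = replica_slice_estimate(c, l, replica_index=2)
        full = estimate_transformation(c, l, n_boot=100, seed=0)
        assert sl.ddg == pytest.approx(full.ddg, abs=1e-9)
        assert sl.sigma is None

    def test_slice_mean_over_replicas_matches_ensemble(self):
        # trapezoid and averaging commute: the mean of per-replica TI
        # estimates equals TI of the replica-mean profile
        truth = TruthSpec()
        noise = NoiseSpec(replica_offset_scale=5.0, within_replica_scale=0.0)
        c, l, _ = simulate_transformation(truth, noise, n_replicas=5,
                                          n_samples=4, seed=13)
        slices = [replica_slice_estimate(c, l, k).ddg for k in range(1, 6)]
        # reference: integrate the exact per-window replica-average profile
        from tieskit.free_energy import integrate_profile, replica_means
        legs = []
        for ens in (c, l):
            pw = [(lam, float(np.mean(replica_means(ens.windows[lam]))), 0.0)
                  for lam in ens.lambdas]
            legs.append(integrate_profile(pw).delta_g)
        assert np.mean(slices) == pytest.approx(legs[0] - legs[1], abs=1e-9)

    def test_missing_replica_rejected(self):
        truth = TruthSpec()
        noise = NoiseSpec()
        c, l, _ = simulate_transformation(truth, noise, n_replicas=3,
                                          n_samples=4, seed=1)
        with pytest.raises(ConfigurationError):
            replica_slice_estimate(c, l, replica_index=9)


class TestProgressiveProtocol:
    def _result(self, tid, sigma, size=5):
        return type("R", (), {"transformation_id": tid, "sigma": sigma,
                              "ensemble_size": size})()

    def test_only_imprecise_transformations_escalate(self):
        plan = progressive_protocol([self._result("a", 0.6),
                                     self._result("b", 0.3)])
        by_id = {p.transformation_id: p for p in plan}
        assert by_id["a"].status == "escalate" and by_id["a"].next_size == 10
        assert by_id["b"].status == "converged"

    def test_all_precise_yields_no_escalations(self):
        plan = progressive_protocol([self._result("a", 0.2),
                                     self._result("b", 0.5)])
        assert all(p.status == "converged" for p in plan)

    def test_unconverged_at_budget_flagged(self):
        plan = progressive_protocol([self._result("a", 0.9, size=40)])
        assert plan[0].status == "unconverged_at_budget"

    def test_escalation_capped_at_max_size(self):
        plan = progressive_protocol([self._result("a", 0.9, size=38)],
                                    step=5, max_size=40)
        assert plan[0].next_size == 40
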