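"""Simulator correctness and closed-form information oracles."""

import numpy as np
import pytest

from causalinfo import (
    LinearDynamicsSpec,
    chain_spec,
    embedded_covariance,
    embedded_triple_covariance,
    gaussian_cmi_from_cov,
    instant_cmi_spec,
    oracle_cmi_instant,
    oracle_cond_dir_chain,
    oracle_dir_chain,
    oracle_example1,
    simulate_example1,
    simulate_linear,
    stationary_covariance,
)

PARAMS = dict(b1=1.0, b2=2.0, sigma_x=3.0, sigma_y=2.0, sigma_z=1.0)


class TestSimulateLinear:
    def test_no_dynamics_gives_iid(self):
        spec = LinearDynamicsSpec(("X", "Y"), np.zeros((2, 2)), np.zeros((2, 2)),
                                  np.array([1.0, 2.0]))
        data = simulate_linear(spec, 100_000, seed=0, burn_in=10)
        for name in ("X", "Y"):
            v = data.processes[name][:, 0]
            r = np.corrcoef(v[:-1], v[1:])[0, 1]
            assert abs(r) < 0.02

    def test_empirical_covariance_matches_lyapunov_solve(self):
        """Lag-0 sample covariance agrees with the solved stationary law."""
        spec = chain_spec(**PARAMS)
        data = simulate_linear(spec, 100_000, seed=1)
        S = np.hstack([data.processes[p] for p in spec.process_names])
        emp = np.cov(S.T)
        theory = stationary_covariance(spec)
        # 5% relative on each entry, with sampling slack scaled to the
        # geometric mean of the variances for the zero entries
        scale = np.sqrt(np.outer(np.diag(theory), np.diag(theory)))
        assert np.all(np.abs(emp - theory) <= 0.05 * scale)

    def test_instantaneous_coupling_scenario_runs(self):
        spec = instant_cmi_spec()
        data = simulate_linear(spec, 5_000, seed=2)
        # X carries the instantaneous copy of Y plus lagged Y
        x, y = data.processes["X"][:, 0], data.processes["Y"][:, 0]
        assert np.corrcoef(x, y)[0, 1] > 0.5

    def test_nonstationary_spec_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            LinearDynamicsSpec(("X",), np.zeros((1, 1)), np.array([[1.1]]),
                               np.array([1.0]))

    def test_singular_instantaneous_coupling_rejected(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="singular"):
            LinearDynamicsSpec(("X", "Y"), A, np.zeros((2, 2)),
                               np.array([1.0, 1.0]))

    def test_truncated_noise_respects_bound(self):
        spec = chain_spec(**PARAMS)
        spec.truncate_at = 2.0
        data = simulate_linear(spec, 20_000, seed=3, burn_in=100)
        # X has no parents, so X_i equals its (truncated) noise draw
        assert np.max(np.abs(data.processes["X"])) <= 2.0 * 3.0 + 1e-9

    def test_stationarity_after_burn_in(self):
        data = simulate_linear(chain_spec(**PARAMS), 100_000, seed=4)
        for name in ("X", "Y", "Z"):
            v = data.processes[name][:, 0]
            a, b = v[: len(v) // 2], v[len(v) // 2 :]
            se = v.std() * np.sqrt(4 / len(v))  # rough SE of a half-mean diff
            assert abs(a.mean() - b.mean()) < 5 * se

    def test_reproducible(self):
        a = simulate_linear(chain_spec(), 500, seed=5, burn_in=10)
        b = simulate_linear(chain_spec(), 500, seed=5, burn_in=10)
        np.testing.assert_array_equal(a.processes["Z"], b.processes["Z"])


class TestSimulateExample1:
    def test_x_is_white_noise(self):
        data = simulate_example1(0.5, (1.0, 1.0, 1.0), 100_000, seed=0)
        x = data.processes["X"][:, 0]
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.02

    @pytest.mark.parametrize("a", [0.0, 0.5])
    def test_variance_algebra(self, a):
        sx, sy, sz = 1.5, 1.0, 0.5
        data = simulate_example1(a, (sx, sy, sz), 100_000, seed=1)
        var_z = data.processes["Z"][:, 0].var()
        assert var_z == pytest.approx(sx**2 + sz**2, rel=0.05)
        if a == 0.0:
            var_y = data.processes["Y"][:, 0].var()
            assert var_y == pytest.approx(sx**2 + sz**2 + sy**2, rel=0.05)

    def test_unstable_a_rejected(self):
        with pytest.raises(ValueError):
            simulate_example1(1.0, (1, 1, 1), 100)


class TestOracles:
    def test_chain_dir_reproduces_reference_table(self):
        vals = {k: v.value for k, v in oracle_dir_chain(**PARAMS).items()}
        assert round(vals["X->Y"], 2) == 0.59
        assert round(vals["X->Z"], 2) == 0.57
        assert round(vals["Y->Z"], 2) == 1.99
        assert vals["Y->X"] == vals["Z->X"] == vals["Z->Y"] == 0.0

    def test_chain_cond_dir_reproduces_reference_table(self):
        vals = {k: v.value for k, v in oracle_cond_dir_chain(**PARAMS).items()}
        assert round(vals["X->Y||Z"], 2) == 0.59
        assert round(vals["Y->Z||X"], 2) == 1.42
        assert vals["X->Z||Y"] == 0.0

    def test_severed_chain_is_all_zero(self):
        vals = oracle_dir_chain(0.0, 2.0, 3.0, 2.0, 1.0)
        assert vals["X->Y"].value == 0.0
        assert vals["X->Z"].value == 0.0

    def test_conditioning_on_z_matches_pairwise_for_chain(self):
        """Z never enters Y's equation, so conditioning on it changes nothing."""
        pair = oracle_dir_chain(**PARAMS)["X->Y"].value
        cond = oracle_cond_dir_chain(**PARAMS)["X->Y||Z"].value
        assert cond == pytest.approx(pair)

    def test_instant_cmi_monotone_in_sigma_x(self):
        vals = [oracle_cmi_instant(sx, 2.0, 2.0).value for sx in (0.5, 1, 4, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_instant_cmi_scales_linearly_in_d(self):
        v1 = oracle_cmi_instant(1.0, 2.0, 2.0, d=1).value
        v7 = oracle_cmi_instant(1.0, 2.0, 2.0, d=7).value
        assert v7 == pytest.approx(7 * v1)

    def test_instant_cmi_agrees_with_covariance_route(self):
        """Closed form vs Gaussian CMI on the solved joint covariance."""
        spec = instant_cmi_spec(1.0, 2.0, 2.0)
        cov, dims = embedded_triple_covariance(spec, "X", "Y", ("Z",), 0)
        via_cov = gaussian_cmi_from_cov(cov, [0], [1], [2])
        assert via_cov == pytest.approx(oracle_cmi_instant(1.0, 2.0, 2.0).value,
                                        abs=1e-9)

    def test_example1_closed_forms(self):
        pair, cond = oracle_example1(0.5, 1.0, 1.0, 1.0)
        assert pair.value == pytest.approx(0.5 * np.log(1.5))
        assert cond.value == 0.0

    def test_example1_closed_forms_agree_with_covariance_route(self):
        """Both Example-1 values re-derived from the stationary covariance
        of the order-1 embedded triple."""
        from causalinfo import example1_spec

        spec = example1_spec(0.5, 1.0, 1.0, 1.0)
        cov, (dx, dy, dz) = embedded_triple_covariance(spec, "X", "Y", (), 1)
        pair = gaussian_cmi_from_cov(
            cov, np.arange(dx), np.arange(dx, dx + dy),
            np.arange(dx + dy, dx + dy + dz),
        )
        assert pair == pytest.approx(0.5 * np.log(1.5), abs=1e-9)
        cov2, (dx, dy, dz) = embedded_triple_covariance(spec, "X", "Y", ("Z",), 1)
        cond = gaussian_cmi_from_cov(
            cov2, np.arange(dx), np.arange(dx, dx + dy),
            np.arange(dx + dy, dx + dy + dz),
        )
        assert abs(cond) < 1e-9

    def test_example1_vanishing_signal(self):
        pair, _ = oracle_example1(0.5, 1e-8, 1.0, 1.0)
        assert pair.value < 1e-9

    def test_all_oracles_nonnegative_finite(self):
        for v in oracle_dir_chain(0.7, 1.3, 1.0, 2.0, 3.0).values():
            assert np.isfinite(v.value) and v.value >= 0
        for v in oracle_cond_dir_chain(0.7, 1.3, 1.0, 2.0, 3.0).values():
            assert np.isfinite(v.value) and v.value >= 0


class TestChainOraclesAgainstCovarianceRoute:
    """The analytic DIR formulas cross-checked against the Lyapunov-solved
    covariance of the embedded variables, at the reference parameters."""

    @pytest.mark.parametrize(
        "src,tgt,extras,key,oracle",
        [
            ("X", "Y", (), "X->Y", "dir"),
            ("Y", "Z", (), "Y->Z", "dir"),
            ("X", "Z", (), "X->Z", "dir"),
            ("Y", "X", (), "Y->X", "dir"),
            ("X", "Y", ("Z",), "X->Y||Z", "cond"),
            ("X", "Z", ("Y",), "X->Z||Y", "cond"),
            ("Y", "Z", ("X",), "Y->Z||X", "cond"),
            ("Z", "Y", ("X",), "Z->Y||X", "cond"),
        ],
    )
    def test_embedded_covariance_agrees(self, src, tgt, extras, key, oracle):
        spec = chain_spec(**PARAMS)
        cov, (dx, dy, dz) = embedded_triple_covariance(spec, src, tgt, extras, 2)
        via_cov = gaussian_cmi_from_cov(
            cov, np.arange(dx), np.arange(dx, dx + dy),
            np.arange(dx + dy, dx + dy + dz),
        )
        table = (oracle_dir_chain(**PARAMS) if oracle == "dir"
                 else oracle_cond_dir_chain(**PARAMS))
        assert via_cov == pytest.approx(table[key].value, abs=1e-8)


class TestGaussianCMIFromCov:
    def test_block_diagonal_independence_gives_zero(self):
        cov = np.diag([1.0, 2.0, 3.0])
        cov[1, 2] = cov[2, 1] = 0.8
        assert gaussian_cmi_from_cov(cov, [0], [1], [2]) == pytest.approx(0.0)

    def test_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 4))
        cov = m @ m.T + 4 * np.eye(4)
        a = gaussian_cmi_from_cov(cov, [0], [1], [2, 3])
        b = gaussian_cmi_from_cov(cov, [1], [0], [2, 3])
        assert a == pytest.approx(b)

    def test_bivariate_reduces_to_mi(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        assert gaussian_cmi_from_cov(cov, [0], [1]) == pytest.approx(
            -0.5 * np.log(1 - 0.64)
        )

    def test_non_pd_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            gaussian_cmi_from_cov(cov, [0], [1])


def test_embedded_covariance_matches_empirical_lags():
    """F^h Sigma0 cross-covariances agree with long-run sample moments."""
    spec = chain_spec(**PARAMS)
    data = simulate_linear(spec, 200_000, seed=6)
    S = np.hstack([data.processes[p] for p in spec.process_names])
    big = embedded_covariance(spec, 1)
    # empirical Cov(S_{t+1}, S_t)
    emp = (S[1:].T @ S[:-1]) / (len(S) - 1)
    theory = big[3:6, 0:3]
    sigma0 = stationary_covariance(spec)
    scale = np.sqrt(np.outer(np.diag(sigma0), np.diag(sigma0)))
    assert np.all(np.abs(emp - theory) <= 0.05 * scale)
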