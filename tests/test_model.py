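"""Core ODE system: right-hand side, simulation, scaling, logistic limit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrgo.errors import (
    DegenerateScalingError,
    InvalidInputError,
    UndefinedRatioError,
)
from carrgo.model import (
    CarrgoParams,
    DimensionlessParams,
    State,
    Trajectory,
    carrgo_rhs,
    endpoint_ratio,
    logistic_solution,
    nondimensionalize,
    redimensionalize,
    scale_trajectory,
    simulate,
    simulate_scaled,
)


def _random_params(rng):
    return CarrgoParams(
        rho=rng.uniform(0.3, 2.5),
        K=rng.uniform(5.0, 20.0),
        kappa1=rng.uniform(0.1, 3.0),
        kappa2=rng.uniform(-1.0, 1.5),
        theta=rng.uniform(0.0, 0.3),
    )


class TestRhs:
    @pytest.mark.parametrize(
        "state, params, expected",
        [
            # carrying capacity with no T cells is stationary
            ((7.0, 0.0), CarrgoParams(1.3, 7.0, 0.8, 0.5, 0.1), (0.0, 0.0)),
            # no cancer: pure exponential T-cell decay
            ((0.0, 2.0), CarrgoParams(1.3, 7.0, 0.8, 0.5, 0.1), (0.0, -0.2)),
            # direct evaluation at an interior point
            ((0.5, 0.5), CarrgoParams(1.0, 1.0, 1.0, 1.0, 0.0), (0.0, 0.25)),
        ],
    )
    def test_examples(self, state, params, expected):
        assert carrgo_rhs(state, params) == pytest.approx(expected, abs=1e-14)

    def test_accepts_state_objects(self):
        p = CarrgoParams(1.0, 1.0, 1.0, 1.0, 0.0)
        assert carrgo_rhs(State(0.5, 0.5), p) == carrgo_rhs((0.5, 0.5), p)

    def test_nonfinite_state_rejected(self):
        p = CarrgoParams(1.0, 1.0, 1.0, 1.0, 0.0)
        with pytest.raises(InvalidInputError):
            carrgo_rhs((np.nan, 0.1), p)

    def test_param_validation(self):
        with pytest.raises(InvalidInputError):
            CarrgoParams(rho=-0.1, K=1.0, kappa1=1.0, kappa2=0.0, theta=0.0)
        with pytest.raises(InvalidInputError):
            CarrgoParams(rho=0.1, K=0.0, kappa1=1.0, kappa2=0.0, theta=0.0)
        # kappa2 may be negative (exhaustion)
        CarrgoParams(rho=0.1, K=1.0, kappa1=1.0, kappa2=-5.0, theta=0.0)


class TestLogisticSolution:
    def test_initial_condition(self):
        assert logistic_solution(0.9, 10.0, 2.3, 0.0) == pytest.approx(2.3)

    def test_carrying_capacity_limit(self):
        assert logistic_solution(0.9, 10.0, 0.5, 500.0) == pytest.approx(10.0)

    def test_half_capacity_doubling(self):
        # rho = ln 2 per day from K/2 reaches 2K/3 after one day
        K = 6.0
        assert logistic_solution(np.log(2), K, K / 2, 1.0) == pytest.approx(2 * K / 3)

    @given(
        rho=st.floats(0.05, 3.0),
        K=st.floats(1.0, 50.0),
        frac=st.floats(0.01, 0.99),
        t=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_monotone_from_below(self, rho, K, frac, t):
        X0 = frac * K
        x = logistic_solution(rho, K, X0, t)
        assert X0 - 1e-12 <= x <= K + 1e-9
        assert logistic_solution(rho, K, X0, t + 1.0) >= x - 1e-12


class TestSimulate:
    def test_logistic_limit_20_random_sets(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 4.0, 60)
        for _ in range(20):
            p = _random_params(rng)
            X0 = rng.uniform(0.1, 0.5) * p.K
            traj = simulate(p, X0, 0.0, t)
            closed = logistic_solution(p.rho, p.K, X0, t)
            assert np.max(np.abs(traj.X - closed)) < 1e-6 * p.K

    def test_endpoint_matches_rk4_oracle(self):
        """Adaptive solution agrees with an independent fixed-step RK4."""

        def rk4(p, X0, Y0, t_end, n_steps):
            h = t_end / n_steps
            z = np.array([X0, Y0], float)

            def f(z):
                X, Y = z
                return np.array(
                    [
                        p.rho * X * (1 - X / p.K) - p.kappa1 * X * Y,
                        p.kappa2 * X * Y - p.theta * Y,
                    ]
                )

            for _ in range(n_steps):
                k1 = f(z)
                k2 = f(z + h / 2 * k1)
                k3 = f(z + h / 2 * k2)
                k4 = f(z + h * k3)
                z = z + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return z

        rng = np.random.default_rng(3)
        for _ in range(5):
            p = _random_params(rng)
            X0, Y0 = rng.uniform(0.5, 3.0), rng.uniform(0.05, 0.5)
            traj = simulate(p, X0, Y0, np.linspace(0, 3.0, 31))
            coarse = rk4(p, X0, Y0, 3.0, 3000)
            fine = rk4(p, X0, Y0, 3.0, 6000)
            # step-halving confirms the oracle itself is converged
            assert np.allclose(coarse, fine, rtol=1e-7, atol=1e-10)
            assert traj.X[-1] == pytest.approx(fine[0], rel=1e-5)
            assert traj.Y[-1] == pytest.approx(fine[1], rel=1e-5, abs=1e-8)

    def test_scaled_system_converges_to_coexistence_point(self):
        dp = DimensionlessParams(A=0.14, B=1.6)
        traj = simulate_scaled(dp, 0.5, 0.3, np.linspace(0, 300, 600))
        assert traj.X[-1] == pytest.approx(0.0875, abs=1e-3)
        assert traj.Y[-1] == pytest.approx(0.9125, abs=1e-3)

    def test_nonnegativity(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 6, 80)
        for _ in range(10):
            p = _random_params(rng)
            traj = simulate(p, rng.uniform(0, 2), rng.uniform(0, 1), t)
            assert traj.X.min() >= 0.0 and traj.Y.min() >= 0.0

    def test_invalid_initial_conditions(self):
        p = CarrgoParams(1.0, 1.0, 1.0, 1.0, 0.0)
        with pytest.raises(InvalidInputError):
            simulate(p, -0.1, 0.0, [0, 1])
        with pytest.raises(InvalidInputError):
            simulate(p, 0.1, 0.0, [0, 1, 1])  # non-increasing grid


class TestScaling:
    def test_dimensionless_examples(self):
        p = CarrgoParams(rho=1.0, K=1.0, kappa1=1.0, kappa2=1.6, theta=0.14)
        dp = nondimensionalize(p)
        assert (dp.A, dp.B) == pytest.approx((0.14, 1.6))
        assert nondimensionalize(p.replace(theta=0.0)).A == 0.0

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = _random_params(rng)
            back = redimensionalize(nondimensionalize(p), p.rho, p.K, p.kappa1)
            for name in ("rho", "K", "kappa1", "kappa2", "theta"):
                assert getattr(back, name) == pytest.approx(getattr(p, name), rel=1e-12)

    def test_degenerate_rho(self):
        p = CarrgoParams(rho=0.0, K=1.0, kappa1=1.0, kappa2=0.5, theta=0.1)
        with pytest.raises(DegenerateScalingError):
            nondimensionalize(p)

    def test_scaling_equivalence_20_random_sets(self):
        """Scaling a dimensional run equals running the scaled system."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = _random_params(rng)
            X0, Y0 = rng.uniform(0.5, 3.0), rng.uniform(0.05, 0.5)
            t = np.linspace(0, 3.0, 40)
            scaled = scale_trajectory(simulate(p, X0, Y0, t), p)
            direct = simulate_scaled(
                nondimensionalize(p), X0 / p.K, p.kappa1 * Y0 / p.rho, t * p.rho
            )
            assert np.allclose(scaled.X, direct.X, rtol=1e-6, atol=1e-9)
            assert np.allclose(scaled.Y, direct.Y, rtol=1e-6, atol=1e-9)

    def test_kappa2_sign_carries_to_B(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = _random_params(rng)
            assert np.sign(nondimensionalize(p).B) == np.sign(p.kappa2)


class TestTrajectory:
    def test_invariants(self):
        with pytest.raises(InvalidInputError):
            Trajectory(t=[0, 1, 1], X=[1, 1, 1], Y=[0, 0, 0])
        with pytest.raises(InvalidInputError):
            Trajectory(t=[0, 1], X=[1, 1, 1], Y=[0, 0])

    def test_to_frame(self):
        traj = Trajectory(t=[0.0, 1.0], X=[1.0, 2.0], Y=[0.1, 0.2], scaled=True)
        df = traj.to_frame()
        assert list(df.columns) == ["t_days", "X", "Y", "scaled_flag"]
        assert df.scaled_flag.all()


class TestEndpointRatio:
    def test_equal_densities(self):
        traj = Trajectory(t=[0.0, 1.0], X=[1.0, 2.0], Y=[0.5, 2.0])
        assert endpoint_ratio(traj) == pytest.approx(1.0)

    def test_collapsed_t_cells(self):
        traj = Trajectory(t=[0.0, 1.0], X=[1.0, 2.0], Y=[0.5, 1e-12])
        with pytest.raises(UndefinedRatioError):
            endpoint_ratio(traj)

    def test_successful_treatment_drives_ratio_to_zero(self):
        # A = 0, B > 0: cancer eliminated, residual T cells persist
        traj = simulate_scaled(
            DimensionlessParams(A=0.0, B=0.2), 0.5, 1.2, np.linspace(0, 150, 300)
        )
        assert endpoint_ratio(traj) < 1e-4
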