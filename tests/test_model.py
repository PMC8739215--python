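"""Vector field, sigmoid, drives, and RK4 simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcnmm import (DriveSpec, ModelParameters, SimulationDiverged,
                   drive_value, simulate, sigmoid, sigmoid_derivative,
                   vector_field)
from tcnmm.model import InvalidState, cortical_mean
from tcnmm.params import _VEC_KEYS


class TestSigmoid:
    def test_midpoint_and_value(self):
        assert sigmoid(0.0, 250000.0) == pytest.approx(0.5)
        assert sigmoid(1.0, 250000.0) == pytest.approx(1 / (1 + 1 / 250000.0))

    @given(st.floats(-50, 50))
    @settings(deadline=None)
    def test_complementarity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_and_stable_at_extremes(self):
        xs = np.linspace(-50, 50, 201)
        ys = sigmoid(xs)
        assert np.all(np.diff(ys) >= 0)
        assert np.all(np.isfinite(ys))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidState):
            sigmoid(float("nan"))
        with pytest.raises(ValueError):
            sigmoid(0.0, epsilon=0.5)

    def test_derivative_against_finite_difference(self):
        # central differences; in the saturated tails the difference
        # itself underflows toward rounding noise, so the relative check
        # applies where the slope is resolvable and an absolute one beyond
        h = 1e-6
        for x in np.linspace(-2, 2, 17):
            fd = (sigmoid(x + h) - sigmoid(x - h)) / (2 * h)
            if abs(x) <= 0.6:
                assert sigmoid_derivative(x) == pytest.approx(fd, rel=1e-6)
            else:
                assert sigmoid_derivative(x) == pytest.approx(fd, abs=1e-8)

    def test_derivative_limits(self):
        assert sigmoid_derivative(0.0, 250000.0) == pytest.approx(
            np.log(250000.0) / 4)
        assert sigmoid_derivative(40.0) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_derivative(-40.0) == pytest.approx(0.0, abs=1e-12)


class TestDrive:
    def test_constant_mode(self):
        d = DriveSpec(B_Npy=0.7, B_Ntc=0.1)
        for t in (0.0, 0.3, 17.2):
            assert drive_value(d, t) == (0.7, 0.1)

    def test_sinusoid_value(self):
        d = DriveSpec(B_Npy=0.7, a_py=0.02, fpy=1.0)
        npy, _ = drive_value(d, 0.25)  # sin(pi/2) = 1
        assert npy == pytest.approx(0.72)

    def test_default_biases(self):
        d = DriveSpec()
        assert (d.B_Npy, d.B_Ntc) == (0.7, 0.1)

    def test_gains_multiply_whole_drive(self, params):
        p = params.replace(c_Npy_py=2.0)
        d = DriveSpec(B_Npy=0.7)
        npy, ntc = drive_value(d, 0.0, p)
        assert npy == pytest.approx(1.4)
        assert ntc == pytest.approx(0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            DriveSpec(a_py=-0.1)
        with pytest.raises(ValueError):
            DriveSpec(ftc=-1.0)


class TestVectorField:
    def test_decoupled_fixed_point_at_offsets(self):
        p = ModelParameters(**{k: 0.0 for k in _VEC_KEYS if k.startswith("c_")})
        s = np.array([p.h_py, p.h_i1, p.h_i2, p.h_ei, p.h_tc, p.h_re])
        assert np.allclose(vector_field(s, p, 0.0, 0.0), 0.0, atol=1e-14)

    def test_kernel_matches_reference(self, params, rng):
        """The jitted kernel's RHS equals the reference implementation."""
        from tcnmm.model import _field
        q = params.to_vector()
        for _ in range(25):
            s = rng.uniform(-3, 1, 6)
            out = np.empty(6)
            _field(s, q, 0.7, 0.1, out)
            assert np.allclose(out, vector_field(s, params, 0.7, 0.1),
                               rtol=1e-13, atol=1e-13)

    def test_ei_ablation_freezes_ei(self, rng):
        p = ModelParameters(ei_enabled=False)
        s = rng.uniform(-2, 1, 6)
        d = vector_field(s, p, 0.7, 0.1)
        assert d[3] == 0.0
        # EI value must not influence the other equations
        s2 = s.copy()
        s2[3] += 1.7
        d2 = vector_field(s2, p, 0.7, 0.1)
        assert np.allclose(np.delete(d, 3), np.delete(d2, 3))

    def test_invalid_state_raises(self, params):
        with pytest.raises(InvalidState):
            vector_field(np.full(6, np.nan), params, 0.7, 0.1)


class TestSimulate:
    def test_determinism(self, params, constant_drive):
        a = simulate(params, constant_drive, duration=5.0)
        b = simulate(params, constant_drive, duration=5.0)
        assert np.array_equal(a.output, b.output)
        assert np.array_equal(a.states, b.states)

    def test_grid_and_output_definition(self, default_run, params):
        r = default_run
        assert len(r.times) == len(r.output) == r.states.shape[0]
        assert np.allclose(np.diff(r.times), r.dt)
        assert np.allclose(r.output, r.states[:, :4].mean(axis=1))

    def test_output_mean_of_three_when_ablated(self):
        p = ModelParameters(ei_enabled=False)
        r = simulate(p, duration=2.0)
        assert np.allclose(r.output, r.states[:, :3].mean(axis=1))
        assert np.allclose(r.states[:, 3], 0.0)

    def test_equilibrium_invariance(self, params, constant_drive):
        from tcnmm import find_equilibria
        rec = min((r for r in find_equilibria(params, constant_drive)
                   if r.stability.startswith("stable")),
                  key=lambda r: np.linalg.norm(r.state))
        r = simulate(params, constant_drive, s0=rec.state)
        assert np.abs(r.states - rec.state).max() < 1e-6

    def test_rk4_exponential_decay_order(self):
        """Decoupled linear decay: one RK4 step reproduces exp(-h) to
        the 4th-order truncation term."""
        p = ModelParameters(
            **{k: 0.0 for k in _VEC_KEYS if k.startswith("c_")},
            tau_1=1.0, tau_2=1.0, tau_3=1.0, tau_4=1.0, tau_5=1.0,
            tau_6=1.0, h_py=0, h_i1=0, h_i2=0, h_ei=0, h_tc=0, h_re=0)
        d = DriveSpec(B_Npy=0.0, B_Ntc=0.0)
        s0 = np.ones(6)
        for h in (0.1, 0.05):
            r = simulate(p, d, duration=2 * h, dt=h, s0=s0)
            step_err = abs(r.states[1, 0] - np.exp(-h))
            assert step_err < h ** 5  # |R4(h) - e^-h| ~ h^5/120

    def test_rk4_fourth_order_convergence_full_model(self, params):
        """Halving dt shrinks the endpoint error ~16x on the full model
        (measured in the asymptotic regime: the near-step transfer
        function keeps the production step outside it)."""
        s0 = np.full(6, -0.5)
        d = DriveSpec()
        base = 0.001
        ref = simulate(params, d, duration=1.0, dt=base / 8, s0=s0)
        errs = []
        for dt in (base, base / 2):
            r = simulate(params, d, duration=1.0, dt=dt, s0=s0)
            errs.append(np.linalg.norm(r.states[-1] - ref.states[-1]))
        ratio = errs[0] / errs[1]
        assert 10 < ratio < 24

    def test_divergence_guard(self, params, constant_drive):
        with pytest.raises(SimulationDiverged) as exc:
            simulate(params, constant_drive, duration=1.0,
                     s0=np.full(6, 2e6))
        assert exc.value.step >= 1

    def test_validation(self, params, constant_drive):
        with pytest.raises(ValueError):
            simulate(params, constant_drive, duration=0.0)
        with pytest.raises(ValueError):
            simulate(params, constant_drive, duration=0.003, dt=0.0039)

    def test_csv_round_trip(self, tmp_path, params, constant_drive):
        import pandas as pd
        r = simulate(params, constant_drive, duration=0.1)
        path = tmp_path / "traj.csv"
        r.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "PY", "I1", "I2", "EI", "TC",
                                    "RE", "output"]
        assert np.allclose(df["output"].to_numpy(), r.output)
        assert np.allclose(df[["PY", "I1", "I2", "EI", "TC", "RE"]].to_numpy(),
                           r.states)


class TestParameters:
    def test_defaults_match_reference_parameterization(self):
        p = ModelParameters()
        assert (p.c_py_py, p.c_py_i1, p.c_i1_py) == (1.89, 4.0, 1.8)
        assert (p.c_tc_re, p.c_re_tc, p.c_re_re) == (10.0, 1.4, 0.01)
        assert (p.c_py_ei, p.c_i1_ei, p.c_tc_ei) == (0.8, 0.3, 4.5)
        assert (p.tau_1, p.tau_2, p.tau_3) == (21.5, 31.5, 0.1)
        assert (p.h_py, p.h_re, p.epsilon) == (-0.4, -3.2, 250000.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(tau_2=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(epsilon=1.0)
        with pytest.raises(ValueError):
            ModelParameters(c_py_py=-0.2)

    def test_round_trip_files(self, tmp_path):
        p = ModelParameters(c_tc_ei=3.5)
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            p.save(path)
            assert ModelParameters.load(path) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="c_bogus"):
            ModelParameters.from_dict({"c_bogus": 1.0})
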