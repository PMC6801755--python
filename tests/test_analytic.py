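import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinstep import (
    MotorParams,
    StallDivergenceError,
    atp_per_forward_step,
    atp_per_step,
    characteristic_distance,
    diffusion_constant,
    dwell_time,
    efficiency,
    max_power,
    nl_docking_energy,
    p_escape,
    p_forward,
    power,
    randomness,
    reduced_ratio,
    scan,
    stall_force,
    stepping_ratio,
    velocity,
)
from kinstep.analytic import futile_atpase_rate, observables

F_GRID = np.linspace(-5.0, 5.0, 41)


class TestPointValues:
    """Frozen direct evaluations of the closed forms."""

    def test_reduced_ratio(self, dmk):
        assert reduced_ratio(0.0, dmk) == pytest.approx(890.0)
        assert reduced_ratio(dmk.FS, dmk) == pytest.approx(1.0)
        assert reduced_ratio(4.0, dmk) == pytest.approx(29.832868, rel=1e-6)

    def test_p_escape(self, hsk, hsk6aa):
        assert p_escape(3.0, hsk) == 1.0 and p_escape(-3.0, hsk) == 1.0
        assert p_escape(0.0, hsk6aa) == pytest.approx(0.33)
        assert p_escape(2.0, hsk6aa) == pytest.approx(0.587938, rel=1e-5)
        # symmetric in |F|
        assert p_escape(-2.0, hsk6aa) == pytest.approx(p_escape(2.0, hsk6aa))

    def test_p_forward(self, dmk):
        assert p_forward(0.0, dmk) == pytest.approx(0.9656420, rel=1e-6)
        assert p_forward(dmk.FS, dmk) == pytest.approx(3 / 98, rel=1e-9)
        assert p_forward(60.0, dmk) == pytest.approx(0.0, abs=1e-9)

    def test_p_forward_inert_leading_head(self):
        p = MotorParams(name="x", r0=100, FS=7, k_plus=100, k_minus=0.0)
        assert p_forward(0.0, p) == 1.0

    def test_stepping_ratio(self, dmk, hsk6aa):
        assert stepping_ratio(0.0, dmk) == pytest.approx(890.0)
        assert stepping_ratio(dmk.FS, dmk) == pytest.approx(1.0)
        assert stepping_ratio(2.0, hsk6aa) == pytest.approx(72.336, rel=1e-4)

    def test_velocity(self, dmk, hskcl6aa):
        assert velocity(0.0, dmk) == pytest.approx(751.390, rel=1e-5)
        assert velocity(dmk.FS, dmk) == pytest.approx(0.0, abs=1e-9)
        assert velocity(0.0, hskcl6aa) == pytest.approx(276.722, rel=1e-5)

    def test_dwell_time(self, dmk):
        from kinstep import preset

        assert dwell_time(0.0, preset("Bovine")) == pytest.approx(8.7219e-3, rel=1e-4)
        assert dwell_time(dmk.FS, dmk) == pytest.approx(0.171930, rel=1e-5)
        # overwhelming forward bias: dwell approaches 1/k+
        fast = MotorParams(name="x", r0=1e6, FS=50, k_plus=100, k_minus=3)
        assert dwell_time(0.0, fast) == pytest.approx(1 / 100, rel=1e-3)

    def test_diffusion_constant(self, dmk):
        assert diffusion_constant(0.0, dmk) == pytest.approx(3087.63, rel=1e-5)
        assert np.all(diffusion_constant(F_GRID, dmk) > 0)

    def test_randomness(self, dmk, hskcl6aa):
        assert randomness(0.0, dmk) == pytest.approx(891 / 889, rel=1e-9)
        assert randomness(0.0, hskcl6aa) == pytest.approx(601 / 599, rel=1e-9)

    def test_atp_per_forward_step(self, dmk, hskcl6aa):
        assert atp_per_forward_step(0.0, hskcl6aa) == pytest.approx(3.28, abs=0.01)
        assert atp_per_forward_step(0.0, dmk) == pytest.approx(1.068283, rel=1e-6)

    def test_atp_per_step(self, dmk, kif17):
        assert atp_per_step(0.0, kif17) == pytest.approx(1.805, abs=0.001)
        assert atp_per_step(0.0, dmk) == pytest.approx(1.067084, rel=1e-6)

    def test_power(self, hskcl6aa, any_preset):
        assert power(0.0, any_preset) == 0.0
        assert power(stall_force(any_preset), any_preset) == pytest.approx(0.0, abs=1e-4)
        assert power(2.0, hskcl6aa) == pytest.approx(85.88, rel=1e-3)

    def test_efficiency(self, hsk):
        assert efficiency(2.0, hsk) == pytest.approx(0.161, abs=0.001)
        assert efficiency(0.0, hsk) == 0.0
        assert efficiency(2.0, hsk, deltaG=40.0) == pytest.approx(
            efficiency(2.0, hsk) / 2)

    def test_stall_force(self, hsk, hsk6aa, kif17):
        assert stall_force(hsk) == 7.0  # wild-type: exactly FS
        assert stall_force(hsk6aa) == pytest.approx(6.032, abs=0.01)
        assert 7.3 < stall_force(kif17) < 7.5

    def test_nl_docking_energy(self, dmk):
        from kinstep import preset

        assert nl_docking_energy(dmk) == pytest.approx(3.34, abs=0.01)
        assert nl_docking_energy(preset("Bovine")) == pytest.approx(1.56, abs=0.01)
        assert nl_docking_energy(preset("HsK-CL")) == pytest.approx(3.1104, rel=1e-4)
        ed, ded = nl_docking_energy(dmk, with_error=True)
        assert ded == pytest.approx(0.28, abs=0.005)

    def test_nl_docking_energy_inert_leading_head(self):
        p = MotorParams(name="x", r0=100, FS=7, k_plus=100, k_minus=0.0)
        with pytest.raises(ValueError):
            nl_docking_energy(p)

    def test_characteristic_distance(self):
        from kinstep import preset

        fig_fit = MotorParams(name="fit", r0=900, FS=7, k_plus=90.5, k_minus=4)
        assert characteristic_distance(fig_fit) == pytest.approx(4.0, abs=0.1)
        assert characteristic_distance(preset("Bovine")) == pytest.approx(2.92, abs=0.005)
        near_one = MotorParams(name="x", r0=1 + 1e-12, FS=7, k_plus=10, k_minus=1)
        assert characteristic_distance(near_one) == pytest.approx(0.0, abs=1e-9)


class TestIdentitiesAndProperties:
    def test_wild_type_reduction(self, any_preset):
        """With P0 = 1 the generalized expressions collapse to the wild-type
        forms at machine precision, for every force."""
        p = any_preset.with_(P0_zero=1.0, errors=None)
        rho = p.r0 ** (1.0 - F_GRID / p.FS)
        K = p.k_plus / p.k_minus
        np.testing.assert_allclose(stepping_ratio(F_GRID, p), rho, rtol=1e-12)
        np.testing.assert_allclose(
            velocity(F_GRID, p), (rho - 1) / (rho + K) * p.k_plus * p.d, rtol=1e-12)
        np.testing.assert_allclose(
            dwell_time(F_GRID, p), (rho + K) / (rho + 1) / p.k_plus, rtol=1e-12)
        np.testing.assert_allclose(
            diffusion_constant(F_GRID, p),
            0.5 * (rho + 1) / (rho + K) * p.k_plus * p.d ** 2, rtol=1e-12)
        np.testing.assert_allclose(
            atp_per_forward_step(F_GRID, p),
            (1 + 1 / K) * (rho + K) / rho, rtol=1e-12)

    def test_continuity_at_zero_force(self, any_preset):
        """The signed-force branches agree across F = 0."""
        eps = 1e-9
        for fn in (stepping_ratio, velocity, dwell_time, diffusion_constant,
                   atp_per_forward_step, atp_per_step, randomness):
            left, mid, right = fn(-eps, any_preset), fn(0.0, any_preset), fn(eps, any_preset)
            assert left == pytest.approx(mid, rel=1e-6)
            assert right == pytest.approx(mid, rel=1e-6)

    @pytest.mark.parametrize("F", [0.0, 2.0, 4.0])
    def test_dwell_series_matches_closed_form(self, any_preset, F):
        """Independent oracle: the dwell time summed over the number of
        ATPase events preceding a step converges to the closed form.

        Per ATPase event (rate k+ + k-) the motor steps with probability
        q = [a PE k+ + b (1-PE) k-]/(k+ + k-); the dwell before a step
        after n events is n/(k+ + k-), weighted by q (1-q)^(n-1).
        """
        p = any_preset
        from kinstep.analytic import _sides

        rho, a, b = _sides(np.asarray([F]), p)
        PE = p_forward(F, p)
        ktot = p.k_plus + p.k_minus
        q = (a[0] * PE * p.k_plus + b[0] * (1 - PE) * p.k_minus) / ktot
        n_terms = min(200_000, max(200, int(math.log(1e-14) / math.log(1 - q))))
        n = np.arange(1, n_terms + 1)
        series = np.sum(n / ktot * q * (1 - q) ** (n - 1))
        assert series == pytest.approx(dwell_time(F, p), rel=1e-9)

    def test_randomness_consistency(self, any_preset):
        """R = 2D/(v d) wherever the velocity is nonzero."""
        F = F_GRID[np.abs(velocity(F_GRID, any_preset)) > 1e-6]
        np.testing.assert_allclose(
            randomness(F, any_preset),
            2 * diffusion_constant(F, any_preset) / (velocity(F, any_preset) * any_preset.d),
            rtol=1e-12)

    def test_velocity_dwell_ratio_identity(self, any_preset):
        """v = (d/Td) (r-1)/(r+1): net displacement per dwell."""
        r = stepping_ratio(F_GRID, any_preset)
        expected = any_preset.d / dwell_time(F_GRID, any_preset) * (r - 1) / (r + 1)
        np.testing.assert_allclose(velocity(F_GRID, any_preset), expected, rtol=1e-12)

    def test_atp_counts_ordering(self, any_preset):
        NF = atp_per_forward_step(F_GRID, any_preset)
        N = atp_per_step(F_GRID, any_preset)
        assert np.all(NF >= N) and np.all(N >= 1.0 - 1e-12)

    def test_monotonicity_below_stall(self, any_preset):
        F = np.linspace(0.0, stall_force(any_preset), 200)
        assert np.all(np.diff(stepping_ratio(F, any_preset)) < 0)
        assert np.all(np.diff(velocity(F, any_preset)) < 0)

    def test_power_has_unique_interior_maximum(self, any_preset):
        F_stall = stall_force(any_preset)
        F = np.linspace(1e-6, F_stall - 1e-6, 400)
        W = power(F, any_preset)
        k = int(np.argmax(W))
        assert 0 < k < len(F) - 1
        # single sign change of the discrete derivative
        signs = np.sign(np.diff(W))
        assert np.all(signs[:k] >= 0) and np.all(signs[k:] <= 0)
        F_opt, W_max = max_power(any_preset)
        assert W_max >= W.max() - 1e-6 and 0 < F_opt < F_stall

    def test_docking_energy_round_trip(self, any_preset):
        """Forward map r0 = (k+/k-) exp(ED/kBT) inverts the estimator."""
        ed = nl_docking_energy(any_preset)
        r0 = any_preset.k_plus / any_preset.k_minus * math.exp(ed)
        assert r0 == pytest.approx(any_preset.r0, rel=1e-12)

    def test_futile_rate_complements_stepping(self, any_preset):
        w0 = futile_atpase_rate(F_GRID, any_preset)
        assert np.all(w0 >= 0)
        total = 1.0 / dwell_time(F_GRID, any_preset) + w0
        np.testing.assert_allclose(total, any_preset.k_plus + any_preset.k_minus,
                                   rtol=1e-12)


class TestDivergenceHandling:
    def test_randomness_at_stall_raises(self, hsk):
        with pytest.raises(StallDivergenceError):
            randomness(hsk.FS, hsk)

    def test_randomness_array_nan_with_warning(self, hsk):
        with pytest.warns(RuntimeWarning):
            out = randomness(np.array([0.0, hsk.FS]), hsk)
        assert math.isnan(out[1]) and math.isfinite(out[0])

    def test_observables_at_stall(self, hsk):
        obs = observables(hsk.FS, hsk)
        assert math.isnan(obs.R) and obs.v == pytest.approx(0.0, abs=1e-9)


class TestScan:
    def test_schema_and_monotone_velocity(self, hsk):
        df = scan(hsk, np.linspace(0, 7, 29))
        assert list(df.columns) == [
            "force_pN", "ratio", "velocity_nm_s", "dwell_s", "D_nm2_s",
            "randomness", "NF", "N", "power_kBT_s", "efficiency"]
        assert np.all(np.diff(df["velocity_nm_s"]) < 0)
        assert df["power_kBT_s"].iloc[0] == 0.0
        assert math.isnan(df["randomness"].iloc[-1])  # stall row


# hypothesis strategies for arbitrary valid motors
motor_st = st.builds(
    lambda r0, FS, kp, km, p0: MotorParams(
        name="h", r0=r0, FS=FS, k_plus=kp, k_minus=km, P0_zero=p0),
    r0=st.floats(1.5, 5e3), FS=st.floats(1.0, 15.0),
    kp=st.floats(1.0, 500.0), km=st.floats(0.5, 50.0),
    p0=st.floats(0.05, 1.0),
)


@settings(derandomize=True, max_examples=50)
@given(p=motor_st, F=st.floats(-10.0, 10.0))
def test_escape_probability_bounds(p, F):
    q = p_escape(F, p)
    assert p.P0_zero - 1e-12 <= q <= 1.0 + 1e-12


@settings(derandomize=True, max_examples=50)
@given(p=motor_st, F=st.floats(-10.0, 10.0))
def test_forward_probability_bounds_and_zero_force_ratio(p, F):
    assert 0.0 < p_forward(F, p) <= 1.0  # rounds to 1.0 at extreme assisting force
    assert stepping_ratio(0.0, p) == pytest.approx(p.r0, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(p=motor_st)
def test_stall_force_never_exceeds_scale(p):
    assert stall_force(p) <= p.FS + 1e-9
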