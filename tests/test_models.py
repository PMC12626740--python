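import math

import numpy as np
import pytest
from scipy.stats import norm

from ntcpkit.dvh import make_differential
from ntcpkit.models import (
    RS_PRESETS,
    LKBParams,
    RSParams,
    eqd2_dvh,
    geud,
    lkb_ntcp,
    max_normalized_slope,
    poisson_response,
    rs_ntcp,
)

from conftest import random_differential


def serial_closed_form(d, p):
    """Independent oracle for s = 1: NTCP = 1 - prod (1 - P_i)^dv_i."""
    probs = np.array([poisson_response(dose, p) for dose in d.bin_dose])
    return 1.0 - np.prod((1.0 - probs) ** d.bin_volume)


def parallel_limit(d, p):
    """Independent oracle for s -> 0: exp(-prod (-ln P_i)^dv_i)."""
    probs = np.array([poisson_response(dose, p) for dose in d.bin_dose])
    return math.exp(-np.prod((-np.log(probs)) ** d.bin_volume))


class TestPoissonResponse:
    def test_half_at_d50(self, parotid_params, lacrimal_params):
        assert poisson_response(24.9, parotid_params) == pytest.approx(0.5, abs=1e-12)
        assert poisson_response(63.9, lacrimal_params) == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_scalar_oracle(self, parotid_params):
        expected = 2.0 ** (-math.exp(math.e * 0.26))  # direct closed form
        assert poisson_response(0.0, parotid_params) == pytest.approx(expected, abs=1e-12)

    def test_saturation(self, parotid_params):
        assert poisson_response(10 * 24.9, parotid_params) > 0.99
        assert poisson_response(100 * 24.9, parotid_params) > 1.0 - 1e-9

    def test_strictly_increasing(self, parotid_params):
        doses = np.linspace(0.0, 100.0, 500)
        probs = poisson_response(doses, parotid_params)
        assert np.all(np.diff(probs) > 0)

    def test_negative_dose_errors(self, parotid_params):
        with pytest.raises(ValueError):
            poisson_response(-1.0, parotid_params)


class TestRSNtcp:
    def test_single_bin_at_d50(self, parotid_params):
        d = make_differential([24.9], [1.0])
        assert rs_ntcp(d, parotid_params) == pytest.approx(0.5, abs=1e-9)

    def test_two_bin_parallel_limit(self, parotid_params):
        d = make_differential([0.0, 24.9], [0.5, 0.5])
        p0 = poisson_response(0.0, parotid_params)
        oracle = math.exp(-math.sqrt(math.log(2.0) * (-math.log(p0))))
        assert rs_ntcp(d, parotid_params) == pytest.approx(oracle, abs=1e-3)
        assert rs_ntcp(d, parotid_params) == pytest.approx(0.373, abs=2e-3)

    @pytest.mark.parametrize("s", [1e-4, 0.01, 1.0, 5.0])
    def test_uniform_dose_reduction(self, s, rng):
        p = RSParams(d50=24.9, gamma=0.26, s=s)
        for dose in rng.uniform(0.0, 60.0, size=10):
            d = make_differential([dose], [1.0])
            assert abs(rs_ntcp(d, p) - poisson_response(dose, p)) < 1e-9

    @pytest.mark.parametrize("s", [1e-4, 1e-3])
    def test_parallel_limit_random_dvhs(self, s, rng):
        for _ in range(20):
            d = random_differential(rng)
            p = RSParams(d50=24.9, gamma=0.26, s=s)
            assert rs_ntcp(d, p) == pytest.approx(parallel_limit(d, p), abs=1e-3)

    def test_serial_closed_form(self, rng):
        p = RSParams(d50=24.9, gamma=0.26, s=1.0)
        for _ in range(20):
            d = random_differential(rng)
            assert rs_ntcp(d, p) == pytest.approx(serial_closed_form(d, p), abs=1e-12)

    def test_in_unit_interval(self, rng, parotid_params):
        for _ in range(30):
            assert 0.0 <= rs_ntcp(random_differential(rng), parotid_params) <= 1.0

    def test_monotone_in_dose(self, rng, parotid_params):
        for _ in range(15):
            d = random_differential(rng, n_bins=6)
            base = rs_ntcp(d, parotid_params)
            bumped = make_differential(d.bin_dose + 1.0, d.bin_volume)
            assert rs_ntcp(bumped, parotid_params) >= base - 1e-12

    def test_zero_dose_baseline_risk(self, parotid_params):
        # shallow-gamma parameterization has a nonzero risk floor at 0 Gy
        d = make_differential([0.0], [1.0])
        floor = 2.0 ** (-math.exp(math.e * 0.26))
        assert rs_ntcp(d, parotid_params) == pytest.approx(floor, abs=1e-9)
        assert floor == pytest.approx(0.245, abs=5e-4)

    def test_extreme_dose_saturates_to_one(self, parotid_params):
        d = make_differential([5000.0], [1.0])
        assert rs_ntcp(d, parotid_params) == pytest.approx(1.0, abs=1e-9)


class TestGeud:
    def test_uniform_identity(self):
        d = make_differential([30.0], [1.0])
        for n in (0.1, 0.5, 1.0, 3.0):
            assert geud(d, n) == pytest.approx(30.0, rel=1e-12)

    def test_n_one_is_mean_dose(self, rng):
        for _ in range(10):
            d = random_differential(rng)
            assert geud(d, 1.0) == pytest.approx(
                float(np.dot(d.bin_dose, d.bin_volume)), rel=1e-12
            )

    def test_small_n_serial_like(self):
        d = make_differential([10.0, 30.0], [0.5, 0.5])
        assert geud(d, 0.1) > 27.0

    def test_monotone_in_n(self):
        d = make_differential([10.0, 30.0], [0.5, 0.5])
        ns = np.linspace(0.05, 3.0, 40)
        vals = [geud(d, n) for n in ns]
        assert np.all(np.diff(vals) < 1e-9)  # non-increasing as n grows

    def test_bounded_by_extremes(self, rng):
        for _ in range(10):
            d = random_differential(rng)
            g = geud(d, 0.7)
            assert d.bin_dose.min() - 1e-9 <= g <= d.bin_dose.max() + 1e-9

    def test_nonpositive_n_errors(self):
        with pytest.raises(ValueError):
            geud(make_differential([30.0], [1.0]), 0.0)


class TestLKB:
    params = LKBParams(td50=28.4, m=0.18, n=1.0, endpoint_label="test")

    def test_half_at_td50(self):
        d = make_differential([self.params.td50], [1.0])
        assert lkb_ntcp(d, self.params) == pytest.approx(0.5, abs=1e-12)

    def test_one_sigma(self):
        d = make_differential([self.params.td50 * (1 + self.params.m)], [1.0])
        assert lkb_ntcp(d, self.params) == pytest.approx(norm.cdf(1.0), abs=1e-9)

    def test_composition_oracle(self, rng):
        for _ in range(15):
            d = random_differential(rng)
            expected = norm.cdf(
                (geud(d, self.params.n) - self.params.td50)
                / (self.params.m * self.params.td50)
            )
            assert lkb_ntcp(d, self.params) == pytest.approx(float(expected), abs=1e-12)

    def test_input_order_invariance(self):
        a = make_differential([10.0, 20.0, 30.0], [0.2, 0.3, 0.5])
        b = make_differential([30.0, 10.0, 20.0], [0.5, 0.2, 0.3])
        assert lkb_ntcp(a, self.params) == lkb_ntcp(b, self.params)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LKBParams(td50=0.0, m=0.2, n=1.0)
        with pytest.raises(ValueError):
            LKBParams(td50=30.0, m=-0.2, n=1.0)


class TestMaxNormalizedSlope:
    def test_parotid_gamma_recovered(self, parotid_params):
        assert max_normalized_slope(parotid_params) == pytest.approx(0.26, abs=1e-3)

    def test_lacrimal_gamma_recovered(self, lacrimal_params):
        assert max_normalized_slope(lacrimal_params) == pytest.approx(0.34, abs=1e-3)

    def test_response_at_steepest_point(self, parotid_params):
        # at the steepest dose the Poisson response passes through 1/e
        step = 1e-4
        x = np.arange(0.0, 3.0 + step / 2, step)
        probs = poisson_response(x * parotid_params.d50, parotid_params)
        j = int(np.argmax(np.gradient(probs, x)))
        assert probs[j] == pytest.approx(1.0 / math.e, abs=1e-3)


class TestEQD2:
    def test_two_gray_fixed_point(self):
        d = make_differential([20.0], [1.0])  # 2 Gy/fx over 10 fractions
        out = eqd2_dvh(d, n_fractions=10, alpha_beta=3.0)
        assert out.bin_dose[0] == pytest.approx(20.0, rel=1e-12)

    def test_hand_value(self):
        d = make_differential([30.0], [1.0])
        out = eqd2_dvh(d, n_fractions=10, alpha_beta=3.0)
        assert out.bin_dose[0] == pytest.approx(36.0, rel=1e-12)

    def test_zero_dose_bin(self):
        d = make_differential([0.0, 30.0], [0.5, 0.5])
        out = eqd2_dvh(d, n_fractions=10, alpha_beta=3.0)
        assert out.bin_dose[0] == 0.0
        np.testing.assert_allclose(out.bin_volume, d.bin_volume)

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            eqd2_dvh(make_differential([30.0], [1.0]), 10, 0.0)


class TestPresets:
    def test_registry_contents(self):
        assert set(RS_PRESETS) == {"parotid_xerostomia_rs", "lacrimal_dryeye_rs"}
        p = RS_PRESETS["parotid_xerostomia_rs"]
        assert (p.d50, p.gamma, p.s) == (24.9, 0.26, 1e-4)
        l = RS_PRESETS["lacrimal_dryeye_rs"]
        assert (l.d50, l.gamma, l.s) == (63.9, 0.34, 1e-4)

    def test_invalid_rs_params(self):
        with pytest.raises(ValueError):
            RSParams(d50=-1.0, gamma=0.3, s=1.0)
        with pytest.raises(ValueError):
            RSParams(d50=20.0, gamma=0.3, s=0.0)
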