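"""Closed-form binding model: isotherms, exchange observables, linewidths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csptitr.binding import (
    BindingSystem,
    QuenchParameters,
    ShiftEndpoints,
    fraction_bound,
    fraction_bound_tight,
    linewidth_mass_scaling,
    observed_shift_fast,
    quenched_intensity,
    slow_exchange_intensities,
)

from _oracles import fraction_bound_bisection

conc = st.floats(1e-9, 1e-2)
sites = st.floats(0.3, 8.0)
kds = st.floats(1e-12, 1e-3)


class TestFractionBound:
    def test_no_ligand_means_nothing_bound(self):
        assert fraction_bound(BindingSystem(1e-3, 0.0, 2, 1e-9)) == 0.0

    def test_tight_binding_half_consumed(self):
        # 1 mM protein, 0.25 mM two-site ligand: half the protein is bound
        # once K_D is negligible
        p = fraction_bound(BindingSystem(1e-3, 0.25e-3, 2, 1e-15))
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_matches_bisection_oracle_at_symmetric_point(self):
        p = fraction_bound(BindingSystem(1e-6, 1e-6, 1, 1e-6))
        expected = fraction_bound_bisection(1e-6, 1e-6, 1, 1e-6)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_matches_bisection_oracle_on_random_grid(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            c_a = 10.0 ** rng.uniform(-9, -2)
            c_b = 10.0 ** rng.uniform(-9, -2)
            n = rng.uniform(0.3, 8.0)
            kd = 10.0 ** rng.uniform(-12, -3)
            p = fraction_bound(BindingSystem(c_a, c_b, n, kd))
            expected = fraction_bound_bisection(c_a, c_b, n, kd)
            assert p == pytest.approx(expected, rel=1e-10, abs=1e-13)

    def test_tight_limit_agreement(self):
        # closed form converges to the stoichiometric kink as K_D -> 0; the
        # slowest convergence, O(sqrt(K_D/c_A)), occurs at the breakpoint
        # itself, with a little discriminant roundoff on top
        for c_a in (1e-6, 1e-4, 1e-3):
            kd = 1e-12 * c_a
            bound = np.sqrt(kd / c_a) + 1e-9
            for ratio in (0.1, 0.25, 0.5, 0.51, 1.0):
                for n in (1.0, 2.0, 3.0):
                    exact = fraction_bound(BindingSystem(c_a, ratio * c_a, n, kd))
                    tight = fraction_bound_tight(BindingSystem(c_a, ratio * c_a, n))
                    assert exact == pytest.approx(tight, abs=bound)

    def test_vectorized_over_ligand_schedule(self):
        c_b = np.array([0.0, 1e-4, 5e-4])
        p = fraction_bound(BindingSystem(1e-3, c_b, 2, 1e-9))
        assert p.shape == (3,)
        assert p[0] == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(c_protein=-1e-3, c_ligand=0.0),
            dict(c_protein=0.0, c_ligand=0.0),
            dict(c_protein=1e-3, c_ligand=-1e-6),
            dict(c_protein=1e-3, c_ligand=np.nan),
            dict(c_protein=1e-3, c_ligand=1e-6, n_sites=0.0),
            dict(c_protein=1e-3, c_ligand=1e-6, kd=-1e-9),
        ],
    )
    def test_invalid_system_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BindingSystem(**kwargs)

    @given(c_a=conc, c_b=conc, n=sites, kd=kds)
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_monotonic(self, c_a, c_b, n, kd):
        p = fraction_bound(BindingSystem(c_a, c_b, n, kd))
        assert 0.0 <= p <= 1.0
        # non-decreasing in ligand, non-increasing in K_D, non-decreasing in N
        assert fraction_bound(BindingSystem(c_a, 1.5 * c_b, n, kd)) >= p - 1e-12
        assert fraction_bound(BindingSystem(c_a, c_b, n, 2.0 * kd)) <= p + 1e-12
        assert fraction_bound(BindingSystem(c_a, c_b, 1.5 * n, kd)) >= p - 1e-12

    def test_stable_when_kd_far_below_concentrations(self):
        # nanomolar K_D at millimolar concentrations: no catastrophic
        # cancellation in the quadratic root
        p = fraction_bound(BindingSystem(1e-3, 0.2e-3, 2, 4e-9))
        assert p == pytest.approx(0.4, rel=1e-4)


class TestTightBinding:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.5, 1.0), (0.25, 0.5), (0.0, 0.0), (0.625, 1.0), (0.125, 0.25)],
    )
    def test_two_site_kink_curve(self, ratio, expected):
        c_a = 1e-3
        p = fraction_bound_tight(BindingSystem(c_a, ratio * c_a, 2))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_saturation_breakpoint_is_inverse_site_count(self):
        # smallest ratio giving full saturation under two sites is 0.5
        c_a = 1e-3
        below = fraction_bound_tight(BindingSystem(c_a, 0.499 * c_a, 2))
        at = fraction_bound_tight(BindingSystem(c_a, 0.5 * c_a, 2))
        assert below < 1.0
        assert at == 1.0


class TestExchangeObservables:
    def test_fast_exchange_endpoints_and_midpoint(self):
        ep = ShiftEndpoints(free_shift=10.35, bound_shift=10.536)
        assert observed_shift_fast(0.0, ep) == 10.35
        assert observed_shift_fast(1.0, ep) == 10.536
        assert observed_shift_fast(0.5, ep) == pytest.approx(10.443)

    @given(p=st.floats(0, 1), a=st.floats(-1, 12), b=st.floats(-1, 12))
    @settings(max_examples=100, derandomize=True)
    def test_fast_exchange_is_affine_interpolation(self, p, a, b):
        out = observed_shift_fast(p, ShiftEndpoints(a, b))
        assert min(a, b) - 1e-12 <= out <= max(a, b) + 1e-12

    def test_fast_exchange_rejects_invalid_population(self):
        ep = ShiftEndpoints(1.0, 2.0)
        with pytest.raises(ValueError):
            observed_shift_fast(1.2, ep)
        with pytest.raises(ValueError):
            observed_shift_fast(-0.1, ep)

    @pytest.mark.parametrize("p", [0.0, 0.3, 1.0])
    def test_slow_exchange_intensities_complementary(self, p):
        free, bound = slow_exchange_intensities(p)
        assert free == pytest.approx(1.0 - p)
        assert bound == pytest.approx(p)
        assert free + bound == pytest.approx(1.0, abs=0)

    def test_slow_exchange_free_peak_gone_at_half_ratio(self):
        # two sites, ratio 0.5, stoichiometric regime: free protein exhausted
        c_a = 1e-3
        p = fraction_bound_tight(BindingSystem(c_a, 0.5 * c_a, 2))
        free, bound = slow_exchange_intensities(p)
        assert free == 0.0
        assert bound == 1.0


class TestQuench:
    def test_endpoints_and_linear_mixing(self):
        qp = QuenchParameters(f0=1.0, max_quench=0.6)
        sys0 = BindingSystem(5e-9, 0.0, 2, 4e-9)
        assert quenched_intensity(sys0, qp) == pytest.approx(1.0)
        # saturating ligand
        sys_sat = BindingSystem(5e-9, 1e-3, 2, 4e-9)
        assert quenched_intensity(sys_sat, qp) == pytest.approx(0.4, rel=1e-4)

    def test_monotone_nonincreasing_in_ligand(self):
        c_b = np.geomspace(1e-10, 1e-5, 40)
        y = quenched_intensity(BindingSystem(5e-9, c_b, 2, 4e-9), QuenchParameters(1.0, 0.8))
        assert np.all(np.diff(y) <= 1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            QuenchParameters(f0=0.0)
        with pytest.raises(ValueError):
            QuenchParameters(f0=1.0, max_quench=1.5)


class TestLinewidthScaling:
    @pytest.mark.parametrize(
        "ratio, expected", [(1.0, 1.0), (2.0, 2.0 ** (1 / 3)), (8.0, 2.0)]
    )
    def test_cube_root_of_mass_ratio(self, ratio, expected):
        assert linewidth_mass_scaling(ratio) == pytest.approx(expected)

    def test_dimer_broadening_factor_to_two_decimals(self):
        assert round(linewidth_mass_scaling(2.0), 2) == 1.26

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_ratio_rejected(self, bad):
        with pytest.raises(ValueError):
            linewidth_mass_scaling(bad)
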