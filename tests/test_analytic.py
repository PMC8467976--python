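"""Closed-form layer: ASR, selection gradients, fixed points, classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import anisogamy as ag
from anisogamy import Regime, Stability


def random_interior_points(seed, n, bp_range=(0.3, 1.8)):
    """Anisogamous parameter draws safely inside the coexistence regime."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        my = rng.uniform(0.05, 1.2)
        mx = my + rng.uniform(0.05, 1.2)
        bz = rng.uniform(0.3, 2.0)
        bp = rng.uniform(*bp_range)
        if bp > 1.02 * ag.asr_threshold(mx, my, bz):
            out.append((mx, my, bz, bp))
    return out


class TestEquilibriumAsr:
    def test_isogamy_is_even(self):
        assert ag.equilibrium_asr(0.4, 0.4, 1.0, 0.7) == 0.5

    def test_interior_value(self):
        assert ag.equilibrium_asr(1.5, 0.2, 1.0, 0.7) == pytest.approx(
            0.61493, abs=1e-5
        )

    def test_macrogamete_extinction_branch(self):
        # threshold 0.860 at (2, 1.5) exceeds beta_p = 0.7
        assert ag.asr_threshold(2.0, 1.5, 1.0) == pytest.approx(0.860, abs=5e-4)
        assert ag.equilibrium_asr(2.0, 1.5, 1.0, 0.7) == 1.0

    def test_symmetric_under_type_exchange(self):
        assert ag.equilibrium_asr(0.2, 1.5, 1.0, 0.7) == ag.equilibrium_asr(
            1.5, 0.2, 1.0, 0.7
        )

    def test_obligate_sex_limit_is_even(self):
        assert ag.equilibrium_asr(1.5, 0.2, 1.0, ag.INFINITE) == 0.5

    def test_fully_parthenogenetic_limit_fixes_microgametes(self):
        # overwhelming zygote mortality leaves only the numerous microgametes
        assert ag.equilibrium_asr(1.0, 0.5, 50.0, 0.7) == 1.0

    def test_large_beta_p_approaches_even(self):
        assert ag.equilibrium_asr(1.5, 0.2, 1.0, 50.0) == pytest.approx(0.5, abs=1e-6)

    @given(
        my=st.floats(0.05, 1.0),
        gap=st.floats(0.01, 1.0),
        bz=st.floats(0.3, 2.0),
        bp=st.floats(0.2, 2.0),
    )
    def test_always_a_proportion(self, my, gap, bz, bp):
        r = ag.equilibrium_asr(my + gap, my, bz, bp)
        assert 0.0 <= r <= 1.0


class TestGradients:
    def test_obligate_sex_fixed_points(self):
        g = ag.gradient_obligate_sex(0.25, 0.25, 1.0)
        assert g.dmx_dtau == pytest.approx(0.0, abs=1e-12)
        assert g.dmy_dtau == pytest.approx(0.0, abs=1e-12)
        # near the extreme anisogamous attractor the macro gradient vanishes
        assert ag.gradient_obligate_sex(1.0, 1e-9, 1.0).dmx_dtau == pytest.approx(
            0.0, abs=1e-6
        )

    def test_obligate_sex_value(self):
        assert ag.gradient_obligate_sex(0.5, 0.5, 1.0).dmx_dtau == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "m, bp, expected", [(0.7, 0.7, 0.0), (2.0, 0.7, -0.325), (0.1, 0.7, 60.0)]
    )
    def test_asexual_gradient_values(self, m, bp, expected):
        assert ag.gradient_asexual(m, bp) == pytest.approx(expected, rel=1e-12)

    def test_mixed_interior_value(self):
        g = ag.gradient_mixed(1.5, 0.2, 1.0, 0.7)
        assert g.dmx_dtau == pytest.approx(-0.12347, abs=1e-5)

    def test_mixed_reduces_to_half_obligate_at_isogamy(self):
        g = ag.gradient_mixed(0.5, 0.5, 1.0, 0.7)
        full = ag.gradient_obligate_sex(0.5, 0.5, 1.0)
        assert g.dmx_dtau == pytest.approx(full.dmx_dtau / 2, rel=1e-12)

    def test_mixed_macro_gradient_vanishes_at_discrete_end_state(self):
        # with the micro trait at its floor m_min, the macro zero sits at the
        # root of beta_z*m = (m + m_min)^2, i.e. beta_z - 2*m_min + O(m_min^2)
        root = 0.5 * (0.96 + math.sqrt(0.96**2 - 4 * 0.02**2))
        g = ag.gradient_mixed(root, 0.02, 1.0, 0.7)
        assert g.dmx_dtau == pytest.approx(0.0, abs=1e-10)
        assert root == pytest.approx(1.0 - 2 * 0.02, abs=1e-3)

    def test_mixed_in_extinction_region_raises(self):
        with pytest.raises(ag.RegimeError):
            ag.gradient_mixed(2.0, 1.5, 1.0, 0.7)

    def test_obligate_limit_recovers_sex_field_up_to_time_rescaling(self):
        # as beta_p grows the mixed field converges to the obligate-sex field
        # scaled by the even type frequency 1/2 (the mutation-supply weight)
        g = ag.gradient_mixed(1.2, 0.3, 1.0, 1e4)
        full = ag.gradient_obligate_sex(1.2, 0.3, 1.0)
        assert 2 * g.dmx_dtau == pytest.approx(full.dmx_dtau, rel=1e-6)
        assert 2 * g.dmy_dtau == pytest.approx(full.dmy_dtau, rel=1e-6)

    def test_macro_component_weight_is_macrogamete_frequency(self):
        # the printed closed form's exponential-ratio factor equals 1 - R
        for mx, my, bz, bp in random_interior_points(5, 25):
            s = mx + my
            ep, ez = math.exp(bp / my), math.exp(bz / s)
            printed_ratio = (my * ep - mx * ez) / (2 * my * ep - s * ez)
            assert printed_ratio == pytest.approx(
                1.0 - ag.equilibrium_asr(mx, my, bz, bp), rel=1e-10
            ), (mx, my, bz, bp)

    def test_micro_component_matches_numerical_differentiation(self):
        # the analytic microgamete gradient is R * d/dm ln(lambda_hat);
        # central differences of the mutant log growth factor are the oracle
        for mx, my, bz, bp in random_interior_points(6, 25):
            R = ag.equilibrium_asr(mx, my, bz, bp)
            F = ag.rare_mutant_fertilized_fraction(mx, my, bz, bp)
            h = 1e-7 * my
            nd = (
                ag.mutant_log_growth(my + h, mx, F, bz, bp)
                - ag.mutant_log_growth(my - h, mx, F, bz, bp)
            ) / (2 * h)
            assert ag.gradient_mixed(mx, my, bz, bp).dmy_dtau == pytest.approx(
                R * nd, rel=1e-6, abs=1e-8
            ), (mx, my, bz, bp)


class TestAsexualInvasionConditions:
    @pytest.mark.parametrize(
        "mx, my, bz, bp, expected",
        [
            (1.5, 0.2, 1.0, 0.7, (False, True)),
            (0.5, 0.5, 1.0, 0.7, (False, False)),
            (1.5, 0.2, 1.0, 1.3, (False, False)),
            (2.0, 1.5, 1.0, 0.7, (True, False)),
        ],
    )
    def test_examples(self, mx, my, bz, bp, expected):
        assert ag.asexual_invasion_conditions(mx, my, bz, bp) == expected

    def test_symmetric_under_type_exchange(self):
        assert ag.asexual_invasion_conditions(
            0.2, 1.5, 1.0, 0.7
        ) == ag.asexual_invasion_conditions(1.5, 0.2, 1.0, 0.7)


class TestFixedPoints:
    def test_obligate_sex_portrait(self):
        pts = ag.find_fixed_points(1.0, 0.7, Regime.OBLIGATE_SEX, box=(0.05, 1.5))
        interior = [p for p in pts if p.stability is not Stability.BOUNDARY]
        assert any(
            np.allclose(p.location, (0.25, 0.25), atol=1e-6)
            and p.stability in (Stability.SADDLE, Stability.UNSTABLE)
            for p in interior
        )
        boundary = [p.location for p in pts if p.stability is Stability.BOUNDARY]
        assert any(np.allclose(loc, (1.0, 0.0), atol=1e-3) for loc in boundary)
        assert any(np.allclose(loc, (0.0, 1.0), atol=1e-3) for loc in boundary)

    def test_asexual_optimum(self):
        pts = ag.find_fixed_points(1.0, 0.7, Regime.ASEXUAL, box=(0.05, 1.5))
        assert len(pts) == 1
        assert pts[0].location[0] == pytest.approx(0.7)
        assert pts[0].stability is Stability.STABLE

    def test_mixed_regime_adds_stable_isogamy_under_partheno_advantage(self):
        pts = ag.find_fixed_points(1.0, 0.7, Regime.MIXED, box=(0.05, 1.5))
        iso = [
            p
            for p in pts
            if abs(p.location[0] - p.location[1]) < 1e-6
            and p.location[0] == pytest.approx(0.25, abs=0.02)
        ]
        assert iso and iso[0].stability is Stability.STABLE

    def test_mixed_regime_isogamy_unstable_under_partheno_disadvantage(self):
        pts = ag.find_fixed_points(1.0, 1.3, Regime.MIXED, box=(0.05, 1.5))
        iso = [
            p
            for p in pts
            if abs(p.location[0] - p.location[1]) < 1e-6
            and p.location[0] == pytest.approx(0.25, abs=0.02)
        ]
        assert iso and iso[0].stability in (Stability.SADDLE, Stability.UNSTABLE)


class TestClassification:
    def test_no_extinction_region_under_partheno_disadvantage(self):
        values = np.arange(0.02, 1.62, 0.02)
        table = ag.classify_grid(values, values, 1.0, 1.3)
        assert not table["macro_extinct"].any()

    def test_extinction_region_under_partheno_advantage(self):
        values = np.arange(0.02, 1.62, 0.02)
        table = ag.classify_grid(values, values, 1.0, 0.7)
        assert table["macro_extinct"].any()
        # extinction coincides with the microgamete asexual-invasion region
        assert (table["macro_extinct"] == table["micro_asex"]).all()

    def test_diagonal_is_even_and_uninvadable(self):
        values = np.arange(0.1, 1.6, 0.1)
        table = ag.classify_grid(values, values, 1.0, 0.7)
        diag = table[table.mx == table.my]
        assert (diag["R"] == 0.5).all()
        assert not diag["micro_asex"].any() and not diag["macro_asex"].any()


class TestTrajectoryIntegration:
    def test_flow_into_extinction_switches_to_asexual_optimum(self):
        df = ag.integrate_trajectory(1.5, 0.2, 1.0, 0.7, t_max=100.0)
        last = df.iloc[-1]
        assert last["regime"] == "ASEXUAL"
        assert last["my"] == pytest.approx(0.7, abs=1e-3)
        assert math.isnan(last["mx"])

    def test_disadvantage_flow_stays_mixed_and_hits_floor(self):
        df = ag.integrate_trajectory(1.0, 0.8, 1.0, 1.3, t_max=200.0, m_min=0.02)
        assert (df["regime"] == "MIXED").all()
        assert df.iloc[-1]["my"] == pytest.approx(0.02, abs=1e-6)
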