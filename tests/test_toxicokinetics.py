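import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwscreen.datamodel import ValidationError
from dwscreen.toxicokinetics import (NonComputableCss, Physiology, TkParams,
                                     VariabilitySpec, aed95_per_endpoint,
                                     build_aed_floors, chemical_aed_floor,
                                     compute_med, css95_monte_carlo,
                                     css_steady_state,
                                     summarize_sample_ear_med)

PHYS = Physiology(body_weight=70.0, liver_blood_flow=90.0,
                  glomerular_filtration_rate=6.7,
                  hepatocellularity=110.0, liver_mass=1820.0)


class TestMed:
    @pytest.mark.parametrize("conc,expected", [(1.0, 2e-4), (0.0, 0.0), (50.0, 0.01)])
    def test_ingestion_rate_arithmetic(self, conc, expected):
        assert compute_med(conc) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            compute_med(-1.0)


class TestCssSteadyState:
    def test_zero_intrinsic_clearance_renal_only_limit(self):
        """CLint = 0 ⇒ Css = dose_rate / (GFR · f_up) exactly."""
        tk = TkParams("x", molecular_weight=100.0, fraction_unbound=0.5,
                      intrinsic_clearance=0.0)
        css = css_steady_state(tk, PHYS, dose=1.0)
        expected_mgL = (1.0 * 70.0 / 24.0) / (6.7 * 0.5)
        assert css == pytest.approx(expected_mgL / 100.0 * 1000.0, rel=1e-9)

    def test_flow_limited_limit(self):
        """CLint → ∞ with f_up = 1 ⇒ Css → dose_rate / (GFR + Q_liver)."""
        tk = TkParams("x", molecular_weight=100.0, fraction_unbound=1.0,
                      intrinsic_clearance=1e12)
        css = css_steady_state(tk, PHYS, dose=1.0)
        expected_mgL = (70.0 / 24.0) / (6.7 + 90.0)
        assert css == pytest.approx(expected_mgL / 100.0 * 1000.0, rel=1e-6)

    def test_toy_parameters_match_hand_oracle(self):
        """Independently hand-computed well-stirred arithmetic.

        MW 100, f_up 0.5, whole-liver CLint 1 L/h, Q 90 L/h, GFR 6.7 L/h,
        BW 70 kg, dose 1 mg/kg/d:
        CL_h = 45/90.5, CL_r = 3.35, Css = (70/24)/(3.35 + 45/90.5) mg/L.
        """
        # per-cell clearance chosen so whole-liver CLint is exactly 1 L/h
        clint_cell = 1.0 / (110.0 * 1820.0 * 60.0 * 1e-6)
        tk = TkParams("toy", molecular_weight=100.0, fraction_unbound=0.5,
                      intrinsic_clearance=clint_cell)
        assert css_steady_state(tk, PHYS, dose=1.0) == pytest.approx(
            7.581197194897202, rel=1e-12)

    def test_linear_in_dose_and_monotone_in_gfr(self):
        tk = TkParams("x", 100.0, 0.5, 5.0)
        c1 = css_steady_state(tk, PHYS, dose=1.0)
        c3 = css_steady_state(tk, PHYS, dose=3.0)
        assert c3 == pytest.approx(3 * c1, rel=1e-12)
        hi_gfr = Physiology(70.0, 90.0, 13.4, 110.0, 1820.0)
        assert css_steady_state(tk, hi_gfr, dose=1.0) < c1

    def test_zero_total_clearance_signalled(self):
        tk = TkParams("x", 100.0, 0.5, 0.0)
        with pytest.raises(NonComputableCss):
            css_steady_state(tk, PHYS, dose=1.0, _gfr=0.0, _clint=0.0)


class TestCss95MonteCarlo:
    TK = TkParams("x", 250.0, 0.3, 10.0)

    def test_zero_cv_equals_deterministic(self):
        var = VariabilitySpec(0.0, 0.0, 0.0, 0.0, n_draws=100, seed=1)
        assert css95_monte_carlo(self.TK, PHYS, var) == pytest.approx(
            css_steady_state(self.TK, PHYS, 1.0), rel=1e-12)

    def test_same_seed_reproducible(self):
        var = VariabilitySpec(n_draws=2000, seed=42)
        assert css95_monte_carlo(self.TK, PHYS, var) == css95_monte_carlo(self.TK, PHYS, var)

    def test_css95_above_median_for_skewed_variation(self):
        var = VariabilitySpec(n_draws=5000, seed=3)
        css95 = css95_monte_carlo(self.TK, PHYS, var)
        assert css95 > css_steady_state(self.TK, PHYS, 1.0) * 0.99

    def test_large_n_quantile_convergence(self):
        """95th-percentile estimates at n = 10k and 100k agree within MC error."""
        a = css95_monte_carlo(self.TK, PHYS, VariabilitySpec(n_draws=10_000, seed=5))
        b = css95_monte_carlo(self.TK, PHYS, VariabilitySpec(n_draws=100_000, seed=6))
        assert a == pytest.approx(b, rel=0.05)


class TestAed:
    def test_identity_and_half(self):
        assert aed95_per_endpoint(2.0, 2.0) == pytest.approx(1.0)
        assert aed95_per_endpoint(2.0, 4.0) == pytest.approx(0.5)

    def test_vector_matches_loop(self):
        accs = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        out = aed95_per_endpoint(accs, 3.0)
        assert np.allclose(out, [a / 3.0 for a in accs], rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            aed95_per_endpoint(-1.0, 2.0)

    def test_aed_decreases_as_css95_increases(self):
        assert aed95_per_endpoint(2.0, 8.0) < aed95_per_endpoint(2.0, 4.0)

    def test_floor_quantile_definition(self):
        """5th percentile of 1..100 under linear interpolation is 5.95."""
        assert chemical_aed_floor(range(1, 101)) == pytest.approx(5.95)
        assert chemical_aed_floor([3.3]) == pytest.approx(3.3)
        assert chemical_aed_floor([2.0, 2.0, 2.0]) == pytest.approx(2.0)

    def test_empty_floor_signals_no_coverage(self):
        with pytest.raises(ValueError, match="coverage"):
            chemical_aed_floor([])


class TestEarMedChain:
    def test_unit_path_invariance(self):
        """EAR_MED via (μg/L→mg/kg/d)/(μM→mg/kg/d) equals direct dimensional form.

        Direct: EAR_MED = C·0.2·1e-3 · css95_uM / acc_uM with css95 per unit dose.
        """
        conc = 12.5
        acc_uM, css95 = 4.0, 0.8
        med = compute_med(conc)
        aed = aed95_per_endpoint(acc_uM, css95)
        via_chain = med / aed
        direct = conc * 0.2 * 1e-3 * css95 / acc_uM
        assert via_chain == pytest.approx(direct, rel=1e-12)

    def test_sample_summary_forced_arithmetic(self):
        det = pd.DataFrame({
            "sample_id": ["s"], "analyte_id": ["a"], "analyte_class": ["VOC"],
            "concentration": [1.0], "detected": [True]})
        floors = pd.DataFrame({"analyte_id": ["a"], "aed_floor": [0.1]})
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        out, contrib = summarize_sample_ear_med(det, floors, samples)
        assert out["sum_ear_med"].iloc[0] == pytest.approx(0.002)
        assert out["exceeds_0p001"].iloc[0]
        assert contrib["ear_med"].iloc[0] == pytest.approx(0.002)

    @given(st.lists(st.tuples(st.floats(0.01, 100.0), st.floats(1e-3, 10.0)),
                    min_size=1, max_size=15))
    @settings(deadline=None, max_examples=40)
    def test_sample_summary_matches_brute_force(self, chems):
        det = pd.DataFrame({
            "sample_id": "s", "analyte_id": [f"c{i}" for i in range(len(chems))],
            "analyte_class": "VOC", "concentration": [c for c, _ in chems],
            "detected": True})
        floors = pd.DataFrame({"analyte_id": [f"c{i}" for i in range(len(chems))],
                               "aed_floor": [f for _, f in chems]})
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        out, _ = summarize_sample_ear_med(det, floors, samples)
        brute = sum(em for em in (c * 2e-4 / f for c, f in chems) if em >= 1e-5)
        assert out["sum_ear_med"].iloc[0] == pytest.approx(brute, rel=1e-12)

    def test_uncovered_chemicals_excluded_and_reported(self):
        acc = pd.DataFrame({"analyte_id": ["a", "b"], "endpoint_id": ["e1", "e2"],
                            "acc_uM": [5.0, 5.0]})
        tk = pd.DataFrame({"analyte_id": ["a"], "molecular_weight": [100.0],
                           "fraction_unbound": [0.5], "intrinsic_clearance": [5.0]})
        floors, aed, cov = build_aed_floors(acc, tk, PHYS, VariabilitySpec(n_draws=200, seed=0))
        assert set(floors["analyte_id"]) == {"a"}
        row = cov.set_index("analyte_id").loc["b"]
        assert not row["covered"] and "toxicokinetic" in row["reason"]

    def test_build_floors_deterministic_and_order_invariant(self):
        acc = pd.DataFrame({"analyte_id": ["a", "b"], "endpoint_id": ["e1", "e2"],
                            "acc_uM": [5.0, 2.0]})
        tk = pd.DataFrame({"analyte_id": ["a", "b"], "molecular_weight": [100.0, 200.0],
                           "fraction_unbound": [0.5, 0.2],
                           "intrinsic_clearance": [5.0, 1.0]})
        var = VariabilitySpec(n_draws=500, seed=9)
        f1, _, _ = build_aed_floors(acc, tk, PHYS, var)
        f2, _, _ = build_aed_floors(acc.iloc[::-1], tk.iloc[::-1], PHYS, var)
        pd.testing.assert_frame_equal(f1, f2.reset_index(drop=True))
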