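import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwscreen.benchmarks import (ConfigurationError, SubstitutionRules,
                                 benchmark_coverage, compute_tq,
                                 individual_exceedance_table,
                                 resolve_benchmark, resolve_benchmarks,
                                 summarize_sample_tq)

from conftest import make_dataset

RULES = SubstitutionRules(by_class={"inorganic": 0.1, "DBP": 0.1, "VOC": 0.1},
                          by_analyte={"pfos": 0.0001, "pfoa": 0.0001})


def cand(*pairs, analyte_id="x"):
    return pd.DataFrame([(analyte_id, t, v) for t, v in pairs],
                        columns=["analyte_id", "benchmark_type", "value"])


class TestResolveBenchmark:
    def test_minimum_positive_candidate_selected(self):
        rb = resolve_benchmark("x", cand(("WHO", 0.5), ("STATE", 0.1), ("DWHA", 0.3)), RULES)
        assert rb.effective_value == 0.1
        assert rb.source_type == "STATE"
        assert not rb.substitution_applied

    def test_zero_mclg_metal_substituted_to_0p1(self):
        rb = resolve_benchmark("as", cand(("MCLG", 0.0), ("MCL", 10.0), analyte_id="as"),
                               RULES, analyte_class="inorganic")
        assert rb.effective_value == 0.1
        assert rb.substitution_applied

    def test_zero_mclg_pfos_substituted_to_1e4(self):
        rb = resolve_benchmark("pfos", cand(("MCLG", 0.0), ("MCL", 0.004), analyte_id="pfos"),
                               RULES, analyte_class="PFAS")
        assert rb.effective_value == 0.0001

    def test_zero_mclg_without_rule_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            resolve_benchmark("x", cand(("MCLG", 0.0)), SubstitutionRules(by_class={}))

    def test_empty_candidates_signal(self):
        with pytest.raises(ValueError, match="no benchmark"):
            resolve_benchmark("x", cand(), RULES)

    def test_tie_breaks_by_type_priority(self):
        rb = resolve_benchmark("x", cand(("HHBP", 2.0), ("DWHA", 2.0)), RULES)
        assert rb.source_type == "DWHA"

    @given(vals=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_minimality_over_positive_candidates(self, vals):
        types = ["MCL", "SOQ", "DWHA", "WHO", "STATE", "HBSL"]
        pairs = [(types[i % len(types)], v) for i, v in enumerate(vals)]
        rb = resolve_benchmark("x", cand(*pairs), RULES)
        assert rb.effective_value == pytest.approx(min(vals))


class TestComputeTq:
    def test_forced_arithmetic_from_substitution(self, small_catalog):
        """1 μg/L metal over substituted 0.1 → TQ 10; 0.004 μg/L PFOA over 0.0001 → TQ 40."""
        ds = make_dataset(small_catalog, [
            ("s1", "private_tw", "as", 1.0, 0.05),
            ("s1", "private_tw", "pfoa", 0.004, 0.004)])
        bench = pd.concat([cand(("MCLG", 0.0), ("MCL", 10.0), analyte_id="as"),
                           cand(("MCLG", 0.0), ("MCL", 0.004), analyte_id="pfoa")])
        resolved = resolve_benchmarks(bench, RULES, small_catalog.table)
        tq = compute_tq(ds.detections, resolved).set_index("analyte_id")["tq"]
        assert tq["as"] == pytest.approx(10.0)
        assert tq["pfoa"] == pytest.approx(40.0)

    def test_identity_and_inclusion_screen(self):
        det = pd.DataFrame({"sample_id": ["a", "a"], "analyte_id": ["x", "y"],
                            "concentration": [0.1, 1e-7], "detected": [True, True]})
        resolved = pd.DataFrame({"analyte_id": ["x", "y"], "effective_value": [0.1, 1.0]})
        tq = compute_tq(det, resolved)
        assert tq.loc[tq["analyte_id"] == "x", "tq"].iloc[0] == pytest.approx(1.0)
        assert not tq.loc[tq["analyte_id"] == "y", "included"].iloc[0]

    def test_nondetects_and_microbial_excluded(self, small_dataset):
        resolved = pd.DataFrame({"analyte_id": ["as", "chcl3"], "effective_value": [0.1, 80.0]})
        tq = compute_tq(small_dataset.detections, resolved)
        # s1 chcl3 and s3 as are non-detects: no rows for them
        assert set(zip(tq["sample_id"], tq["analyte_id"])) == {("s1", "as"), ("s2", "chcl3")}


class TestSummarizeSampleTq:
    def test_empty_sample_zero_sum(self, small_catalog):
        samples = pd.DataFrame({"sample_id": ["s1"], "supply_class": ["bottled"]})
        out, contrib = summarize_sample_tq(pd.DataFrame(
            columns=["sample_id", "analyte_id", "tq", "included"]), samples)
        assert out["sum_tq"].iloc[0] == 0.0
        assert not out["exceeds_0p1"].iloc[0] and not out["exceeds_1p0"].iloc[0]
        assert contrib.empty

    def test_subunit_tqs_sum_over_one(self):
        q = pd.DataFrame({"sample_id": ["s", "s"], "analyte_id": ["a", "b"],
                          "tq": [0.5, 0.7], "included": [True, True]})
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        out, _ = summarize_sample_tq(q, samples)
        assert out["sum_tq"].iloc[0] == pytest.approx(1.2)
        assert out["exceeds_1p0"].iloc[0]
        assert out["n_tq_over_1"].iloc[0] == 0

    @given(st.lists(st.floats(1e-6, 1e3), min_size=1, max_size=20), st.data())
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_and_scaling_linearity(self, tqs, data):
        """∑TQ equals the loop sum of included quotients; scaling concentrations by k scales ∑TQ by k."""
        q = pd.DataFrame({"sample_id": "s", "analyte_id": [f"a{i}" for i in range(len(tqs))],
                          "tq": tqs})
        q["included"] = q["tq"] >= 1e-5
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        out, contrib = summarize_sample_tq(q, samples)
        brute = sum(t for t in tqs if t >= 1e-5)
        assert out["sum_tq"].iloc[0] == pytest.approx(brute, rel=1e-12)
        assert out["n_tq_over_1"].iloc[0] == sum(t > 1 for t in tqs)
        if brute > 0:
            assert contrib["contribution_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
            # monotone ranking
            assert contrib["contribution_fraction"].is_monotonic_decreasing
        k = data.draw(st.floats(0.1, 10.0))
        q2 = q.assign(tq=q["tq"] * k)
        q2["included"] = q2["tq"] >= 1e-5
        out2, _ = summarize_sample_tq(q2, samples)
        scaled = sum(t * k for t in tqs if t * k >= 1e-5)
        assert out2["sum_tq"].iloc[0] == pytest.approx(scaled, rel=1e-9)

    def test_adding_detection_never_decreases_sum(self):
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        q = pd.DataFrame({"sample_id": ["s"], "analyte_id": ["a"], "tq": [0.4],
                          "included": [True]})
        base, _ = summarize_sample_tq(q, samples)
        q2 = pd.concat([q, pd.DataFrame({"sample_id": ["s"], "analyte_id": ["b"],
                                         "tq": [0.01], "included": [True]})])
        more, _ = summarize_sample_tq(q2, samples)
        assert more["sum_tq"].iloc[0] >= base["sum_tq"].iloc[0]

    def test_lower_benchmark_weakly_greater_sum(self):
        det = pd.DataFrame({"sample_id": ["s"], "analyte_id": ["x"],
                            "concentration": [1.0], "detected": [True]})
        samples = pd.DataFrame({"sample_id": ["s"], "supply_class": ["bottled"]})
        sums = []
        for eff in (10.0, 1.0, 0.1):
            resolved = pd.DataFrame({"analyte_id": ["x"], "effective_value": [eff]})
            out, _ = summarize_sample_tq(compute_tq(det, resolved), samples)
            sums.append(out["sum_tq"].iloc[0])
        assert sums == sorted(sums)


class TestIndividualExceedance:
    def test_zero_mclg_any_detection_exceeds(self, small_catalog):
        ds = make_dataset(small_catalog, [("s1", "private_tw", "as", 0.001, 0.0005)])
        reg = cand(("MCLG", 0.0), ("MCL", 10.0), analyte_id="as")
        out = individual_exceedance_table(ds, reg)
        mclg = out.loc[out["benchmark_type"] == "MCLG", "exceeds"]
        mcl = out.loc[out["benchmark_type"] == "MCL", "exceeds"]
        assert bool(mclg.iloc[0]) is True
        assert bool(mcl.iloc[0]) is False

    def test_equal_to_benchmark_is_not_exceedance(self, small_catalog):
        ds = make_dataset(small_catalog, [("s1", "public_tw", "chcl3", 80.0, 0.02)])
        out = individual_exceedance_table(ds, cand(("MCL", 80.0), analyte_id="chcl3"))
        assert bool(out["exceeds"].iloc[0]) is False

    def test_hand_enumerated_counts(self, small_catalog):
        ds = make_dataset(small_catalog, [
            ("s1", "public_tw", "chcl3", 100.0, 0.02),
            ("s2", "public_tw", "chcl3", 10.0, 0.02),
            ("s3", "public_tw", "chcl3", 90.0, 0.02),
            ("s4", "public_tw", "chcl3", 80.0, 0.02),
            ("s5", "public_tw", "chcl3", 1.0, 0.02)])
        out = individual_exceedance_table(ds, cand(("MCL", 80.0), analyte_id="chcl3"))
        assert int(out["exceeds"].sum()) == 2


def test_coverage_counts_detected_vs_benchmarked(small_dataset):
    resolved = pd.DataFrame({"analyte_id": ["as"], "effective_value": [0.1]})
    cov = benchmark_coverage(small_dataset, resolved).set_index("analyte_class")
    assert cov.loc["inorganic", "n_detected_analytes"] == 1
    assert cov.loc["inorganic", "n_with_benchmark"] == 1
    assert cov.loc["PFAS", "n_with_benchmark"] == 0
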