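"""Screen statistics: CV/QC, ANOVA+Tukey against independent references,
hit calling and dose-response on constructed plates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chondroscreen.stats import (
    anova_tukey,
    call_morphology_hits,
    coefficient_of_variation,
    dilution_factor,
    dose_response_summary,
    qc_gate,
    tost_equivalence,
    unpaired_t,
)
from chondroscreen.synthetic import (
    basal_effect,
    benchmark_effects,
    chondro_effect,
    dose_plate_spec,
    sample_well_summaries,
    screen_plate_spec,
)


class TestDilution:
    def test_screen_protocol_yields_1000x(self):
        # 50x pre-dilution, then 10 µL into 190 µL (20x) -> 1000x overall
        assert dilution_factor() == 1000.0
        assert dilution_factor(50, 10, 190) == 1000.0

    def test_general_arithmetic(self):
        assert dilution_factor(10, 100, 900) == 100.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            dilution_factor(0, 10, 190)


class TestCV:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_hand_computation(self):
        # SD({10,12,14}) = 2, mean 12 -> 16.67%
        assert coefficient_of_variation([10, 12, 14]) == pytest.approx(100 * 2 / 12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([1, -1])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([3])

    @given(st.floats(min_value=0.01, max_value=1e3),
           st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=3, max_size=12))
    def test_scale_invariance(self, c, xs):
        assert coefficient_of_variation(np.array(xs) * c) == pytest.approx(
            coefficient_of_variation(xs), rel=1e-9, abs=1e-9
        )


class TestQCGate:
    def test_control_cvs_pass(self):
        # the assay's observed control CVs: 11/18% (area), 2.7/3.1% (roundness)
        report = qc_gate({"basal/area": 11, "chondro/area": 18,
                          "basal/roundness": 2.7, "chondro/roundness": 3.1})
        assert report.overall_pass and all(report.passes.values())

    def test_boundary_is_strict(self):
        assert not qc_gate({"x": 20.0}).overall_pass
        assert qc_gate({"x": 19.999}).overall_pass

    def test_empty_report_passes_vacuously_with_warning(self):
        with pytest.warns(UserWarning, match="no entries"):
            report = qc_gate({})
        assert report.overall_pass


class TestAnovaTukey:
    def test_identical_groups_degenerate(self):
        res = anova_tukey({"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0]})
        assert res.f_statistic == 0.0 and res.p_value == 1.0
        assert (res.pairwise_p.values == 1.0).all()

    def test_matches_statsmodels_reference(self):
        """Cross-check against an independent implementation to 1e-8."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        groups = {
            "g1": rng.normal(0.0, 1.0, 6),
            "g2": rng.normal(1.0, 1.0, 5),
            "g3": rng.normal(0.5, 1.0, 7),
        }
        res = anova_tukey(groups)
        data = pd.DataFrame(
            {"y": np.concatenate(list(groups.values())),
             "g": np.repeat(list(groups), [len(v) for v in groups.values()])}
        )
        table = sm.stats.anova_lm(ols("y ~ C(g)", data).fit())
        assert res.f_statistic == pytest.approx(table["F"].iloc[0], abs=1e-8)
        assert res.p_value == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-8)
        tk = pairwise_tukeyhsd(data["y"], data["g"])
        ours = [res.p_between("g1", "g2"), res.p_between("g1", "g3"), res.p_between("g2", "g3")]
        np.testing.assert_allclose(ours, tk.pvalues, atol=1e-8)

    def test_tukey_p_not_below_unadjusted_pairwise(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(i * 0.4, 1.0, 6) for i, k in enumerate("abc")}
        res = anova_tukey(groups)
        # adjusted p >= the unadjusted pooled-variance pairwise p, every pair
        arrays = list(groups.values())
        sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        df = sum(len(a) for a in arrays) - len(arrays)
        mse = sse / df
        from scipy import stats as sps
        for i, a in enumerate("abc"):
            for b in "abc"[i + 1:]:
                diff = groups[a].mean() - groups[b].mean()
                se = np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
                p_unadj = 2 * sps.t.sf(abs(diff) / se, df)
                assert res.p_between(a, b) >= p_unadj - 1e-12

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})


class TestUnpairedT:
    def test_identical_vectors(self):
        assert unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_matches_reference(self):
        sw = pytest.importorskip("statsmodels.stats.weightstats")
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 9)
        t, p = unpaired_t(a, b)
        t_ref, p_ref, _ = sw.ttest_ind(a, b, usevar="pooled")
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_antisymmetry(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        t1, p1 = unpaired_t(a, b)
        t2, p2 = unpaired_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0, 1.0], [2.0, 2.0])


class TestTost:
    def test_clearly_equivalent(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(0, 0.1, 20)
        assert tost_equivalence(a, b, margin=1.0) < 0.05

    def test_clearly_different(self):
        rng = np.random.default_rng(12)
        assert tost_equivalence(rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10), margin=1.0) > 0.5


def _benchmark_plate(seed, positive_model, replicates=4):
    spec = screen_plate_spec(["X"], concentrations_nM=(100.0,), replicates=replicates, rng_seed=seed)
    eff = benchmark_effects()
    return sample_well_summaries(spec, {**eff, "X": positive_model})


class TestHitCalling:
    def test_constructed_positive_is_flagged(self):
        summ = _benchmark_plate(1, benchmark_effects()["positive"])
        tab = call_morphology_hits(summ)
        assert bool(tab["morphology_hit"].iloc[0])

    def test_constructed_negative_is_not_flagged(self):
        summ = _benchmark_plate(2, benchmark_effects()["negative"])
        tab = call_morphology_hits(summ)
        assert not bool(tab["morphology_hit"].iloc[0])

    def test_null_compound_fails_differs_from_basal_arm(self):
        # identical to both controls is impossible; identical to basal means
        # the differs-from-basal arm cannot fire
        summ = _benchmark_plate(3, benchmark_effects()["negative"])
        tab = call_morphology_hits(summ)
        row = tab.iloc[0]
        assert row["p_area_vs_basal"] >= 0.05 or row["p_roundness_vs_basal"] >= 0.05

    def test_missing_controls_rejected(self):
        summ = _benchmark_plate(4, benchmark_effects()["positive"])
        no_pos = summ[summ["role"] != "positive"]
        with pytest.raises(ValueError, match="control wells"):
            call_morphology_hits(no_pos)

    def test_migration_flag_present(self):
        summ = _benchmark_plate(5, benchmark_effects()["positive"])
        tab = call_morphology_hits(summ)
        assert {"migration_count", "migration_hit"} <= set(tab.columns)


class TestDoseResponse:
    def test_step_effect_detected_only_at_high_concentrations(self):
        """Concentrations >= 10 nM draw from the chondro-like model, lower
        ones from basal: significance vs basal appears only at >= 10 nM."""
        eff = benchmark_effects()
        spec = dose_plate_spec("X", rng_seed=21)
        models = {**eff}
        for conc in (0.0, 1.0, 3.0):
            models[f"X@{conc:g}nM"] = eff["negative"]
        for conc in (10.0, 30.0, 100.0, 300.0, 1000.0):
            models[f"X@{conc:g}nM"] = eff["positive"]
        summ = sample_well_summaries(spec, models)
        table = dose_response_summary(summ)
        sig = dict(zip(table["concentration_nM"], table["sig_area_vs_basal"]))
        assert not any(sig[c] for c in (0.0, 1.0, 3.0))
        assert all(sig[c] for c in (10.0, 30.0, 100.0, 300.0, 1000.0))
        assert list(table["concentration_nM"]) == sorted(table["concentration_nM"])

    def test_single_concentration_degenerate(self):
        eff = benchmark_effects()
        spec = screen_plate_spec(["X"], concentrations_nM=(30.0,), replicates=4, rng_seed=22)
        summ = sample_well_summaries(spec, {**eff, "X": eff["positive"]})
        table = dose_response_summary(summ, concentrations_nM=(30.0,))
        assert len(table) == 1

    def test_missing_levels_warn(self):
        eff = benchmark_effects()
        spec = screen_plate_spec(["X"], concentrations_nM=(30.0,), replicates=4, rng_seed=23)
        summ = sample_well_summaries(spec, {**eff, "X": eff["positive"]})
        with pytest.warns(UserWarning, match="missing"):
            dose_response_summary(summ)
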