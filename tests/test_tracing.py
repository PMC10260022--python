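"""Natural-abundance correction and tracer enrichment comparisons."""

import numpy as np
import pytest
from scipy import stats

from tifmkit import synthetic_data as sd
from tifmkit import tracing


def pure_carbon_table(p13: float) -> tracing.AbundanceTable:
    return tracing.AbundanceTable(
        {"C": [1 - p13, p13], "H": [1.0], "N": [1.0], "O": [1.0]}, version="test"
    )


MONOISOTOPIC = tracing.AbundanceTable(
    {"C": [1.0], "H": [1.0], "N": [1.0], "O": [1.0], "S": [1.0]}, version="mono"
)


class TestFormulaParsing:
    def test_parse_counts(self):
        f = tracing.ElementalFormula.parse("C6H14N4O2", "N", 2)
        assert f.counts == {"C": 6, "H": 14, "N": 4, "O": 2}
        assert f.max_tracer_atoms == 2

    def test_tracer_capacity_enforced(self):
        with pytest.raises(ValueError, match="exceeds"):
            tracing.ElementalFormula.parse("C3H7NO2", "N", 2)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            tracing.ElementalFormula.parse("notaformula!")


class TestCorrectionMatrix:
    def test_monoisotopic_abundance_gives_identity(self):
        for formula_str, tracer in [("C1", "C"), ("C6H14N4O2", "C"), ("C5H10N2O3", "N")]:
            f = tracing.ElementalFormula.parse(formula_str, tracer)
            m = tracing.build_correction_matrix(f, MONOISOTOPIC)
            assert np.allclose(m, np.eye(f.max_tracer_atoms + 1))

    def test_two_carbon_binomial_column(self):
        p = 0.0107
        f = tracing.ElementalFormula.parse("C2", "C")
        m = tracing.build_correction_matrix(f, pure_carbon_table(p))
        expect = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        assert np.allclose(m[:, 0], expect)
        # fully labeled column has no free carbon: delta at M+2
        assert np.allclose(m[:, 2], [0, 0, 1])

    def test_c6_skeleton_m1_entry_is_binomial(self):
        p = 0.0107
        f = tracing.ElementalFormula.parse("C6", "C")
        m = tracing.build_correction_matrix(f, pure_carbon_table(p))
        assert m[1, 0] == pytest.approx(6 * p * (1 - p) ** 5, rel=1e-12)

    def test_columns_sum_at_most_one_and_lower_triangular(self, asa_formula, abundances):
        m = tracing.build_correction_matrix(asa_formula, abundances)
        assert np.all(m.sum(axis=0) <= 1.0 + 1e-12)
        assert np.allclose(m, np.tril(m))

    def test_tracer_only_mode_ignores_other_elements(self, abundances):
        f = tracing.ElementalFormula.parse("C2H100", "C")
        full = tracing.build_correction_matrix(f, abundances)
        tronly = tracing.build_correction_matrix(f, abundances, tracer_only=True)
        # hydrogen broadens the full matrix but not the tracer-only one
        p = abundances.distribution("C")[1]
        assert tronly[1, 0] == pytest.approx(2 * p * (1 - p), rel=1e-12)
        assert full[1, 0] > tronly[1, 0]


class TestCorrection:
    def test_pure_unlabeled_recovers_delta(self, asa_formula, abundances):
        m = tracing.build_correction_matrix(asa_formula, abundances)
        raw = tracing.IsotopologueVector("asa", m[:, 0])
        corr = tracing.correct_natural_abundance(raw, m)
        expect = np.zeros(6)
        expect[0] = 1.0
        assert np.allclose(corr.values, expect, atol=1e-9)
        assert corr.corrected

    def test_forward_convolve_round_trip(self, asa_formula, abundances):
        m = tracing.build_correction_matrix(asa_formula, abundances)
        x = np.array([0.5, 0.5, 0, 0, 0, 0])
        corr = tracing.correct_natural_abundance(
            tracing.IsotopologueVector("asa", m @ x), m
        )
        assert np.allclose(corr.values, x, atol=1e-9)

    @pytest.mark.parametrize(
        "formula_str,tracer,n",
        [("C1H2O1", "C", None), ("C6H12O6", "C", None), ("C20H30N5O10S2", "C", None),
         ("C5H10N2O3", "N", None), ("C6H14N4O2", "N", 4)],
    )
    def test_round_trip_random_probability_vectors(self, formula_str, tracer, n, abundances, rng):
        """correct(matrix @ x) = x for random probability vectors."""
        f = tracing.ElementalFormula.parse(formula_str, tracer, n)
        m = tracing.build_correction_matrix(f, abundances)
        for _ in range(25):
            x = rng.dirichlet(np.ones(f.max_tracer_atoms + 1))
            corr = tracing.correct_natural_abundance(
                tracing.IsotopologueVector("x", m @ x), m
            )
            np.testing.assert_allclose(corr.values, x, atol=1e-9)

    def test_corrected_mid_is_probability_vector(self, asa_formula, abundances, rng):
        m = tracing.build_correction_matrix(asa_formula, abundances)
        raw = tracing.IsotopologueVector("asa", rng.uniform(0.0, 1.0, 6))
        corr = tracing.correct_natural_abundance(raw, m)
        assert np.all(corr.values >= 0)
        assert corr.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noisy_correction_close_to_truth(self, asa_formula, abundances):
        gt = sd.default_ground_truth(seed=11)
        raw, true_mid = sd.simulate_labeling(
            gt, asa_formula, abundances, noise_sd=0.005,
            rng=np.random.default_rng(11),
        )
        m = tracing.build_correction_matrix(asa_formula, abundances)
        corr = tracing.correct_natural_abundance(raw, m)
        assert np.max(np.abs(corr.values - true_mid)) < 0.02

    def test_all_zero_input_rejected(self, asa_formula, abundances):
        m = tracing.build_correction_matrix(asa_formula, abundances)
        with pytest.raises(ValueError, match="all-zero"):
            tracing.correct_natural_abundance(
                tracing.IsotopologueVector("x", np.zeros(6)), m
            )


class TestLabeledFraction:
    @pytest.mark.parametrize(
        "values,expect",
        [([1, 0, 0], 0.0), ([0, 0, 1], 1.0), ([0.52, 0.13, 0.35], 0.48)],
    )
    def test_complement_of_m0(self, values, expect):
        mid = tracing.IsotopologueVector("m", np.array(values), corrected=True)
        assert tracing.labeled_fraction(mid) == pytest.approx(expect)

    def test_uncorrected_input_refused(self):
        mid = tracing.IsotopologueVector("m", np.array([0.9, 0.1]), corrected=False)
        with pytest.raises(ValueError, match="corrected"):
            tracing.labeled_fraction(mid)

    def test_monotone_in_m0(self):
        fracs = [
            tracing.labeled_fraction(
                tracing.IsotopologueVector("m", np.array([m0, 1 - m0]), corrected=True)
            )
            for m0 in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(fracs) <= 0)


class TestSynthesisFraction:
    def test_direct_read_of_diagnostic_shift(self):
        mid = tracing.IsotopologueVector(
            "arg", np.array([0.5, 0, 0, 0, 0, 0.5]), corrected=True
        )
        assert tracing.synthesis_fraction_from_precursor(mid, 5) == pytest.approx(0.5)

    def test_unlabeled_pool_is_zero(self):
        mid = tracing.IsotopologueVector(
            "arg", np.array([1.0, 0, 0, 0, 0, 0]), corrected=True
        )
        assert tracing.synthesis_fraction_from_precursor(mid, 5) == 0.0

    def test_shift_beyond_capacity_errors(self):
        mid = tracing.IsotopologueVector("arg", np.array([1.0, 0.0]), corrected=True)
        with pytest.raises(ValueError, match="exceeds"):
            tracing.synthesis_fraction_from_precursor(mid, 5)

    def test_non_steady_state_refused(self):
        mid = tracing.IsotopologueVector("arg", np.array([0.5, 0.5]), corrected=True)
        with pytest.raises(ValueError, match="non-steady-state"):
            tracing.synthesis_fraction_from_precursor(mid, 1, steady_state=False)

    def test_end_to_end_simulation(self, asa_formula, abundances):
        """45% synthesized from fully labeled precursor: convolve, correct, read."""
        gt = sd.default_ground_truth(seed=2)
        assert gt.synthesis_fraction == 0.45
        raw, _ = sd.simulate_labeling(gt, asa_formula, abundances)
        m = tracing.build_correction_matrix(asa_formula, abundances)
        corr = tracing.correct_natural_abundance(raw, m)
        got = tracing.synthesis_fraction_from_precursor(corr, 5)
        assert got == pytest.approx(0.45, abs=0.01)


class TestExcessEnrichment:
    def make_pairs(self, diffs, base=0.8):
        tissue, plasma = {}, {}
        for i, d in enumerate(diffs):
            plasma[f"a{i}"] = tracing.IsotopologueVector(
                "arg", np.array([base, 1 - base]), corrected=True
            )
            tissue[f"a{i}"] = tracing.IsotopologueVector(
                "arg", np.array([base - d, 1 - base + d]), corrected=True
            )
        return tissue, plasma

    def test_identical_compartments(self):
        tissue, plasma = self.make_pairs([0.0] * 5)
        rep = tracing.excess_enrichment(tissue, plasma)
        assert np.allclose(rep["mean_difference"], 0.0)
        assert np.allclose(rep["p_one_tailed"], 0.5)

    def test_constant_positive_difference_underflows(self):
        tissue, plasma = self.make_pairs([0.05] * 4)
        rep = tracing.excess_enrichment(tissue, plasma)
        labeled = rep[rep["isotopologue"] == 1].iloc[0]
        assert labeled["p_one_tailed"] == np.finfo(float).tiny
        assert np.isinf(labeled["t"])

    def test_matches_paired_t_test(self, rng):
        diffs = rng.normal(0.03, 0.01, 7)
        tissue, plasma = self.make_pairs(diffs)
        rep = tracing.excess_enrichment(tissue, plasma)
        labeled = rep[rep["isotopologue"] == 1].iloc[0]
        t_vals = np.vstack([tissue[f"a{i}"].values[1] for i in range(7)])
        p_vals = np.vstack([plasma[f"a{i}"].values[1] for i in range(7)])
        oracle = stats.ttest_rel(t_vals.ravel(), p_vals.ravel(), alternative="greater")
        assert labeled["t"] == pytest.approx(float(oracle.statistic), rel=1e-9)
        assert labeled["p_one_tailed"] == pytest.approx(float(oracle.pvalue), rel=1e-9)

    def test_unpaired_ids_listed(self):
        tissue, plasma = self.make_pairs([0.1, 0.1])
        del plasma["a1"]
        plasma["b9"] = tissue["a0"]
        with pytest.raises(ValueError, match="a1"):
            tracing.excess_enrichment(tissue, plasma)

    def test_abundance_table_versioned(self, abundances):
        assert abundances.version.startswith("IUPAC")
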