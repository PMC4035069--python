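from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from oracles import ac_pmf_equal_depths, ac_two_sided, bh_stepup
from ovamir.diffexpr import (
    RATIO_GT2,
    RATIO_LE_HALF,
    RATIO_MID,
    adjust_and_filter,
    bh_qvalues,
    cluster_de,
    de_table,
    exact_count_pvalue,
    fold_change,
    normalize_tpm,
    sig_label,
)
from ovamir.synthetic_data import SimulationConfig
from conftest import make_study


class TestNormalizeTpm:
    def test_printed_example(self):
        assert normalize_tpm(5214, 5_948_837) == pytest.approx(876.47, abs=0.01)

    def test_identity(self):
        assert normalize_tpm(1234, 1234) == 1e6

    def test_zero_count(self):
        assert normalize_tpm(0, 100) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_tpm(1, 0)
        with pytest.raises(ValueError):
            normalize_tpm(-1, 10)


class TestAdjustAndFilter:
    def _frame(self, pairs):
        return pd.DataFrame([{"mirna_id": f"m{i}", "std_lib1": a, "std_lib2": b}
                             for i, (a, b) in enumerate(pairs)])

    def test_zero_revised_and_retained(self):
        out = adjust_and_filter(self._frame([(0.0, 50.0)]))
        assert out.loc[0, "std_lib1"] == 0.01 and out.loc[0, "std_lib2"] == 50.0

    def test_both_below_one_dropped(self):
        assert len(adjust_and_filter(self._frame([(0.4, 0.9)]))) == 0

    def test_boundary_exactly_one_retained(self):
        assert len(adjust_and_filter(self._frame([(1.0, 0.2)]))) == 1


class TestExactCountPvalue:
    def test_no_evidence_capped_at_one(self):
        assert exact_count_pvalue(0, 0, 1_000_000, 1_000_000) == 1.0

    def test_closed_form_termwise_equal_depths(self):
        # pmf at N1 == N2 must equal C(x+k, x) / 2^(x+k+1) term by term
        for x in (0, 1, 5, 20):
            for k in range(0, 30):
                expected = float(ac_pmf_equal_depths(k, x))
                got = float(nbinom.pmf(k, x + 1, 0.5))
                assert got == pytest.approx(expected, rel=1e-12)

    def test_tail_example_x1_y0(self):
        # P(Y <= 0 | x=1) = 1/4 exactly; doubled -> 0.5
        assert exact_count_pvalue(1, 0, 500, 500) == pytest.approx(0.5, rel=1e-12)

    def test_brute_force_oracle_case(self):
        got = exact_count_pvalue(50, 5, 1_000_000, 1_000_000)
        expected = float(ac_two_sided(50, 5, 1_000_000, 1_000_000))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_brute_force_oracle_unequal_depths(self):
        got = exact_count_pvalue(12, 40, 2_000_000, 3_000_000)
        expected = float(ac_two_sided(12, 40, 2_000_000, 3_000_000))
        assert got == pytest.approx(expected, rel=1e-10)

    @given(st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=40, deadline=None)
    def test_swap_duality_termwise(self, x, y):
        # the conditional law obeys the exact duality
        # p(y | x; N1, N2) = (N1/N2) * p(x | y; N2, N1);
        # the two-sided p-value is therefore only approximately symmetric
        # under library relabelling (see test below), never to 1e-12.
        n1, n2 = 1_500_000, 900_000
        lhs = float(nbinom.pmf(y, x + 1, n1 / (n1 + n2)))
        rhs = (n1 / n2) * float(nbinom.pmf(x, y + 1, n2 / (n1 + n2)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @given(st.integers(20, 200), st.integers(20, 200))
    @settings(max_examples=40, deadline=None)
    def test_swap_symmetry_approximate(self, x, y):
        p1 = exact_count_pvalue(x, y, 1_500_000, 900_000)
        p2 = exact_count_pvalue(y, x, 900_000, 1_500_000)
        if p1 > 0 and p2 > 0:
            assert abs(np.log10(p1) - np.log10(p2)) < 1.0

    def test_monotone_in_discrepancy(self):
        x, n = 30, 1_000_000
        up = [exact_count_pvalue(x, y, n, n) for y in range(30, 120, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(up, up[1:]))
        down = [exact_count_pvalue(x, y, n, n) for y in range(30, 0, -5)]
        assert all(a >= b - 1e-12 for a, b in zip(down, down[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_count_pvalue(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            exact_count_pvalue(0, 0, 0, 10)


class TestFoldChange:
    def test_doubling_class(self):
        fc, cls = fold_change(10, 40)
        assert fc == pytest.approx(2.0) and cls == RATIO_GT2

    def test_antisymmetry(self):
        fc, cls = fold_change(40, 10)
        assert fc == pytest.approx(-2.0) and cls == RATIO_LE_HALF

    def test_equal_is_mid(self):
        fc, cls = fold_change(7, 7)
        assert fc == 0.0 and cls == RATIO_MID

    def test_boundaries(self):
        assert fold_change(10, 20)[1] == RATIO_MID      # ratio exactly 2
        assert fold_change(20, 10)[1] == RATIO_LE_HALF  # ratio exactly 1/2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0, 5)


class TestSigLabel:
    @pytest.mark.parametrize("fc,p,expected", [
        (1.5, 0.005, "**"),
        (0.5, 0.001, "None"),
        (-2.0, 0.03, "*"),
        (1.5, 0.05, "None"),
        (1.0, 0.001, "None"),   # |fc| must exceed 1 strictly
        (-3.0, 0.0099, "**"),
        (2.0, 0.01, "*"),       # boundary p = 0.01 is single-star
    ])
    def test_rule(self, fc, p, expected):
        assert sig_label(fc, p) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sig_label(float("nan"), 0.5)


class TestBH:
    def test_hand_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.9]))
        assert q == pytest.approx([0.03, 0.03, 0.9])

    def test_all_equal(self):
        assert bh_qvalues(np.array([0.2, 0.2, 0.2])) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        assert bh_qvalues(p) == pytest.approx(bh_stepup(list(p)))


class TestDeTable:
    def test_null_calibration(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_mirnas=300, library_depths=(50_000, 50_000),
                               de_fraction=0.0, contamination_fractions={},
                               n_novel_hairpins=0)
        study = make_study(cfg, tmp_path)
        from ovamir.quantify import assign_tags_to_mirnas
        rec, _ = assign_tags_to_mirnas(study.annotated, study.refs.bundle.mature)
        de = de_table(rec, study.report1.clean_reads, study.report2.clean_reads)
        assert (de["pvalue"] < 0.05).mean() <= 0.07

    def test_orientation_configurable(self, expression_records, small_study):
        n1 = small_study.report1.clean_reads
        n2 = small_study.report2.clean_reads
        a = de_table(expression_records, n1, n2, control="lib1").set_index("mirna_id")
        b = de_table(expression_records, n1, n2, control="lib2").set_index("mirna_id")
        common = a.index.intersection(b.index)
        assert a.loc[common, "log2fc"].to_numpy() == pytest.approx(
            -b.loc[common, "log2fc"].to_numpy())
        # p-values condition on the control count, so orientation changes
        # them only mildly (exact symmetry is impossible; see duality test)
        pa = a.loc[common, "pvalue"].to_numpy()
        pb = b.loc[common, "pvalue"].to_numpy()
        mask = (pa > 1e-300) & (pb > 1e-300)
        assert np.all(np.abs(np.log10(pa[mask]) - np.log10(pb[mask])) < 2.0)


class TestClusterDe:
    def _frame(self, profiles):
        return pd.DataFrame([
            {"mirna_id": f"m{i}", "std_lib1": a, "std_lib2": b, "sig_label": "**"}
            for i, (a, b) in enumerate(profiles)])

    def test_identical_profiles_merge_at_zero(self):
        tree = cluster_de(self._frame([(8, 2), (8, 2)]))
        assert tree.linkage[0, 2] == 0.0

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            cluster_de(self._frame([(8, 2)]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        profiles = [(float(a), float(b)) for a, b in rng.uniform(1, 100, size=(12, 2))]
        t1 = cluster_de(self._frame(profiles))
        t2 = cluster_de(self._frame(profiles[::-1]))
        assert sorted(t1.linkage[:, 2]) == pytest.approx(sorted(t2.linkage[:, 2]))

    def test_two_block_recovery(self):
        rng = np.random.default_rng(8)
        up = [(10 * (1 + 0.05 * rng.standard_normal()),
               160 * (1 + 0.05 * rng.standard_normal())) for _ in range(6)]
        down = [(160 * (1 + 0.05 * rng.standard_normal()),
                 10 * (1 + 0.05 * rng.standard_normal())) for _ in range(6)]
        tree = cluster_de(self._frame(up + down))
        labels = tree.cut(2)
        up_labels = {labels[f"m{i}"] for i in range(6)}
        down_labels = {labels[f"m{i}"] for i in range(6, 12)}
        assert len(up_labels) == 1 and len(down_labels) == 1
        assert up_labels != down_labels

    def test_newick_parses(self):
        import dendropy

        tree = cluster_de(self._frame([(8, 2), (9, 2), (2, 64)]))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 3
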