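"""Welch/Student t, permutation FDR, interactor calling, ANOVA, Sidak,
Tukey, ELISA normalization — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phagoquant import stats, synthgen
from phagoquant.synthgen import TmtSimConfig, TmtTable, simulate_tmt


def _table(rows):
    frame = pd.DataFrame(rows)
    return TmtTable(
        frame=frame,
        control_cols=[c for c in frame.columns if c.startswith("control")],
        gfp_cols=[c for c in frame.columns if c.startswith("gfp")],
    )


def _row(pid, values, peptides=5, con=False, rev=False):
    d = {"protein_id": pid}
    for i, v in enumerate(values[:4]):
        d[f"control_{i + 1}"] = v
    for i, v in enumerate(values[4:]):
        d[f"gfp_{i + 1}"] = v
    d.update(unique_peptides=peptides, is_contaminant=con, is_reverse=rev)
    return d


class TestPreprocess:
    def test_stated_filters(self):
        rows = [
            _row("A", [8.0] * 8),
            _row("B", [8.0] * 8, rev=True),
            _row("C", [8.0] * 8, peptides=1),
            _row("D", [8.0] * 8),
            _row("E", [8.0] * 8),
        ]
        out = stats.preprocess_tmt(_table(rows))
        assert list(out.index) == ["A", "D", "E"]
        assert (out.to_numpy() == 3.0).all()  # log2(8) = 3

    def test_zero_rows_dropped_by_default(self):
        rows = [_row("A", [8.0] * 8), _row("B", [8.0] * 7 + [0.0])]
        out = stats.preprocess_tmt(_table(rows))
        assert list(out.index) == ["A"]

    def test_zero_offset_option(self):
        rows = [_row("B", [0.0] + [7.0] * 7)]
        out = stats.preprocess_tmt(_table(rows), zero_policy="offset", zero_offset=1.0)
        assert out.iloc[0, 0] == 0.0  # log2(0 + 1)
        assert out.iloc[0, 1] == 3.0

    def test_all_filtered_raises_with_dominant_filter(self):
        rows = [_row("A", [8.0] * 8, rev=True), _row("B", [8.0] * 8, con=True)]
        with pytest.raises(ValueError, match="contaminant/reverse"):
            stats.preprocess_tmt(_table(rows))

    def test_seeded_table_retained_count(self):
        cfg = TmtSimConfig(n_proteins=2000, n_contaminants=10, n_reverse=5,
                           peptide_poisson_mean=5.0, rng_seed=0)
        table, _ = simulate_tmt(cfg)
        out = stats.preprocess_tmt(table)
        n_low_pep = int(
            (table.frame.loc[~(table.frame.is_contaminant | table.frame.is_reverse),
                             "unique_peptides"] < 2).sum()
        )
        assert len(out) == 2000 - 15 - n_low_pep


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = stats.welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert (t, p) == (0.0, 1.0)

    def test_equal_variance_equal_n_df_collapses(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = stats.welch_t(a, a + 10.0)
        assert df == pytest.approx(6.0, abs=1e-12)
        # direct formula: diff / sqrt(2 * s^2 / n)
        s2 = a.var(ddof=1)
        assert abs(t) == pytest.approx(10.0 / np.sqrt(2 * s2 / 4), rel=1e-12)

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n1, n2 = rng.integers(2, 12, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n1)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n2)
            t, df, p = stats.welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert df == pytest.approx(ref.df, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_constant_groups_unequal_means(self):
        t, df, p = stats.welch_t([3.0, 3.0], [1.0, 1.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t([1.0], [1.0, 2.0])


class TestStudentT:
    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 6)
        t, df, p = stats.student_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert df == 12


@pytest.fixture(scope="module")
def spike_result():
    cfg = TmtSimConfig(
        n_proteins=2000, n_true_interactors=50, interactor_log2fc=5.0,
        background_log2_sd=0.2, rng_seed=11,
    )
    table, truth = simulate_tmt(cfg)
    log2 = stats.preprocess_tmt(table)
    res = stats.permutation_fdr(log2, gfp_cols=table.gfp_cols, rng_seed=3)
    return table, truth, res


class TestPermutationFdr:

    def test_spike_ins_fully_recovered(self, spike_result):
        table, truth, res = spike_result
        called = set(stats.call_interactors(res.table).protein_id)
        true_ids = set(truth.loc[truth.is_interactor, "protein_id"])
        assert called == true_ids

    def test_levels_nest(self, spike_result):
        _, _, res = spike_result
        assert (res.table.significant_1pct <= res.table.significant_5pct).all()

    def test_fdr_curve_monotone(self, spike_result):
        _, _, res = spike_result
        assert (np.diff(res.fdr_curve.fdr) <= 1e-12).all()

    def test_null_table_rarely_calls(self):
        hits = 0
        for seed in range(20):
            table, _ = simulate_tmt(TmtSimConfig(n_proteins=500, rng_seed=300 + seed))
            log2 = stats.preprocess_tmt(table)
            res = stats.permutation_fdr(log2, gfp_cols=table.gfp_cols, rng_seed=seed)
            hits += int(res.table.significant_1pct.any())
        assert hits <= 2  # >= 95% of null runs make no 1% calls

    def test_invariant_to_row_order(self):
        table, _ = simulate_tmt(
            TmtSimConfig(n_proteins=300, n_true_interactors=10, rng_seed=8)
        )
        log2 = stats.preprocess_tmt(table)
        res1 = stats.permutation_fdr(log2, gfp_cols=table.gfp_cols, rng_seed=1)
        shuffled = log2.sample(frac=1.0, random_state=4)
        res2 = stats.permutation_fdr(shuffled, gfp_cols=table.gfp_cols, rng_seed=1)
        s1 = res1.table.set_index("protein_id").significant_1pct
        s2 = res2.table.set_index("protein_id").significant_1pct
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_too_few_permutations_rejected(self):
        table, _ = simulate_tmt(TmtSimConfig(n_proteins=50, rng_seed=0))
        log2 = stats.preprocess_tmt(table)
        with pytest.raises(ValueError):
            stats.permutation_fdr(log2, gfp_cols=table.gfp_cols, n_permutations=50)


class TestInteractorCalls:
    def _results(self):
        return pd.DataFrame(
            {
                "protein_id": ["a", "b", "c", "d"],
                "log2fc": [np.log2(1.9), np.log2(4.0), np.log2(2.5), np.log2(3.5)],
                "significant_1pct": [True, False, True, True],
            }
        )

    def test_fold_rule_is_strict(self):
        called = stats.call_interactors(self._results())
        assert list(called.protein_id) == ["c", "d"]  # a: fold <= 2; b: not significant

    def test_top_set_fold_floor_and_ordering(self):
        top = stats.top_set(self._results(), fold_min=3.0, k=50)
        assert list(top.protein_id) == ["b", "d"]  # sorted by descending fold

    def test_missing_level_is_an_error(self):
        with pytest.raises(ValueError):
            stats.call_interactors(self._results(), fdr_level=0.10)


def _brute_force_ss(y, fa, fb):
    """Oracle: balanced two-way sums of squares by cell/marginal means."""
    y = np.asarray(y, float)
    a_lv = sorted(set(fa))
    b_lv = sorted(set(fb))
    grand = y.mean()
    ss_a = sum(
        sum((fa == al)) * (y[np.asarray(fa) == al].mean() - grand) ** 2 for al in a_lv
    )
    ss_b = sum(
        sum((fb == bl)) * (y[np.asarray(fb) == bl].mean() - grand) ** 2 for bl in b_lv
    )
    ss_cells = 0.0
    ss_resid = 0.0
    for al in a_lv:
        for bl in b_lv:
            sel = (np.asarray(fa) == al) & (np.asarray(fb) == bl)
            cm = y[sel].mean()
            ss_cells += sel.sum() * (cm - grand) ** 2
            ss_resid += ((y[sel] - cm) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return ss_a, ss_b, ss_ab, ss_resid


class TestTwoWayAnova:
    def _fixture(self):
        rng = np.random.default_rng(21)
        fa = np.repeat(["g1", "g2"], 6)
        fb = np.tile(np.repeat(["t1", "t2"], 3), 2)
        y = rng.normal(0, 1, 12) + (fa == "g2") * 1.5 + (fb == "t2") * 0.7
        return y, fa, fb

    def test_balanced_matches_brute_force(self):
        y, fa, fb = self._fixture()
        tab = stats.two_way_anova(y, fa, fb)
        ss_a, ss_b, ss_ab, ss_resid = _brute_force_ss(y, fa, fb)
        assert tab.loc["A", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert tab.loc["B", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert tab.loc["A:B", "sum_sq"] == pytest.approx(ss_ab, rel=1e-9)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_resid, rel=1e-9)

    def test_ss_decomposition_exact(self):
        y, fa, fb = self._fixture()
        tab = stats.two_way_anova(y, fa, fb)
        parts = tab.loc[["A", "B", "A:B", "Residual"], "sum_sq"].sum()
        assert parts == pytest.approx(tab.loc["Total", "sum_sq"], rel=1e-9)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y, fa, fb = self._fixture()
        tab = stats.two_way_anova(y, fa, fb)
        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        ref = sm.stats.anova_lm(smf.ols("y ~ C(A) * C(B)", df).fit(), typ=2)
        assert tab.loc["A", "F"] == pytest.approx(ref.loc["C(A)", "F"], rel=1e-9)
        assert tab.loc["A", "p"] == pytest.approx(ref.loc["C(A)", "PR(>F)"], rel=1e-9)
        assert tab.loc["A:B", "p"] == pytest.approx(ref.loc["C(A):C(B)", "PR(>F)"], rel=1e-9)

    def test_unbalanced_uses_type2(self):
        y, fa, fb = self._fixture()
        y2 = np.append(y, [2.2, 1.1])
        fa2 = np.append(fa, ["g1", "g1"])
        fb2 = np.append(fb, ["t1", "t1"])
        tab = stats.two_way_anova(y2, fa2, fb2)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        ref = sm.stats.anova_lm(
            smf.ols("y ~ C(A) * C(B)", pd.DataFrame({"y": y2, "A": fa2, "B": fb2})).fit(),
            typ=2,
        )
        assert tab.loc["A", "F"] == pytest.approx(ref.loc["C(A)", "F"], rel=1e-9)

    def test_degenerate_all_equal(self):
        y = np.full(12, 3.0)
        fa = np.repeat(["g1", "g2"], 6)
        fb = np.tile(np.repeat(["t1", "t2"], 3), 2)
        tab = stats.two_way_anova(y, fa, fb)
        assert tab.loc["A", "sum_sq"] == 0.0
        assert tab.attrs.get("degenerate")

    def test_empty_cell_is_an_error(self):
        with pytest.raises(ValueError):
            stats.two_way_anova(
                [1.0, 2.0, 3.0], ["a", "a", "b"], ["x", "y", "x"]
            )


class TestTukeySidak:
    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(m, 1, 8) for m in (0.0, 0.5, 2.0)])
        g = np.repeat(["a", "b", "c"], 8)
        ours = stats.tukey_hsd(y, g)
        ref = pairwise_tukeyhsd(y, g)
        for row, p_ref in zip(ours.itertuples(), ref.pvalues):
            assert row.p_adj == pytest.approx(p_ref, abs=1e-6)

    def test_sidak_identity_at_m1(self):
        assert stats.sidak_adjust(0.05, m=1)[0] == pytest.approx(0.05)

    def test_sidak_formula_and_cap(self):
        assert stats.sidak_adjust(0.01, m=10)[0] == pytest.approx(1 - 0.99**10)
        assert stats.sidak_adjust(0.9, m=50)[0] == 1.0

    def test_sidak_rejects_bad_p(self):
        with pytest.raises(ValueError):
            stats.sidak_adjust([1.5], m=2)


class TestCytokineNormalization:
    @pytest.mark.parametrize(
        "conc,content,reference,expected",
        [
            (200.0, 100.0, 100.0, 200.0),  # identity at the reference
            (200.0, 50.0, 100.0, 400.0),  # proportional rescaling
            (100.0, 250.0, 500.0, 200.0),  # coculture reference is 500 ug
        ],
    )
    def test_arithmetic(self, conc, content, reference, expected):
        assert stats.normalize_cytokine(conc, content, reference) == expected

    def test_non_positive_content_rejected(self):
        with pytest.raises(ValueError):
            stats.normalize_cytokine(100.0, 0.0, 100.0)
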