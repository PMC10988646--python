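"""The rank-correlation screen: statistics, filters, composites, model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirnet import (
    AnalysisConfig,
    ExpressionMatrix,
    MiRNAPhenotypeModel,
    ValidationError,
    composite_domain_score,
    critical_rho,
    normalize_per_subject,
    point_biserial,
    presence_filter,
    rank_with_ties,
    screen,
    spearman,
    summarize,
    summarize_all,
)
from mirnet.association import phenotype_frame

finite_vectors = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False), min_size=4, max_size=30
)


class TestRankWithTies:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 2], [2.5, 2.5, 1]),
            ([0, 0, 0, 7], [2, 2, 2, 4]),
        ],
    )
    def test_mean_rank_rule(self, x, expected):
        np.testing.assert_allclose(rank_with_ties(x).values, expected)

    def test_tie_groups_recorded(self):
        assert rank_with_ties([0, 0, 0, 7]).tie_groups == (3,)
        assert rank_with_ties([1, 2, 3]).tie_groups == ()

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            rank_with_ties([1.0, np.nan, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_vectors)
    def test_rank_sum_conserved_and_bounded(self, x):
        r = rank_with_ties(x)
        n = r.n
        assert np.isclose(r.values.sum(), n * (n + 1) / 2)
        assert r.values.min() >= 1 and r.values.max() <= n


class TestSpearman:
    def test_identity_gives_rho_one_with_floored_p(self):
        rho, p, n = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0, abs=1e-14)
        assert 0 < p <= np.finfo(float).tiny
        assert n == 5

    def test_single_swap_matches_closed_form(self):
        # tie-free closed form 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        rho, _, _ = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9, abs=1e-12)

    def test_tied_case_matches_pearson_on_ranks_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 1, 2]
        rho, _, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho == pytest.approx(stats.pearsonr(rx, ry).statistic, abs=1e-12)

    def test_matches_scipy_oracle_on_1000_random_vectors(self):
        # independent oracle: scipy.stats.spearmanr handles ties the same way
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(5, 30)
            x = rng.integers(0, n // 2 + 2, size=n).astype(float)  # force ties
            y = rng.normal(size=n)
            if np.ptp(stats.rankdata(x)) == 0:
                continue
            rho, p, _ = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_sign_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=12).astype(float)
        y = rng.permutation(np.arange(12)).astype(float)  # tie-free
        if np.ptp(x) == 0:
            return
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0], abs=1e-12)
        assert spearman(x, -y)[0] == pytest.approx(-spearman(x, y)[0], abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPointBiserial:
    def test_known_value(self):
        r, p, n = point_biserial([0, 0, 1, 1], [1, 2, 3, 4])
        assert r == pytest.approx(0.894427, abs=1e-6)
        assert n == 4

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            point_biserial([0, 0, 0, 0], [1, 2, 3, 4])

    def test_equals_pearson_on_binary_codes(self):
        rng = np.random.default_rng(3)
        b = rng.integers(0, 2, size=20).astype(float)
        y = rng.normal(size=20)
        r, p, _ = point_biserial(b, y)
        ref = stats.pearsonr(b, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestCriticalRho:
    def test_study_scale_bound(self):
        # at the cohort size n = 26 the screen admits |rho| >= ~0.388,
        # consistent with (and just above) the printed bound 0.38
        assert critical_rho(26, 0.05) == pytest.approx(0.3882, abs=5e-4)
        assert critical_rho(26, 0.05) >= 0.38

    def test_small_n(self):
        assert critical_rho(5, 0.05) == pytest.approx(0.8783, abs=5e-4)

    def test_monotone_in_n_and_alpha(self):
        rhos = [critical_rho(n, 0.05) for n in range(5, 60, 5)]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))
        assert critical_rho(26, 1e-8) > critical_rho(26, 0.05)
        assert critical_rho(26, 1e-12) > 0.9  # threshold -> 1 as alpha -> 0

    def test_threshold_is_exact_boundary(self):
        rc = critical_rho(26, 0.05)
        n = 26
        t = rc * np.sqrt((n - 2) / (1 - rc**2))
        assert 2 * stats.t.sf(t, n - 2) == pytest.approx(0.05, abs=1e-10)


class TestNormalizeAndPresence:
    def test_column_arithmetic(self):
        df = pd.DataFrame({"s1": [2.0, 3.0, 5.0]}, index=["a", "b", "c"])
        out = normalize_per_subject(ExpressionMatrix(df))
        np.testing.assert_allclose(out.counts["s1"], [0.2, 0.3, 0.5])
        assert out.normalized

    def test_zero_total_column_names_subject(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="s2"):
            normalize_per_subject(ExpressionMatrix(df))

    def test_columns_sum_to_one(self, tiny_counts):
        out = normalize_per_subject(tiny_counts)
        np.testing.assert_allclose(out.counts.sum(axis=0), 1.0, atol=1e-9)

    def test_presence_boundary_inclusive(self):
        n_subj = 26
        row_11 = np.r_[np.ones(11), np.zeros(n_subj - 11)]
        row_10 = np.r_[np.ones(10), np.zeros(n_subj - 10)]
        df = pd.DataFrame([row_11, row_10], index=["keep", "drop"],
                          columns=[f"s{i}" for i in range(n_subj)])
        kept = presence_filter(ExpressionMatrix(df), 11)
        assert kept.mirna_ids == ["keep"]

    def test_min_present_one_is_identity(self, tiny_counts):
        assert presence_filter(tiny_counts, 1).mirna_ids == tiny_counts.mirna_ids


class TestCompositeScore:
    def test_single_test_domain_is_its_zscore(self, tiny_cohort, domain_map):
        dom = "perceptual speed"
        tests = domain_map.domains[dom]
        comp = composite_domain_score(tiny_cohort, domain_map, dom)
        z = (tiny_cohort.df[tests] - tiny_cohort.df[tests].mean()) / tiny_cohort.df[tests].std(ddof=1)
        np.testing.assert_allclose(comp, z.mean(axis=1))

    def test_constant_shift_invariance(self, tiny_cohort, domain_map):
        before = composite_domain_score(tiny_cohort, domain_map, "semantic memory")
        df = tiny_cohort.df.copy().drop(columns="group")
        df["bost.nam"] = df["bost.nam"] + 100.0
        from mirnet import CohortTable

        shifted = CohortTable(df, tests=tiny_cohort.tests)
        after = composite_domain_score(shifted, domain_map, "semantic memory")
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_balanced_zscores_cancel(self, tiny_cohort, domain_map):
        # craft two tests whose z-scores are exact negatives: composite = 0
        from mirnet import CohortTable, DomainMap

        df = tiny_cohort.df.copy().drop(columns="group")
        df["t_plus"] = np.arange(8.0)
        df["t_minus"] = -np.arange(8.0)
        dm = DomainMap(domains={"toy": ["t_plus", "t_minus"]})
        c = CohortTable(df, tests=["t_plus", "t_minus"])
        np.testing.assert_allclose(composite_domain_score(c, dm, "toy"), 0.0, atol=1e-12)

    def test_all_missing_subject_reported(self, tiny_cohort, domain_map):
        from mirnet import CohortTable

        df = tiny_cohort.df.copy().drop(columns="group")
        tests = domain_map.domains["perceptual speed"]
        df.loc[0, tests] = np.nan
        c = CohortTable(df, tests=tiny_cohort.tests)
        with pytest.raises(ValidationError, match="T0"):
            composite_domain_score(c, domain_map, "perceptual speed")


class TestScreen:
    def test_phenotype_frame_covers_screen_set(self, tiny_cohort, domain_map):
        cols = phenotype_frame(tiny_cohort, domain_map).columns
        for must in ["age", "educ", "sex", "mmse", "glob.cog", "epis.mem", "sem.mem",
                     "work.mem", "perc.or", "perc.sp", "braak", "cerad", "niareagan",
                     "6e10", "at8"]:
            assert must in cols
        assert len(cols) == 15 + 19

    def test_sign_definition(self, fitted):
        rec = fitted.records
        assert (rec.loc[rec["rho"] > 0, "sign"] == "positive").all()
        assert (rec.loc[rec["rho"] < 0, "sign"] == "negative").all()

    def test_sex_uses_point_biserial(self, fitted):
        rec = fitted.records_all
        assert (rec.loc[rec["phenotype"] == "sex", "statistic_kind"] == "point_biserial_r").all()
        other = rec[rec["phenotype"] != "sex"]
        assert (other["statistic_kind"] == "spearman_rho").all()

    def test_lowering_alpha_never_adds_records(self, counts, cohort):
        norm = presence_filter(normalize_per_subject(counts), 11)
        loose = screen(norm, cohort, cfg=AnalysisConfig(alpha=0.05))
        strict = screen(norm, cohort, cfg=AnalysisConfig(alpha=0.01))
        key = lambda df: set(zip(df["mirna"], df["phenotype"]))
        assert key(strict) <= key(loose)

    def test_raising_min_present_never_adds_mirnas(self, counts, cohort):
        norm = normalize_per_subject(counts)
        m_low = presence_filter(norm, 5)
        m_high = presence_filter(norm, 20)
        assert set(m_high.mirna_ids) <= set(m_low.mirna_ids)
        rec_low = screen(m_low, cohort)
        rec_high = screen(m_high, cohort)
        assert set(rec_high["mirna"]) <= set(rec_low["mirna"])

    def test_all_significant_exceed_critical_rho(self, fitted, cohort):
        rec = fitted.records
        full_n = rec[rec["n_used"] == cohort.n_subjects]
        assert (full_n["rho"].abs() >= critical_rho(cohort.n_subjects, 0.05) - 1e-12).all()

    def test_pairwise_complete_logs_n_used(self, fitted, cohort):
        # the default simulation hides pathology loads for two stage-III
        # subjects; those phenotypes use fewer subjects
        rec = fitted.records_all
        loads = rec[rec["phenotype"].isin(["6e10", "at8"])]
        assert (loads["n_used"] == cohort.n_subjects - 2).all()

    def test_fdr_mode_only_removes(self, counts, cohort):
        norm = presence_filter(normalize_per_subject(counts), 11)
        plain = screen(norm, cohort, cfg=AnalysisConfig())
        bh = screen(norm, cohort, cfg=AnalysisConfig(fdr_q=0.1))
        assert bh["q"].notna().all()
        key = lambda df: set(zip(df["mirna"], df["phenotype"]))
        assert key(bh) <= key(plain)


class TestSummarize:
    def test_direct_example(self):
        rec = pd.DataFrame(
            {
                "mirna": ["a", "b", "c"],
                "phenotype": ["age"] * 3,
                "rho": [0.39, 0.47, 0.72],
                "p": [0.04, 0.02, 0.0001],
                "sign": ["positive"] * 3,
                "highlight": [False, False, True],
            }
        )
        s = summarize(rec, "age", "positive")
        assert s.count == 3
        assert s.median_rho == pytest.approx(0.47)
        assert s.rho_range == (0.39, 0.72)
        assert s.highlighted == ("c",)

    def test_even_count_median_is_central_mean(self):
        rec = pd.DataFrame(
            {
                "mirna": ["a", "b"],
                "phenotype": ["sem.mem"] * 2,
                "rho": [-0.4, -0.6],
                "p": [0.03, 0.01],
                "sign": ["negative"] * 2,
                "highlight": [False, False],
            }
        )
        s = summarize(rec, "sem.mem", "negative")
        assert s.median_rho == pytest.approx(-0.5)

    def test_empty_subset_flagged(self, example_records):
        s = summarize(example_records, "braak", "positive")
        assert s.count == 0 and s.median_rho is None and s.rho_range is None

    def test_summarize_all_counts_match(self, example_records):
        summ = summarize_all(example_records)
        assert summ["count"].sum() == len(example_records)
        row = summ[(summ["phenotype"] == "age") & (summ["sign"] == "positive")].iloc[0]
        assert row["count"] == 3 and row["n_highlighted"] == 1


class TestModelResults:
    def test_fit_produces_consistent_results(self, fitted, counts):
        assert fitted.n_mirna_tested <= counts.shape[0]
        assert fitted.n_mirna_significant == fitted.records["mirna"].nunique()
        assert (fitted.records["p"] < fitted.config.alpha).all()

    def test_summary_text_mentions_key_figures(self, fitted):
        text = fitted.summary()
        assert str(fitted.n_mirna_tested) in text
        assert "alpha" in text

    def test_subject_mismatch_rejected(self, counts, tiny_cohort):
        with pytest.raises(ValidationError, match="subject"):
            MiRNAPhenotypeModel(counts, tiny_cohort)
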