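"""Exon-skipping index: parsing, centering, index, incidence, group tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from exonskip.exon_index import (
    ParseError,
    ProbeAlignmentRecord,
    build_exon_map,
    call_incidence,
    compute_delta_index,
    dunnett_posthoc,
    median_center_sample,
    one_way_anova,
    parse_probe_alignments,
    reference_interval,
)
from exonskip.fixtures import load_probe_alignments
from exonskip.preprocess import rma_preprocess
from exonskip.synthetic import (
    CASE_GROUP,
    REFERENCE_GROUP,
    SkipFractionModel,
    default_cohort_spec,
    simulate_index_cohort,
    simulate_probe_intensities,
)


class TestParsing:
    def test_printed_records_parse_with_expected_exon_counts(self, printed_alignment_text):
        records = parse_probe_alignments(printed_alignment_text)
        assert len(records) == 10
        by_exon = {}
        for r in records:
            by_exon.setdefault(r.exon_label, []).append(r)
        assert len(by_exon["Exon 12"]) == 3
        flanking = [r for r in records if r.exon_label != "Exon 12"]
        assert len(flanking) == 7
        assert {r.exon_label for r in flanking} == {"Exon 10", "Exon 11", "Exon 13", "Exon 14"}

    def test_coordinates_and_ids_extracted(self, printed_alignment_text):
        records = {r.probe_id: r for r in parse_probe_alignments(printed_alignment_text)}
        r7 = records["HG-U133_PLUS_2:217422_S_AT_7"]
        assert (r7.chrom, r7.start, r7.end, r7.exon_label) == ("chr19", 35836590, 35836614, "Exon 12")

    def test_bundled_fixture_matches_printed_text(self, printed_alignment_text):
        assert load_probe_alignments() == parse_probe_alignments(printed_alignment_text)

    def test_malformed_line_error_names_the_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_probe_alignments(["P1 aligned to chr1:10-20 (Exon 1)", "garbage"])

    def test_empty_input_gives_empty_list(self):
        assert parse_probe_alignments("") == []

    def test_bed_export_is_zero_based_half_open(self):
        rec = ProbeAlignmentRecord("p", "chr19", 35836590, 35836614, "Exon 12")
        assert rec.to_bed6().split("\t")[1:3] == ["35836589", "35836614"]


class TestExonMap:
    def test_printed_list_gives_3_target_7_flanking(self):
        em = build_exon_map(load_probe_alignments(), "Exon 12")
        assert len(em.target_probes) == 3
        assert len(em.flanking_probes) == 7

    def test_single_exon_probeset_rejected(self):
        recs = [ProbeAlignmentRecord(f"p{i}", "chr1", i * 10, i * 10 + 5, "Exon 2") for i in range(4)]
        with pytest.raises(ValueError):
            build_exon_map(recs, "Exon 2")
        with pytest.raises(ValueError):
            build_exon_map(recs, "Exon 7")

    def test_unlisted_probe_is_unassigned(self):
        em = build_exon_map(load_probe_alignments(), "Exon 12")
        assert em.group_of("SOME_OTHER_PROBE") == "unassigned"


class TestMedianCentering:
    def test_hand_computed_even_count_median(self):
        v = [4, 4, 4, 5, 5, 5, 5, 5, 5, 5]
        out = median_center_sample(v)
        np.testing.assert_allclose(out, [-1, -1, -1, 0, 0, 0, 0, 0, 0, 0])

    def test_constant_vector_centers_to_zero(self):
        np.testing.assert_allclose(median_center_sample([3.0] * 5), 0.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        st.floats(-100, 100),
    )
    def test_shift_invariance(self, values, shift):
        base = median_center_sample(values)
        shifted = median_center_sample(np.asarray(values) + shift)
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_too_few_finite_values_rejected(self):
        with pytest.raises(ValueError):
            median_center_sample([np.nan, 1.0])


def _probeset_matrix(values_by_probe):
    return pd.DataFrame(values_by_probe).T  # dict probe -> per-sample values


class TestDeltaIndex:
    @pytest.fixture
    def exon_map(self):
        return build_exon_map(load_probe_alignments(), "Exon 12")

    def test_hand_computed_index(self, exon_map):
        # targets one unit below the flank: centered targets -1, flank 0 -> index -1
        em = exon_map
        data = {p: [4.0] for p in em.target_probes}
        data.update({p: [5.0] for p in em.flanking_probes})
        idx = compute_delta_index(_probeset_matrix(data), em)
        assert idx.iloc[0] == pytest.approx(-1.0)

    def test_all_probes_equal_gives_zero(self, exon_map):
        em = exon_map
        data = {p: [7.0, 3.0] for p in list(em.target_probes) + list(em.flanking_probes)}
        idx = compute_delta_index(_probeset_matrix(data), em)
        np.testing.assert_allclose(idx, 0.0)

    def test_swap_of_roles_negates_index(self, exon_map):
        rng = np.random.default_rng(5)
        em = exon_map
        probes = list(em.target_probes) + list(em.flanking_probes)
        mat = _probeset_matrix({p: rng.normal(size=3) for p in probes})
        swapped = dataclasses.replace(
            em, target_probes=em.flanking_probes, flanking_probes=em.target_probes
        )
        np.testing.assert_allclose(
            compute_delta_index(mat, em), -compute_delta_index(mat, swapped), atol=1e-12
        )

    def test_per_sample_shift_leaves_index_unchanged(self, exon_map):
        rng = np.random.default_rng(6)
        em = exon_map
        probes = list(em.target_probes) + list(em.flanking_probes)
        mat = _probeset_matrix({p: rng.normal(size=4) for p in probes})
        shifted = mat + np.array([10.0, -3.0, 0.5, 100.0])[None, :]
        np.testing.assert_allclose(
            compute_delta_index(mat, em), compute_delta_index(shifted, em), atol=1e-9
        )

    def test_linear_response_to_target_depletion(self, exon_map):
        """Dropping every target probe by delta lowers the index by exactly delta
        while the median stays inside the flanking group."""
        em = exon_map
        delta = 0.8
        data = {p: [5.0] for p in em.flanking_probes}
        data.update({p: [5.3] for p in em.target_probes})
        base = compute_delta_index(_probeset_matrix(data), em)
        data_low = dict(data)
        for p in em.target_probes:
            data_low[p] = [5.3 - delta]
        low = compute_delta_index(_probeset_matrix(data_low), em)
        assert (base.iloc[0] - low.iloc[0]) == pytest.approx(delta, abs=1e-12)

    def test_unassigned_probe_affects_centering_only(self, exon_map):
        em = exon_map
        data = {p: [5.0] for p in em.flanking_probes}
        data.update({p: [4.0] for p in em.target_probes})
        base = compute_delta_index(_probeset_matrix(data), em).iloc[0]
        # add an extreme unassigned probe: median over 11 probes is still 5
        data_extra = dict(data, EXTRA_PROBE=[50.0])
        extra = compute_delta_index(_probeset_matrix(data_extra), em).iloc[0]
        assert extra == pytest.approx(base)

    def test_missing_group_flags_sample(self, exon_map):
        em = exon_map
        data = {p: [5.0] for p in em.flanking_probes}
        data.update({p: [np.nan] for p in em.target_probes})
        idx = compute_delta_index(_probeset_matrix(data), em)
        assert np.isnan(idx.iloc[0])


class TestReferenceInterval:
    def test_hand_computed_t_interval(self):
        lo, hi = reference_interval([1.0, 2.0, 3.0, 4.0])
        assert lo == pytest.approx(0.446, abs=1e-3)
        assert hi == pytest.approx(4.554, abs=1e-3)

    def test_constant_reference_degenerates_with_warning(self):
        with pytest.warns(RuntimeWarning):
            lo, hi = reference_interval([2.0, 2.0, 2.0])
        assert lo == hi == 2.0

    def test_published_cohort_summary_brackets_printed_interval(self):
        """n=74, mean 0.52, SE 0.07 reproduces the printed (0.394, 0.655) to rounding."""
        rng = np.random.default_rng(0)
        # build a sample with exactly the target mean and SE
        v = rng.normal(size=74)
        v = (v - v.mean()) / (v.std(ddof=1) / np.sqrt(74)) * 0.07
        v = v + 0.52
        lo, hi = reference_interval(v)
        assert lo == pytest.approx(0.52 - stats.t.ppf(0.975, 73) * 0.07, abs=1e-9)
        assert 0.37 < lo < 0.40
        assert 0.64 < hi < 0.67

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            reference_interval([1.0])


class TestIncidence:
    def test_direct_count(self):
        res = call_incidence([-1.0, 0.5, 2.0], (0.446, 4.554))
        assert res.n_below == 1 and res.n_cases == 3
        assert res.incidence == pytest.approx(1 / 3)
        assert res.incidence_ci[0] < res.incidence < res.incidence_ci[1]

    def test_all_above_upper_gives_zero(self):
        res = call_incidence([10.0, 12.0], (0.0, 1.0))
        assert res.incidence == 0.0

    def test_boundary_is_strict(self):
        res = call_incidence([0.446, 0.4459], (0.446, 1.0))
        assert res.n_below == 1

    def test_nan_cases_excluded_and_counted(self):
        res = call_incidence([np.nan, -1.0], (0.0, 1.0))
        assert res.n_cases == 1 and res.n_excluded == 1

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            call_incidence([np.nan], (0.0, 1.0))

    def test_incidence_monotone_in_case_mean(self):
        """Lowering the case mean never decreases incidence (same spread, same seed)."""
        incidences = []
        for mean_case in (0.3, 0.0, -0.3, -0.6):
            ref, case = simulate_index_cohort(74, 0.52, 0.07, 200, mean_case, 0.03, seed=99)
            interval = reference_interval(ref)
            incidences.append(call_incidence(case, interval).incidence)
        assert all(a <= b for a, b in zip(incidences, incidences[1:]))


class TestOneWayAnova:
    def test_hand_computed_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.f_statistic == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_equal_means_give_small_f(self, rng):
        g = [rng.normal(0, 1, 50), rng.normal(0, 1, 50)]
        g[1] = g[1] - g[1].mean() + g[0].mean()
        res = one_way_anova(g)
        assert res.f_statistic < 1e-20

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_degenerate_flagged(self):
        res = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert not res.defined


class TestDunnett:
    def test_two_groups_reduce_to_two_sample_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 10)
        res = dunnett_posthoc([a, b], control_index=0, n_mc=100_000, seed=11)
        t_p = stats.ttest_ind(b, a, equal_var=True).pvalue
        assert abs(res["p_adjusted"].iloc[0] - t_p) <= 3 * max(res["mc_se"].iloc[0], 1e-4)

    def test_agrees_with_multivariate_t_implementation(self, rng):
        ctl = rng.normal(0, 1, 15)
        g1 = rng.normal(0.2, 1, 15)
        g2 = rng.normal(0.9, 1, 15)
        mine = dunnett_posthoc([ctl, g1, g2], 0, n_mc=200_000, seed=13)
        ref = stats.dunnett(g1, g2, control=ctl)
        for p_mine, p_ref, se in zip(mine["p_adjusted"], ref.pvalue, mine["mc_se"]):
            assert abs(p_mine - p_ref) <= 4 * max(se, 1e-3)

    def test_identical_constant_groups_give_p_one(self):
        res = dunnett_posthoc([[2.0, 2.0, 2.0], [2.0, 2.0], [2.0, 2.0]], 0, n_mc=2000, seed=0)
        assert (res["p_adjusted"] == 1.0).all()

    def test_low_precision_request_refused(self):
        with pytest.raises(ValueError, match="n_mc"):
            dunnett_posthoc([[1.0, 2.0], [3.0, 4.0]], 0, n_mc=500, seed=0)

    def test_familywise_error_calibrated_at_5_percent(self):
        """All-null k=3 simulation: rejections at the MC critical value ~ 5%."""
        k, n = 3, 10
        rng = np.random.default_rng(7)
        # 5% critical value of max |t| from one large MC draw of the null
        n_mc = 200_000
        z = rng.standard_normal((n_mc, k)) / np.sqrt(n)
        s2 = rng.chisquare(k * (n - 1), n_mc) / (k * (n - 1))
        t_null = (z[:, 1:] - z[:, [0]]) / np.sqrt(s2[:, None] * (2 / n))
        crit = np.quantile(np.max(np.abs(t_null), axis=1), 0.95)
        # simulate 2000 independent null experiments
        reps = 2000
        x = rng.normal(size=(reps, k, n))
        means = x.mean(axis=2)
        ss = ((x - means[:, :, None]) ** 2).sum(axis=(1, 2))
        s2_rep = ss / (k * (n - 1))
        t_obs = (means[:, 1:] - means[:, [0]]) / np.sqrt(s2_rep[:, None] * (2 / n))
        fwe = float(np.mean(np.max(np.abs(t_obs), axis=1) >= crit))
        assert fwe == pytest.approx(0.05, abs=0.02)


class TestPipelineSeparation:
    def test_index_separates_deep_skipping_cases(self):
        """psi_case = 0.7 vs 0: cases sit clearly lower; AUC reflects the
        probe-level exponential noise floor (~0.84 with 3 target probes)."""
        spec = dataclasses.replace(
            default_cohort_spec(seed=5, n_reference=120, n_case=120),
            skip_fraction_case=SkipFractionModel("fixed", 0.7),
        )
        ds = simulate_probe_intensities(spec)
        norm = rma_preprocess(ds.intensities)["probe_level"]
        em = build_exon_map(load_probe_alignments(), "Exon 12")
        probes = ds.probeset_ids[ds.probeset_ids == "217422_s_at"].index
        idx = compute_delta_index(norm.loc[probes], em)
        ref = idx[ds.group_labels == REFERENCE_GROUP]
        case = idx[ds.group_labels == CASE_GROUP]
        u = stats.mannwhitneyu(ref, case, alternative="greater").statistic
        auc = u / (len(ref) * len(case))
        assert case.mean() < ref.mean()  # sign convention: skipping lowers the index
        assert auc > 0.78
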