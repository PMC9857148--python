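"""Interval validation, rasterization and the four agreement metrics."""

import numpy as np
import pytest

from gmaes import (
    AES,
    ArtifactInterval,
    GMInterval,
    HRSeries,
    evaluate_concordance,
    pool_reports,
    rasterize,
    validate_gm_intervals,
)
from gmaes.concordance import ConcordanceReport

from _brute import brute_concordance, brute_rasterize_1s


@pytest.fixture
def grid12():
    return HRSeries(np.full(12, 150.0))  # 120 s, sections [0,10) .. [110,120)


class TestValidate:
    def test_accept_reject_by_duration(self):
        accepted, rejected = validate_gm_intervals([(65, 95), (100, 115)])
        assert accepted == [GMInterval(65, 95)]
        assert len(rejected) == 1 and "15" in rejected[0][1]

    def test_exactly_20s_is_a_gm(self):
        accepted, rejected = validate_gm_intervals([(0, 20)])
        assert accepted and not rejected

    def test_overlap_is_an_annotation_defect(self):
        with pytest.raises(ValueError, match="overlap"):
            validate_gm_intervals([(0, 30), (25, 60)])

    def test_inverted_interval_rejected_outright(self):
        with pytest.raises(ValueError):
            validate_gm_intervals([(30, 10)])

    def test_unsorted_input_is_sorted(self):
        accepted, _ = validate_gm_intervals([(200, 230), (0, 40)])
        assert accepted == [GMInterval(0, 40), GMInterval(200, 230)]


class TestRasterize:
    def test_partial_overlap_flags_edge_sections(self, grid12):
        mask = rasterize([GMInterval(65, 95)], grid12)
        assert list(np.flatnonzero(mask)) == [6, 7, 8, 9]

    def test_boundary_aligned_interval_respects_half_open_sections(self, grid12):
        mask = rasterize([GMInterval(60, 90)], grid12)
        assert list(np.flatnonzero(mask)) == [6, 7, 8]

    def test_empty_interval_list(self, grid12):
        assert not rasterize([], grid12).any()

    def test_interval_outside_span_rejected(self, grid12):
        with pytest.raises(ValueError, match="outside"):
            rasterize([GMInterval(100, 130)], grid12)

    def test_matches_per_second_membership_oracle(self):
        rng = np.random.default_rng(5)
        series = HRSeries(np.full(60, 150.0))  # 600 s
        for _ in range(40):
            n_iv = int(rng.integers(0, 6))
            ivs = []
            for _ in range(n_iv):
                a = int(rng.integers(0, 590))
                b = int(rng.integers(a + 1, 601))
                ivs.append(ArtifactInterval(a, b))
            got = rasterize(ivs, series)
            want = brute_rasterize_1s(
                [(iv.start_time, iv.end_time) for iv in ivs], 60
            )
            assert list(got) == want


class TestEvaluate:
    def test_perfect_agreement_toy(self, grid12):
        rep = evaluate_concordance([AES(6, 9)], [GMInterval(65, 95)], [], grid12)
        assert rep.pct_aes_with_gm == 100.0
        assert rep.pct_gm_with_aes == 100.0
        assert rep.pct_full_course_among_gm_with_aes == 100.0
        assert rep.total_aes_seconds == 40.0
        assert rep.evaluable_recording_seconds == 120.0
        assert rep.pct_aes_of_recording == pytest.approx(100 * 40 / 120)

    def test_accompanied_but_not_full_course(self):
        grid = HRSeries(np.full(14, 150.0))
        rep = evaluate_concordance([AES(6, 9)], [GMInterval(95, 130)], [], grid)
        # GM sections {9,...,12}; only section 9 lies in the AES
        assert rep.n_gm_with_aes == 1
        assert rep.n_full_course_gm_in_aes == 0
        assert rep.pct_full_course_among_gm_with_aes == 0.0

    def test_degenerate_denominators_are_none(self, grid12):
        rep = evaluate_concordance([], [GMInterval(65, 95)], [], grid12)
        assert rep.pct_aes_with_gm is None  # no AES at all
        assert rep.pct_gm_with_aes == 0.0  # GMs exist, none covered
        assert rep.pct_full_course_among_gm_with_aes is None
        rep2 = evaluate_concordance([], [], [], grid12)
        assert rep2.pct_gm_with_aes is None

    def test_gm_straddling_two_aes_is_not_full_course(self):
        grid = HRSeries(np.full(20, 150.0))
        # GM sections 5..10; AES [4,6] and [8,11] both overlap it but
        # neither contains it entirely
        rep = evaluate_concordance(
            [AES(4, 6), AES(8, 11)], [GMInterval(50, 110)], [], grid
        )
        assert rep.n_gm_with_aes == 1
        assert rep.n_full_course_gm_in_aes == 0

    def test_untouched_artifact_changes_nothing(self, grid12):
        base = evaluate_concordance([AES(6, 9)], [GMInterval(65, 95)], [], grid12)
        with_art = evaluate_concordance(
            [AES(6, 9)], [GMInterval(65, 95)], [ArtifactInterval(0, 30)], grid12
        )
        assert with_art.n_aes == base.n_aes
        assert with_art.n_gm_with_aes == base.n_gm_with_aes
        assert with_art.total_aes_seconds == base.total_aes_seconds
        # denominator shrinks by the 3 artifact sections
        assert with_art.evaluable_recording_seconds == 90.0

    def test_drop_events_policy_excludes_touching_events(self, grid12):
        rep = evaluate_concordance(
            [AES(6, 9)],
            [GMInterval(65, 95)],
            [ArtifactInterval(88, 92)],  # touches sections 8,9: AES and GM
            grid12,
            artifact_policy="drop-events",
        )
        assert rep.n_aes == 0 and rep.n_gm == 0
        assert rep.pct_aes_with_gm is None

    def test_mask_sections_policy_keeps_events(self, grid12):
        rep = evaluate_concordance(
            [AES(6, 9)],
            [GMInterval(65, 95)],
            [ArtifactInterval(88, 92)],
            grid12,
            artifact_policy="mask-sections",
        )
        assert rep.n_aes == 1 and rep.n_gm == 1
        assert rep.n_gm_with_aes == 1
        assert rep.n_full_course_gm_in_aes == 1  # clean GM sections {6,7} in AES

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(17)
        n_sections = 90  # 900 s
        series = HRSeries(np.full(n_sections, 150.0))
        for _ in range(40):
            # random disjoint AES ranges
            aes, pos = [], 0
            while pos < n_sections - 4 and len(aes) < 6:
                first = pos + int(rng.integers(0, 8))
                last = first + int(rng.integers(0, 6))
                if last >= n_sections:
                    break
                aes.append(AES(first, last))
                pos = last + 2
            # random disjoint GM intervals (integer seconds, >= 20 s)
            gms, t = [], 0
            while t < 850 and len(gms) < 5:
                a = t + int(rng.integers(0, 120))
                b = a + int(rng.integers(20, 90))
                if b > 900:
                    break
                gms.append(GMInterval(a, b))
                t = b + 1
            arts = []
            if rng.random() < 0.6:
                a = int(rng.integers(0, 800))
                arts.append(ArtifactInterval(a, a + int(rng.integers(10, 80))))
            rep = evaluate_concordance(aes, gms, arts, series)
            want = brute_concordance(
                [(x.first_section, x.last_section) for x in aes],
                [(g.start_time, g.end_time) for g in gms],
                [(ar.start_time, ar.end_time) for ar in arts],
                n_sections,
            )
            got = rep.to_dict()
            for key, val in want.items():
                assert got[key] == val, key

    def test_full_course_implies_accompanied_and_monotone_enlargement(self):
        rng = np.random.default_rng(23)
        series = HRSeries(np.full(60, 150.0))
        for _ in range(20):
            a = int(rng.integers(0, 40))
            b = a + int(rng.integers(2, 8))
            g0 = int(rng.integers(0, 500))
            gms = [GMInterval(g0, g0 + 60)]
            small = evaluate_concordance([AES(a, b)], gms, [], series)
            assert small.n_full_course_gm_in_aes <= small.n_gm_with_aes
            big = evaluate_concordance(
                [AES(max(0, a - 2), min(59, b + 2))], gms, [], series
            )
            assert big.n_gm_with_aes >= small.n_gm_with_aes
            assert big.n_full_course_gm_in_aes >= small.n_full_course_gm_in_aes
            assert big.pct_aes_of_recording >= small.pct_aes_of_recording


class TestPooling:
    def mk(self, **kw):
        base = dict(
            n_aes=2, n_aes_with_gm=1, n_gm=3, n_gm_with_aes=2,
            n_full_course_gm_in_aes=1, total_aes_seconds=100.0,
            evaluable_recording_seconds=1000.0,
        )
        base.update(kw)
        return ConcordanceReport(**base)

    def test_single_report_identity(self):
        r = self.mk()
        pooled = pool_reports([r])
        assert pooled.pct_aes_with_gm == r.pct_aes_with_gm
        assert pooled.pct_gm_with_aes == r.pct_gm_with_aes
        assert pooled.n_recordings == 1

    def test_pooled_counts_not_mean_of_percentages(self):
        r1 = self.mk(n_aes=2, n_aes_with_gm=1)   # 50%
        r2 = self.mk(n_aes=3, n_aes_with_gm=3)   # 100%
        pooled = pool_reports([r1, r2])
        assert pooled.pct_aes_with_gm == pytest.approx(80.0)  # 4/5, not 75

    def test_mean_full_course_per_recording(self):
        r1 = self.mk(n_gm=20, n_gm_with_aes=12, n_full_course_gm_in_aes=10)
        r2 = self.mk(n_gm=20, n_gm_with_aes=15, n_full_course_gm_in_aes=14)
        pooled = pool_reports([r1, r2])
        assert pooled.mean_full_course_per_recording == pytest.approx(12.0)

    def test_undefined_percentages_do_not_poison_pool(self):
        r1 = self.mk(n_aes=0, n_aes_with_gm=0)  # undefined pct_aes_with_gm
        r2 = self.mk(n_aes=4, n_aes_with_gm=3)
        pooled = pool_reports([r1, r2])
        assert pooled.pct_aes_with_gm == pytest.approx(75.0)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            pool_reports([])
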