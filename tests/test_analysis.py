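"""BIS scoring and nonparametric statistics against independent oracles."""

import dataclasses
import itertools
import math

import numpy as np
import pytest

from fatiguebattery.analysis import (
    DegenerateInputError,
    DegenerateTestError,
    PerformanceCell,
    UndefinedCorrelationError,
    UndefinedRTError,
    analysis_report,
    compute_bis,
    effect_size_r,
    performance_cells,
    spearman_corr,
    wilcoxon_signed_rank,
)
from fatiguebattery.brums import DEFAULT_ITEM_MAP, BrumsForm
from fatiguebattery.simulate import SessionData, TrialRecord

LABELS = tuple(DEFAULT_ITEM_MAP)


def form(ratings, completion=120.0):
    return BrumsForm(item_order=LABELS, item_ratings=tuple(ratings), completion_time_s=completion)


def axcpt_trial(block, i, correct, rt):
    return TrialRecord(
        block_index=block,
        task="AXCPT",
        trial_index=i,
        stimulus="AQFX",
        trial_type="AX",
        correct_key="k",
        response=None if rt is None else ("k" if correct else "d"),
        correct=correct,
        rt_ms=rt,
        onset_ms=i * 7000,
    )


def session_from_blocks(pid, block1, block12, pre=None, post=None):
    trials = [axcpt_trial(1, i, c, rt) for i, (c, rt) in enumerate(block1)]
    trials += [axcpt_trial(12, i, c, rt) for i, (c, rt) in enumerate(block12)]
    return SessionData(
        participant_id=pid,
        pre_brums=pre or form([1, 2] * 12),
        post_brums=post or form([2, 1] * 12),
        trials=trials,
    )


class TestPerformanceCells:
    def test_hand_computed_fixture(self):
        block1 = [(True, rt) for rt in (400, 500, 600, 700, 800, 450, 550, 650)]
        block1 += [(False, 900), (False, None)]  # one error, one omission
        block12 = [(True, 500)] * 10
        s = session_from_blocks("P01", block1, block12)
        cells = performance_cells([s])
        pre, post = cells
        assert pre.timepoint == "pre" and post.timepoint == "post"
        assert pre.proportion_correct == pytest.approx(0.8)
        assert pre.mean_rt == pytest.approx(np.mean([400, 500, 600, 700, 800, 450, 550, 650]))
        assert post.proportion_correct == 1.0
        assert post.mean_rt == 500.0

    def test_omissions_and_errors_never_enter_mean_rt(self):
        block = [(True, 1000), (False, 100), (False, None)]
        s = session_from_blocks("P01", block, [(True, 1000)])
        pre = performance_cells([s])[0]
        assert pre.mean_rt == 1000.0
        assert pre.proportion_correct == pytest.approx(1 / 3)

    def test_no_correct_trial_raises_named_error(self):
        s = session_from_blocks("P99", [(False, 500)], [(True, 500)])
        with pytest.raises(UndefinedRTError, match="P99"):
            performance_cells([s])


class TestBis:
    def test_two_point_symmetry(self):
        cells = [
            PerformanceCell("P1", "pre", 0.9, 500.0),
            PerformanceCell("P1", "post", 0.7, 700.0),
        ]
        bis = compute_bis(cells)["bis"].to_numpy()
        assert bis[0] == pytest.approx(-bis[1])
        assert bis.sum() == pytest.approx(0.0)

    def test_four_cell_fixture_matches_hand_computation(self):
        # pc = (.9,.8,.7,.6): mean .75, sd .129099; rt = (500,600,650,800):
        # mean 637.5, sd 125 -> z(pc) - z(rt) computed by hand
        cells = [
            PerformanceCell("P1", "pre", 0.9, 500.0),
            PerformanceCell("P1", "post", 0.8, 600.0),
            PerformanceCell("P2", "pre", 0.7, 650.0),
            PerformanceCell("P2", "post", 0.6, 800.0),
        ]
        bis = compute_bis(cells)["bis"].to_numpy()
        expected = np.array(
            [
                0.15 / 0.12909944 + 1.1,
                0.05 / 0.12909944 + 0.3,
                -0.05 / 0.12909944 - 0.1,
                -0.15 / 0.12909944 - 1.3,
            ]
        )
        np.testing.assert_allclose(bis, expected, rtol=1e-6)
        assert bis.mean() == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_ms_to_seconds(self):
        cells = [
            PerformanceCell("P1", "pre", 0.9, 500.0),
            PerformanceCell("P1", "post", 0.8, 600.0),
            PerformanceCell("P2", "pre", 0.7, 650.0),
            PerformanceCell("P2", "post", 0.6, 800.0),
        ]
        rescaled = [
            dataclasses.replace(c, mean_rt=c.mean_rt / 1000.0) for c in cells
        ]
        np.testing.assert_allclose(
            compute_bis(cells)["bis"], compute_bis(rescaled)["bis"]
        )

    def test_component_standardization_invariant(self):
        rng = np.random.default_rng(0)
        cells = [
            PerformanceCell(f"P{i}", tp, pc, rt)
            for i, (tp, pc, rt) in enumerate(
                zip(
                    itertools.cycle(["pre", "post"]),
                    rng.uniform(0.5, 1.0, 40),
                    rng.uniform(300, 900, 40),
                )
            )
        ]
        pc = np.array([c.proportion_correct for c in cells])
        rt = np.array([c.mean_rt for c in cells])
        zpc = (pc - pc.mean()) / pc.std(ddof=1)
        zrt = (rt - rt.mean()) / rt.std(ddof=1)
        for comp in (zpc, zrt):
            assert comp.mean() == pytest.approx(0.0, abs=1e-12)
            assert comp.std(ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(compute_bis(cells)["bis"], zpc - zrt)

    def test_degenerate_variance_rejected(self):
        flat = [
            PerformanceCell("P1", "pre", 0.8, 500.0),
            PerformanceCell("P1", "post", 0.8, 600.0),
        ]
        with pytest.raises(DegenerateInputError):
            compute_bis(flat)
        with pytest.raises(DegenerateInputError):
            compute_bis(flat[:1])


def brute_force_signed_rank_p(d):
    """Independent oracle: enumerate all 2^k sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    k = len(d)
    absd = np.abs(d)
    # average ranks computed from scratch
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(k)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < k:
        j = i
        while j + 1 < k and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=k):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_exact_p_matches_enumeration_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            n = int(rng.integers(5, 11))
            pre = rng.normal(10, 3, n).round(1)
            post = pre + rng.normal(1, 2, n).round(1)
            res = wilcoxon_signed_rank(pre, post)
            assert res.p == pytest.approx(brute_force_signed_rank_p(post - pre), abs=1e-3)

    def test_matches_r_reference_exact_case(self):
        # frozen from R: wilcox.test(post, pre, paired=TRUE, conf.int=TRUE)
        d = np.array([3, -1, 6, 0.5, 4, -1.5, 2, 2.5, 3.5, 5])
        pre = np.full(10, 10.0)
        res = wilcoxon_signed_rank(pre, pre + d)
        assert res.p == pytest.approx(0.01953125, abs=1e-9)
        assert res.estimate == pytest.approx(2.5)
        assert res.ci_low == pytest.approx(0.5)
        assert res.ci_high == pytest.approx(4.25)

    def test_z_matches_scipy_normal_approximation(self):
        from scipy import stats as st

        rng = np.random.default_rng(3)
        pre = rng.integers(0, 17, 40).astype(float)
        post = np.minimum(16, pre + rng.integers(-2, 7, 40)).astype(float)
        d = post - pre
        res = wilcoxon_signed_rank(pre, post)
        ref = st.wilcoxon(d[d != 0], correction=False, method="approx")
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic))
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_differences_dropped_but_n_retained(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        post = np.array([1.0, 2.0, 4.5, 5.5, 6.5, 7.5, 8.5])  # two zeros
        res = wilcoxon_signed_rank(pre, post)
        assert res.n == 7 and res.n_nonzero == 5
        assert res.r == pytest.approx(abs(res.z) / math.sqrt(7))

    def test_all_zero_differences_is_no_test(self):
        x = np.arange(8, dtype=float)
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(x, x)

    def test_sign_convention_worsening_cohort(self):
        rng = np.random.default_rng(11)
        cells = []
        for i in range(12):
            pc = rng.uniform(0.8, 0.95)
            rt = rng.uniform(400, 600)
            cells.append(PerformanceCell(f"P{i:02d}", "pre", pc, rt))
            cells.append(PerformanceCell(f"P{i:02d}", "post", pc - 0.1, rt + 150))
        bis = compute_bis(cells)
        wide = bis.pivot(index="participant_id", columns="timepoint", values="bis")
        res = wilcoxon_signed_rank(wide["pre"], wide["post"])
        assert (wide["post"] - wide["pre"]).mean() < 0
        assert res.z < 0
        assert res.p < 0.05

    def test_continuity_correction_shrinks_z(self):
        pre = np.arange(10, dtype=float)
        post = pre + np.array([3, -1, 6, 0.5, 4, -1.5, 2, 2.5, 3.5, 5])
        plain = wilcoxon_signed_rank(pre, post)
        corrected = wilcoxon_signed_rank(pre, post, continuity=True)
        assert abs(corrected.z) < abs(plain.z)


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,n,expected",
        [(5.72, 45, 0.85), (2.64, 45, 0.39), (5.39, 45, 0.80), (3.15, 45, 0.47),
         (2.16, 45, 0.32), (1.73, 45, 0.26), (0.19, 45, 0.03), (0.0, 45, 0.0)],
    )
    def test_r_from_z(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman_corr(x, x)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_seven_point_fixture_matches_manual_ranks(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0])
        # manual average ranks
        rx = np.array([4.0, 1.5, 5.0, 1.5, 6.0, 7.0, 3.0])
        ry = np.array([3.5, 5.0, 1.5, 6.5, 3.5, 6.5, 1.5])
        manual_rho = np.corrcoef(rx, ry)[0, 1]
        rho, p = spearman_corr(x, y)
        assert rho == pytest.approx(manual_rho)
        assert 0 <= p <= 1

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_corr(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            spearman_corr(np.ones(2), np.ones(2))


class TestAnalysisReport:
    def test_degenerate_cohort_reports_no_tests_without_crashing(self):
        same = form([1, 2] * 12)
        block = [(True, 500)] * 5
        sessions = [
            SessionData(
                participant_id=f"P{i}",
                pre_brums=same,
                post_brums=same,
                trials=[axcpt_trial(1, j, True, 500) for j in range(5)]
                + [axcpt_trial(12, j, True, 500) for j in range(5)],
            )
            for i in range(5)
        ]
        report = analysis_report(sessions)
        assert all(v is None for v in report.brums_tests.values())
        assert report.bis_test is None and report.bis_note
        assert report.spearman_fatigue_vigor is None
        assert "no test" in report.to_dict()["bis"].get("note", "no test") or report.bis_note
        assert isinstance(report.summary_text(), str)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            analysis_report([])
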