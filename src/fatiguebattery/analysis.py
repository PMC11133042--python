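"""Scoring and statistics for the pre/post fatigue contrast.

Performance on the critical task (AX-CPT, first vs last block) is summarised
per participant and timepoint by proportion correct and mean correct RT,
then combined into the balanced integration score

    BIS = z(PC) - z(RT),

where each component is z-standardized (sample SD) jointly across all
participants and both timepoints, so a BIS of zero is the grand-average
performance level and higher is better.  The BIS resists speed-accuracy
trade-offs because a participant trading accuracy for speed moves both
components together.

Pre/post contrasts use the Wilcoxon signed-rank test.  Zero differences are
dropped (classic signed-rank); z comes from the normal approximation with
tie correction (continuity correction optional); the p-value is exact —
computed from the permutation distribution of the rank sum — whenever 25 or
fewer nonzero pairs remain, and asymptotic otherwise.  The effect size is
r = |z| / sqrt(n) with n the full pre-drop pair count, and the confidence
interval is the Hodges-Lehmann interval on the Walsh averages of the paired
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .brums import SUBSCALES, score_brums, DEFAULT_ITEM_MAP
from .simulate import SessionData
from .tasks import AXCPT

EXACT_MAX_N = 25

PRE = "pre"
POST = "post"


class UndefinedRTError(ValueError):
    """A performance cell has no correct responded trial to average."""


class DegenerateInputError(ValueError):
    """Standardization is undefined (zero variance in a BIS component)."""


class DegenerateTestError(ValueError):
    """The test statistic is undefined (e.g. all paired differences zero)."""


class UndefinedCorrelationError(ValueError):
    """Rank correlation is undefined for a constant input."""


@dataclass(frozen=True, slots=True)
class PerformanceCell:
    participant_id: str
    timepoint: str
    proportion_correct: float
    mean_rt: float


@dataclass(frozen=True, slots=True)
class TestResult:
    """Wilcoxon signed-rank outcome.

    ``n`` is the number of pairs entering the test before zero differences
    are dropped (the basis of ``r``); ``n_nonzero`` the pairs actually
    ranked.
    """

    z: float
    p: float
    ci_low: float
    ci_high: float
    r: float
    n: int
    n_nonzero: int
    estimate: float


def performance_cells(
    sessions: Sequence[SessionData],
    task: str = AXCPT,
    blocks: tuple[int, int] = (1, 12),
) -> list[PerformanceCell]:
    """Per-participant pre/post summaries from the first and last task blocks.

    Omitted trials count as incorrect in proportion correct; mean RT is taken
    over correct responded trials only.
    """
    cells: list[PerformanceCell] = []
    for session in sessions:
        for block_index, timepoint in zip(blocks, (PRE, POST)):
            trials = [
                t
                for t in session.trials
                if t.block_index == block_index and t.task == task
            ]
            if not trials:
                raise UndefinedRTError(
                    f"participant {session.participant_id!r} has no {task} "
                    f"trials in block {block_index}"
                )
            correct_rts = [t.rt_ms for t in trials if t.correct and t.rt_ms is not None]
            if not correct_rts:
                raise UndefinedRTError(
                    f"participant {session.participant_id!r} has no correct "
                    f"responded trial in block {block_index}; mean RT undefined"
                )
            cells.append(
                PerformanceCell(
                    participant_id=session.participant_id,
                    timepoint=timepoint,
                    proportion_correct=sum(t.correct for t in trials) / len(trials),
                    mean_rt=float(np.mean(correct_rts)),
                )
            )
    return cells


def compute_bis(cells: Sequence[PerformanceCell]) -> pd.DataFrame:
    """Balanced integration scores, standardized over all cells jointly.

    Returns a tidy frame (participant_id, timepoint, bis) whose bis column
    has mean zero by construction.
    """
    if len(cells) < 2:
        raise DegenerateInputError("need at least two cells to standardize")
    pc = np.array([c.proportion_correct for c in cells], dtype=float)
    rt = np.array([c.mean_rt for c in cells], dtype=float)
    sd_pc = pc.std(ddof=1)
    sd_rt = rt.std(ddof=1)
    if sd_pc == 0 or sd_rt == 0:
        raise DegenerateInputError(
            "zero variance in proportion correct or mean RT; BIS undefined"
        )
    bis = (pc - pc.mean()) / sd_pc - (rt - rt.mean()) / sd_rt
    return pd.DataFrame(
        {
            "participant_id": [c.participant_id for c in cells],
            "timepoint": [c.timepoint for c in cells],
            "bis": bis,
        }
    )


def _signrank_pmf(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of twice the positive-rank sum over all sign assignments.

    ``ranks`` are midranks (possibly half-integral); doubling makes them
    integers.  Returns (counts indexed by 2*W, number of sign vectors).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in r2:
        dp[r:] = dp[r:] + dp[: total + 1 - r]
    return dp, len(ranks)


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    dp, k = _signrank_pmf(ranks)
    w2 = int(round(2 * w))
    denom = 2.0**k
    cdf = dp[: w2 + 1].sum() / denom
    sf = dp[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _qsignrank(p: float, k: int) -> int:
    """Smallest q with P(W <= q) >= p for the untied signed-rank distribution."""
    dp, _ = _signrank_pmf(np.arange(1, k + 1, dtype=float))
    cdf = np.cumsum(dp[::2]) / 2.0**k  # rank sums are integers: even doubled sums
    return int(np.searchsorted(cdf, p - 1e-12))


def _hodges_lehmann_ci(
    d: np.ndarray, conf_level: float
) -> tuple[float, float, float]:
    """Pseudomedian and CI from the sorted Walsh averages of the differences."""
    k = len(d)
    walsh = np.sort(
        np.concatenate([(d[i] + d[i:]) / 2.0 for i in range(k)])
    )
    m = k * (k + 1) // 2
    estimate = float(np.median(walsh))
    alpha = 1.0 - conf_level
    if k <= EXACT_MAX_N:
        qu = _qsignrank(alpha / 2.0, k)
    else:
        sigma = math.sqrt(k * (k + 1) * (2 * k + 1) / 24.0)
        qu = int(round(m / 2.0 + stats.norm.ppf(alpha / 2.0) * sigma))
    qu = max(qu, 1)
    ql = m - qu
    return estimate, float(walsh[qu - 1]), float(walsh[ql])


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    continuity: bool = False,
    conf_level: float = 0.95,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    See the module docstring for the conventions (zero-drop, tie-corrected
    normal z, exact p for <=25 nonzero pairs, Hodges-Lehmann CI, r based on
    the pre-drop n).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d samples")
    n_total = len(pre)
    d = post - pre
    nz = d[d != 0]
    k = len(nz)
    if k == 0:
        raise DegenerateTestError("all paired differences are zero; no test")

    ranks = stats.rankdata(np.abs(nz))
    w = float(ranks[nz > 0].sum())
    mu = k * (k + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = k * (k + 1) * (2 * k + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if sigma2 <= 0:
        raise DegenerateTestError("variance of the rank sum is zero; no test")
    corr = 0.5 * math.copysign(1.0, w - mu) if (continuity and w != mu) else 0.0
    z = (w - mu - corr) / math.sqrt(sigma2)

    if k <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))

    estimate, ci_low, ci_high = _hodges_lehmann_ci(nz, conf_level)
    r = abs(z) / math.sqrt(n_total)
    return TestResult(
        z=float(z),
        p=p,
        ci_low=ci_low,
        ci_high=ci_high,
        r=float(r),
        n=n_total,
        n_nonzero=k,
        estimate=estimate,
    )


def effect_size_r(z: float, n: int) -> float:
    """Matched-pairs rank-biserial-style effect size r = |z| / sqrt(n)."""
    if n <= 0:
        raise ValueError("n must be a positive number of pairs")
    return abs(z) / math.sqrt(n)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length samples of at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant sample")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class AnalysisReport:
    """Full pipeline output: one test per BRUMS subscale, the BIS contrast,
    the fatigue-vigor change correlation, and responder counts."""

    n_participants: int
    brums_tests: dict[str, Optional[TestResult]]
    brums_notes: dict[str, str] = field(default_factory=dict)
    bis_test: Optional[TestResult] = None
    bis_note: str = ""
    spearman_fatigue_vigor: Optional[tuple[float, float]] = None
    spearman_note: str = ""
    n_fatigue_increased: int = 0
    n_bis_improved: int = 0
    bis_table: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        order = ["fatigue", "bis", "vigor", "anger", "confusion", "depression", "tension"]
        for name in order:
            res = self.bis_test if name == "bis" else self.brums_tests.get(name)
            note = self.bis_note if name == "bis" else self.brums_notes.get(name, "")
            if res is None:
                rows.append({"measure": name, "note": note or "no test"})
            else:
                rows.append(
                    {
                        "measure": name,
                        "z": res.z,
                        "p": res.p,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "r": res.r,
                        "n": res.n,
                        "note": note,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def pack(res: Optional[TestResult], note: str) -> dict:
            if res is None:
                return {"note": note or "no test"}
            return {
                "z": res.z,
                "p": res.p,
                "ci": [res.ci_low, res.ci_high],
                "r": res.r,
                "n": res.n,
                "n_nonzero": res.n_nonzero,
                "estimate": res.estimate,
            }

        sp = self.spearman_fatigue_vigor
        return {
            "n_participants": self.n_participants,
            "brums": {
                s: pack(self.brums_tests.get(s), self.brums_notes.get(s, ""))
                for s in SUBSCALES
            },
            "bis": pack(self.bis_test, self.bis_note),
            "spearman_dfatigue_dvigor": (
                {"rho": sp[0], "p": sp[1]} if sp else {"note": self.spearman_note or "no test"}
            ),
            "counts": {
                "fatigue_increased": self.n_fatigue_increased,
                "bis_improved": self.n_bis_improved,
            },
        }

    def summary_text(self) -> str:
        lines = [f"Participants analysed: {self.n_participants}"]
        for name in ("fatigue", "vigor", "anger", "confusion", "depression", "tension"):
            res = self.brums_tests.get(name)
            if res is None:
                lines.append(f"BRUMS {name}: no test ({self.brums_notes.get(name, '')})")
            else:
                lines.append(
                    f"BRUMS {name}: z = {res.z:.2f}, p = {res.p:.3g}, "
                    f"95% CI [{res.ci_low:.2g}, {res.ci_high:.2g}], r = {res.r:.2f}"
                )
        if self.bis_test is None:
            lines.append(f"AX-CPT BIS: no test ({self.bis_note})")
        else:
            res = self.bis_test
            lines.append(
                f"AX-CPT BIS (post - pre): z = {res.z:.2f}, p = {res.p:.3g}, "
                f"95% CI [{res.ci_low:.2g}, {res.ci_high:.2g}], r = {res.r:.2f}"
            )
        if self.spearman_fatigue_vigor:
            rho, p = self.spearman_fatigue_vigor
            lines.append(f"Spearman dFatigue~dVigor: rho = {rho:.2f}, p = {p:.3g}")
        lines.append(
            f"{self.n_fatigue_increased}/{self.n_participants} participants "
            f"reported increased fatigue; {self.n_bis_improved}/"
            f"{self.n_participants} improved in AX-CPT BIS."
        )
        return "\n".join(lines)


def analysis_report(
    sessions: Sequence[SessionData],
    item_map=DEFAULT_ITEM_MAP,
    task: str = AXCPT,
    blocks: tuple[int, int] = (1, 12),
) -> AnalysisReport:
    """Run the full scoring and statistics pipeline on quality-checked sessions."""
    if len(sessions) < 5:
        raise ValueError("need at least 5 retained participants with pre/post data")
    sessions = sorted(sessions, key=lambda s: s.participant_id)
    n = len(sessions)

    pre_scores = {s: [] for s in SUBSCALES}
    post_scores = {s: [] for s in SUBSCALES}
    for session in sessions:
        pre = score_brums(session.pre_brums, item_map).as_dict()
        post = score_brums(session.post_brums, item_map).as_dict()
        for s in SUBSCALES:
            pre_scores[s].append(pre[s])
            post_scores[s].append(post[s])

    report = AnalysisReport(n_participants=n, brums_tests={})
    for s in SUBSCALES:
        try:
            report.brums_tests[s] = wilcoxon_signed_rank(pre_scores[s], post_scores[s])
        except DegenerateTestError as exc:
            report.brums_tests[s] = None
            report.brums_notes[s] = str(exc)

    try:
        cells = performance_cells(sessions, task=task, blocks=blocks)
        bis = compute_bis(cells)
        wide = bis.pivot(index="participant_id", columns="timepoint", values="bis")
        report.bis_table = bis
        report.bis_test = wilcoxon_signed_rank(wide[PRE].to_numpy(), wide[POST].to_numpy())
        report.n_bis_improved = int((wide[POST] > wide[PRE]).sum())
    except (DegenerateInputError, DegenerateTestError, UndefinedRTError) as exc:
        report.bis_note = str(exc)

    d_fatigue = np.array(post_scores["fatigue"]) - np.array(pre_scores["fatigue"])
    d_vigor = np.array(post_scores["vigor"]) - np.array(pre_scores["vigor"])
    report.n_fatigue_increased = int((d_fatigue > 0).sum())
    try:
        report.spearman_fatigue_vigor = spearman_corr(d_fatigue, d_vigor)
    except UndefinedCorrelationError as exc:
        report.spearman_note = str(exc)

    return report
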