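"""Simulated participants for the fatigue battery.

No generative response model is implied by the protocol itself; the one here
is a deliberately minimal psychometric stand-in that reproduces the
qualitative pre/post structure the analysis pipeline assumes:

* accuracy: Bernoulli with P(correct) = logistic(logit(baseline) -
  accuracy_slope * hours_on_task), so a positive slope is a fatigue-driven
  decline in log-odds correct per hour;
* reaction time: lognormal with location mu + rt_slope * hours_on_task
  (log-ms), truncated to the task's response window and floored at a 150 ms
  physiological minimum;
* omissions: independent per-trial no-response events (never in visual
  search, whose response window is unlimited); omitted trials are incorrect
  and carry no RT;
* mood: post-battery BRUMS item ratings are the pre ratings shifted by a
  per-subscale amount spread evenly over the four items, plus item noise,
  rounded and clipped to 0..4.

Trials are consumed from the battery schedule until the next trial would
overrun the block's 600 s budget, so realized trial counts depend on the
simulated response times exactly as they would for a human participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, NamedTuple, Optional

import numpy as np

from .brums import DEFAULT_ITEM_MAP, SUBSCALES, BrumsForm
from .schedule import BatterySchedule, Block, assemble_battery, trials_for_block
from .tasks import (
    AXCPT,
    MROT,
    NBACK,
    RESPONSE_WINDOW_MS,
    TASK_IDS,
    VSEARCH,
    trial_duration,
)

RT_FLOOR_MS = 150

#: Conservative minimum wall time of one trial (ms), used to size the
#: candidate trial lists a block can possibly consume.
_MIN_TRIAL_MS = {
    AXCPT: 3 * 1500 + RT_FLOOR_MS + 2200,
    NBACK: 4200,
    VSEARCH: RT_FLOOR_MS + 2200,
    MROT: RT_FLOOR_MS + 2200,
}

_OTHER_KEY = {"k": "d", "d": "k"}


class TrialRecord(NamedTuple):
    """One behavioural log row (times in integer ms)."""

    block_index: int
    task: str
    trial_index: int
    stimulus: str
    trial_type: str
    correct_key: str
    response: Optional[str]
    correct: bool
    rt_ms: Optional[int]
    onset_ms: int


@dataclass
class SessionData:
    """One participant's full session: pre/post mood forms plus the trial log."""

    participant_id: str
    pre_brums: BrumsForm
    post_brums: BrumsForm
    trials: list[TrialRecord]


@dataclass(frozen=True)
class ResponderParams:
    """Generative parameters of one simulated participant.

    ``accuracy`` are per-task baseline probabilities correct; ``rt_mu`` /
    ``rt_sigma`` the per-task lognormal location/scale in log-ms.  The two
    fatigue slopes are per-hour drifts (log-odds correct, log-RT).
    ``brums_pre_means`` are subscale means on the 0..16 scale and
    ``brums_shifts`` signed post-minus-pre subscale shifts.
    """

    accuracy: Mapping[str, float]
    rt_mu: Mapping[str, float]
    rt_sigma: Mapping[str, float]
    fatigue_accuracy_slope: float
    fatigue_rt_slope: float
    omission_rate: float
    brums_pre_means: Mapping[str, float]
    brums_shifts: Mapping[str, float]
    brums_item_sd: float
    seed: int

    def __post_init__(self) -> None:
        for task in TASK_IDS:
            p = self.accuracy[task]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy[{task}] must be in [0, 1], got {p}")
            if self.rt_sigma[task] <= 0:
                raise ValueError(f"rt_sigma[{task}] must be positive")
        if not 0.0 <= self.omission_rate <= 1.0:
            raise ValueError("omission_rate must be in [0, 1]")
        if any(v < 0 for v in self.brums_pre_means.values()):
            raise ValueError("brums_pre_means must be non-negative")


def default_params(seed: int = 0) -> ResponderParams:
    """A single plausible participant with moderate fatigue drift.

    Baselines sit in the ranges typical for practiced adult performance on
    these paradigms; mental-rotation RT centres on ~3000 ms, the largest mean
    latency reported for the cube-figure set.  Mood levels start around a
    mild pre-battery state and shift in the directions the protocol induces
    (fatigue up ~5 points, vigor down ~4.5, anger and confusion up slightly,
    depression and tension flat).
    """
    return ResponderParams(
        accuracy={AXCPT: 0.90, NBACK: 0.80, VSEARCH: 0.92, MROT: 0.85},
        rt_mu={
            AXCPT: math.log(450.0),
            NBACK: math.log(700.0),
            VSEARCH: math.log(1400.0),
            MROT: math.log(3000.0),
        },
        rt_sigma={AXCPT: 0.30, NBACK: 0.30, VSEARCH: 0.35, MROT: 0.35},
        fatigue_accuracy_slope=0.25,
        fatigue_rt_slope=0.05,
        omission_rate=0.02,
        brums_pre_means={
            "anger": 1.0,
            "confusion": 1.5,
            "depression": 1.0,
            "fatigue": 4.0,
            "tension": 1.5,
            "vigor": 9.0,
        },
        brums_shifts={
            "anger": 2.5,
            "confusion": 1.0,
            "depression": 0.0,
            "fatigue": 5.0,
            "tension": 0.0,
            "vigor": -4.5,
        },
        brums_item_sd=0.6,
        seed=seed,
    )


def candidate_trials(schedule: BatterySchedule) -> dict[int, list]:
    """Pre-generate, per block, more trials than its time budget can consume."""
    lists: dict[int, list] = {}
    for block in schedule.blocks:
        n = block.duration_s * 1000 // _MIN_TRIAL_MS[block.task_id] + 2
        lists[block.index] = trials_for_block(block, n)
    return lists


#: Latent test-retest correlation of an item between the two administrations.
BRUMS_TEST_RETEST = 0.7


def _simulate_brums_ratings(
    rng: np.random.Generator, params: ResponderParams
) -> tuple[dict[str, int], dict[str, int]]:
    """Draw pre and post item ratings from a latent bivariate-normal item model.

    Each item has a latent value mean + noise at both timepoints with
    test-retest correlation; the post latent value additionally carries a
    quarter of its subscale's shift.  Ratings are the latent values rounded
    and clipped to 0..4.  Because pre and post latents share the same
    marginal distribution, a zero shift leaves the two administrations
    exchangeable (no rounding/clipping artefact masquerading as a mood
    change).
    """
    rho = BRUMS_TEST_RETEST
    mix = math.sqrt(1.0 - rho**2)
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    for label, sub in DEFAULT_ITEM_MAP.items():
        m = params.brums_pre_means[sub] / 4.0
        e1, e2 = rng.standard_normal(2)
        lat_pre = m + params.brums_item_sd * e1
        lat_post = (
            m
            + params.brums_shifts.get(sub, 0.0) / 4.0
            + params.brums_item_sd * (rho * e1 + mix * e2)
        )
        pre[label] = int(np.clip(round(lat_pre), 0, 4))
        post[label] = int(np.clip(round(lat_post), 0, 4))
    return pre, post


def _make_form(
    rng: np.random.Generator, ratings: dict[str, int]
) -> BrumsForm:
    order = list(DEFAULT_ITEM_MAP)
    rng.shuffle(order)
    # 0.1 s resolution: realistic and lossless through CSV round-trips
    completion = round(float(np.clip(rng.normal(80.0, 15.0), 30.0, 600.0)), 1)
    return BrumsForm(
        item_order=tuple(order),
        item_ratings=tuple(ratings[label] for label in order),
        completion_time_s=completion,
    )


def _simulate_block(
    rng: np.random.Generator,
    params: ResponderParams,
    block: Block,
    trials: list,
    t0_ms: int,
) -> tuple[list[TrialRecord], int]:
    """Respond to one block's trials until the time budget would be exceeded."""
    task = block.task_id
    budget_ms = block.duration_s * 1000
    window = RESPONSE_WINDOW_MS[task]
    logit0 = math.log(params.accuracy[task] / (1.0 - params.accuracy[task]))
    mu = params.rt_mu[task]
    sigma = params.rt_sigma[task]
    a_slope = params.fatigue_accuracy_slope
    r_slope = params.fatigue_rt_slope
    o_rate = params.omission_rate if task != VSEARCH else 0.0

    m = len(trials)
    z = rng.standard_normal(m)
    u_corr = rng.random(m)
    u_omit = rng.random(m)

    records: list[TrialRecord] = []
    clock = 0
    exp = math.exp
    for i, trial in enumerate(trials):
        hours = (t0_ms + clock) / 3.6e6
        omitted = u_omit[i] < o_rate
        if omitted:
            rt = None
            correct = False
            response = None
        else:
            p = 1.0 / (1.0 + exp(-(logit0 - a_slope * hours)))
            correct = u_corr[i] < p
            r = exp(mu + r_slope * hours + sigma * z[i])
            if r < RT_FLOOR_MS:
                r = RT_FLOOR_MS
            if window is not None and r > window:
                r = window
            rt = int(round(r))
            response = trial.correct_key if correct else _OTHER_KEY[trial.correct_key]
        duration = trial_duration(task, rt)
        if clock + duration > budget_ms:
            break
        records.append(
            TrialRecord(
                block_index=block.index,
                task=task,
                trial_index=i,
                stimulus=trial.descriptor,
                trial_type=_trial_type(trial),
                correct_key=trial.correct_key,
                response=response,
                correct=bool(correct),
                rt_ms=rt,
                onset_ms=t0_ms + clock,
            )
        )
        clock += duration
    else:  # pragma: no cover - candidate lists are sized to outlast the budget
        raise RuntimeError(f"candidate trial list exhausted in block {block.index}")
    return records, clock


def _trial_type(trial) -> str:
    if hasattr(trial, "trial_type"):
        return trial.trial_type
    if hasattr(trial, "is_target"):
        return "target" if trial.is_target else "nontarget"
    if hasattr(trial, "target_present"):
        return "present" if trial.target_present else "absent"
    return "match" if trial.matching else "mirror"


def simulate_session(
    params: ResponderParams,
    schedule: BatterySchedule,
    participant_id: str = "P01",
    trial_lists: dict[int, list] | None = None,
) -> SessionData:
    """Simulate one full session (pre BRUMS, 12 blocks, post BRUMS).

    ``trial_lists`` may supply pre-generated per-block candidate trials (they
    are deterministic functions of the schedule, so sharing them across a
    cohort changes nothing); otherwise they are generated here.  Everything
    else is driven by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    if trial_lists is None:
        trial_lists = candidate_trials(schedule)

    pre_ratings, post_ratings = _simulate_brums_ratings(rng, params)
    pre_form = _make_form(rng, pre_ratings)

    trials: list[TrialRecord] = []
    elapsed = 0
    for block in schedule.blocks:
        records, used = _simulate_block(rng, params, block, trial_lists[block.index], elapsed)
        trials.extend(records)
        elapsed += used

    post_form = _make_form(rng, post_ratings)
    return SessionData(
        participant_id=participant_id,
        pre_brums=pre_form,
        post_brums=post_form,
        trials=trials,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Population distribution over :class:`ResponderParams`.

    ``base`` holds the population means; the ``*_sd`` fields the
    between-participant SDs (baseline accuracy varies on the log-odds scale,
    RT location on the log scale).  ``improver_fraction`` participants get
    their fatigue slopes negated and damped, modelling people whose
    performance improves over the battery (practice or late engagement).
    """

    base: ResponderParams = field(default_factory=default_params)
    accuracy_logit_sd: float = 0.5
    rt_mu_sd: float = 0.15
    accuracy_slope_sd: float = 0.10
    rt_slope_sd: float = 0.02
    shift_sd: float = 1.5
    pre_mean_sd: float = 2.0
    fatigue_vigor_coupling: float = 0.7
    improver_fraction: float = 0.0

    def sample(self, rng: np.random.Generator) -> ResponderParams:
        b = self.base
        acc = {}
        mu = {}
        for task in TASK_IDS:
            l0 = math.log(b.accuracy[task] / (1 - b.accuracy[task]))
            l0 += rng.normal(0.0, self.accuracy_logit_sd)
            acc[task] = 1.0 / (1.0 + math.exp(-l0))
            mu[task] = b.rt_mu[task] + rng.normal(0.0, self.rt_mu_sd)
        a_slope = b.fatigue_accuracy_slope + rng.normal(0.0, self.accuracy_slope_sd)
        r_slope = b.fatigue_rt_slope + rng.normal(0.0, self.rt_slope_sd)
        if rng.random() < self.improver_fraction:
            damp = rng.uniform(0.2, 0.8)
            a_slope = -abs(a_slope) * damp
            r_slope = -abs(r_slope) * damp
        pre = {
            s: max(0.0, b.brums_pre_means[s] + rng.normal(0.0, self.pre_mean_sd))
            for s in SUBSCALES
        }
        # One latent "fatigue response" factor drives both the fatigue rise
        # and (negatively) the vigor drop, so participants with larger
        # fatigue increases show larger vigor decreases.
        g = rng.standard_normal()
        mix = math.sqrt(1.0 - self.fatigue_vigor_coupling**2)
        shifts = {}
        for s in SUBSCALES:
            base_shift = b.brums_shifts.get(s, 0.0)
            if base_shift == 0.0:
                shifts[s] = 0.0
            elif s == "fatigue":
                shifts[s] = base_shift + self.shift_sd * g
            elif s == "vigor":
                shifts[s] = base_shift - self.shift_sd * (
                    self.fatigue_vigor_coupling * g + mix * rng.standard_normal()
                )
            else:
                shifts[s] = base_shift + rng.normal(0.0, self.shift_sd)
        return replace(
            b,
            accuracy=acc,
            rt_mu=mu,
            fatigue_accuracy_slope=a_slope,
            fatigue_rt_slope=r_slope,
            brums_pre_means=pre,
            brums_shifts=shifts,
        )


def study_like_cohort(improver_fraction: float = 0.3) -> CohortSpec:
    """Cohort emulating the study population: fatigue drift in most
    participants, roughly a third improving instead (14 of 45 did)."""
    return CohortSpec(improver_fraction=improver_fraction)


def moderate_fatigue_cohort() -> CohortSpec:
    """Uniform-direction moderate fatigue effect (no improvers)."""
    return CohortSpec(improver_fraction=0.0)


def null_cohort() -> CohortSpec:
    """No time-on-task drift and no mood shift; baseline heterogeneity kept."""
    base = default_params()
    base = replace(
        base,
        fatigue_accuracy_slope=0.0,
        fatigue_rt_slope=0.0,
        brums_shifts={s: 0.0 for s in SUBSCALES},
    )
    return CohortSpec(
        base=base, accuracy_slope_sd=0.0, rt_slope_sd=0.0, shift_sd=0.0
    )


def simulate_cohort(
    n: int,
    params_sampler: Callable[[np.random.Generator], ResponderParams] | CohortSpec | None = None,
    seed: int = 0,
    schedule: BatterySchedule | None = None,
    block_duration_s: int | None = None,
) -> list[SessionData]:
    """Simulate ``n`` independent participants through one battery deployment.

    All participants share one schedule (one deployment of the experiment
    program, as in the study); participant-level parameters are drawn from
    ``params_sampler`` (a :class:`CohortSpec` or a callable on a Generator;
    default: :func:`study_like_cohort`) and each session gets its own child
    seed derived from ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if params_sampler is None:
        params_sampler = study_like_cohort()
    sampler = params_sampler.sample if isinstance(params_sampler, CohortSpec) else params_sampler

    root = np.random.SeedSequence(seed)
    children = root.spawn(n + 2)
    sched_ss, sample_ss = children[0], children[1]
    if schedule is None:
        schedule = assemble_battery(
            int(sched_ss.generate_state(1)[0] % (2**31)),
            block_duration_s or 600,
        )
    trial_lists = candidate_trials(schedule)
    sample_rng = np.random.default_rng(sample_ss)

    sessions = []
    width = max(2, len(str(n)))
    for i, child in enumerate(children[2:]):
        params = sampler(sample_rng)
        params = replace(params, seed=int(child.generate_state(1)[0] % (2**31)))
        sessions.append(
            simulate_session(
                params,
                schedule,
                participant_id=f"P{i + 1:0{width}d}",
                trial_lists=trial_lists,
            )
        )
    return sessions
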