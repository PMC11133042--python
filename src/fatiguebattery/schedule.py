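"""Assembly and validation of the 12-block, 120-minute battery schedule.

The protocol runs each of the four tasks three times for 10 minutes (600 s),
with the AX-CPT as the critical first and last block and no task repeated
back-to-back.  The concrete middle-block order is fixed (identical for every
participant) so that any order effect is shared across the cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .tasks import (
    AXCPT,
    MROT,
    NBACK,
    TASK_IDS,
    VSEARCH,
    gen_axcpt_trials,
    gen_mrot_trials,
    gen_nback_trials,
    gen_vsearch_trials,
)

#: Fixed block order: AX-CPT first and last, no back-to-back repeats, each
#: task three times, repeats of a task spread roughly evenly.
DEFAULT_TASK_ORDER = (
    AXCPT, NBACK, VSEARCH, MROT, NBACK, AXCPT,
    VSEARCH, MROT, NBACK, VSEARCH, MROT, AXCPT,
)

DEFAULT_BLOCK_DURATION_S = 600
N_BLOCKS = 12

_GENERATORS = {
    AXCPT: gen_axcpt_trials,
    NBACK: gen_nback_trials,
    VSEARCH: gen_vsearch_trials,
    MROT: gen_mrot_trials,
}


@dataclass(frozen=True, slots=True)
class Block:
    """One scheduled block: 1-based index, task, time budget and RNG seed."""

    index: int
    task_id: str
    duration_s: int
    seed: int


@dataclass(frozen=True, slots=True)
class BatterySchedule:
    blocks: tuple[Block, ...]

    @property
    def total_minutes(self) -> float:
        return sum(b.duration_s for b in self.blocks) / 60.0

    def task_sequence(self) -> tuple[str, ...]:
        return tuple(b.task_id for b in self.blocks)


def derive_block_seed(battery_seed: int, block_index: int) -> int:
    """Deterministic per-block child seed from the battery seed (1-based index)."""
    ss = np.random.SeedSequence(entropy=battery_seed, spawn_key=(block_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def assemble_battery(
    seed: int, block_duration_s: int = DEFAULT_BLOCK_DURATION_S
) -> BatterySchedule:
    """Build the fixed 12-block schedule with per-block seeds derived from ``seed``."""
    if block_duration_s <= 0:
        raise ValueError("block_duration_s must be positive")
    blocks = tuple(
        Block(
            index=i + 1,
            task_id=task,
            duration_s=block_duration_s,
            seed=derive_block_seed(seed, i + 1),
        )
        for i, task in enumerate(DEFAULT_TASK_ORDER)
    )
    return BatterySchedule(blocks=blocks)


def validate_schedule(schedule: BatterySchedule) -> list[str]:
    """Return one named violation per broken schedule constraint (empty if valid)."""
    violations: list[str] = []
    blocks = schedule.blocks
    if len(blocks) != N_BLOCKS:
        violations.append(f"block count: expected {N_BLOCKS}, got {len(blocks)}")
    for b in blocks:
        if b.task_id not in TASK_IDS:
            violations.append(f"unknown task: block {b.index} has {b.task_id!r}")
        if b.duration_s <= 0:
            violations.append(f"block duration: block {b.index} has {b.duration_s} s")
    if blocks and (blocks[0].task_id != AXCPT or blocks[-1].task_id != AXCPT):
        violations.append("first/last task: AX-CPT must open and close the battery")
    for a, b in zip(blocks, blocks[1:]):
        if a.task_id == b.task_id:
            violations.append(
                f"back-to-back repeat: blocks {a.index} and {b.index} are both {a.task_id}"
            )
    counts = Counter(b.task_id for b in blocks)
    for task in TASK_IDS:
        if len(blocks) == N_BLOCKS and counts.get(task, 0) != 3:
            violations.append(
                f"task occurrence: {task} appears {counts.get(task, 0)} times, expected 3"
            )
    total_s = sum(b.duration_s for b in blocks)
    if len(blocks) == N_BLOCKS and blocks and total_s != N_BLOCKS * blocks[0].duration_s:
        violations.append("total duration: blocks have unequal time budgets")
    return violations


def trials_for_block(block: Block, n_trials: int):
    """Generate ``n_trials`` trials for a block with its own task and seed."""
    return _GENERATORS[block.task_id](n_trials, block.seed)
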