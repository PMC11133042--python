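"""Constrained pseudorandom trial generation for the four battery tasks.

The fatigue battery alternates four keyboard tasks — the AX continuous
performance test (AX-CPT), a 3-back letter task, a T-among-Ls visual search,
and a cube-figure mental rotation task.  Every task uses the same two response
keys ('k' for targets/matches, 'd' otherwise) and every generator here
enforces the battery's hard pseudorandomization constraints:

* AX-CPT: each non-overlapping decade of 10 trials contains exactly seven AX
  (target) trials and one each of the BX, AY and BY non-target types.
* 3-back: each decade contains exactly three targets (current letter equals
  the letter three positions back) and seven non-targets.
* Visual search: each decade contains exactly five target-present and five
  target-absent trials; every display holds 11 rotated letters on distinct
  cells of a 4x4 grid.
* Mental rotation: stimuli are drawn in epochs, each epoch a fresh
  permutation of the full 96-item catalogue, so every stimulus is seen once
  before any repeats.

Stimuli are carried as metadata only (letters, grid placements, catalogue
ids); nothing here renders anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from string import ascii_uppercase

import numpy as np

AXCPT = "AXCPT"
NBACK = "NBACK"
VSEARCH = "VSEARCH"
MROT = "MROT"
TASK_IDS = (AXCPT, NBACK, VSEARCH, MROT)

ALPHABET = ascii_uppercase

#: Letters usable as AX-CPT "B"/"Y" role letters and as distractors
#: (anything except the reserved A, X and the response-key look-alikes K, Y).
AXCPT_NEUTRAL_LETTERS = tuple(c for c in ALPHABET if c not in "AKXY")

# Shared trial tail: written feedback then a blank inter-trial interval.
FEEDBACK_MS = 1000
ITI_MS = 1200

AXCPT_LETTER_MS = 300       # cue / distractor / probe display
AXCPT_BLANK_MS = 1200       # blank after every letter
NBACK_PRESENTATION_MS = 2000
MROT_WINDOW_MS = 7500

#: Response window per task, in ms from stimulus (probe) onset.
#: ``None`` means unlimited (visual search waits for a response).
RESPONSE_WINDOW_MS = {AXCPT: 1200, NBACK: 2000, VSEARCH: None, MROT: 7500}

GRID_CELLS = 16             # invisible 4x4 placement grid
N_SEARCH_ITEMS = 11
ROTATIONS = (0, 90, 180, 270)

MROT_ANGLES = (0, 50, 100, 150)
MROT_N_OBJECTS = 12

_AXCPT_DECADE = ("AX",) * 7 + ("BX", "AY", "BY")
_KEY_FOR = {True: "k", False: "d"}


@dataclass(frozen=True, slots=True)
class AxcptTrial:
    """One AX-CPT trial: a cue, two distractors, then a probe.

    The correct response is 'k' only on AX trials (cue A, probe X); all three
    non-target types (BX, AY, BY) require 'd'.
    """

    cue: str
    distractors: tuple[str, str]
    probe: str
    trial_type: str
    correct_key: str

    @property
    def descriptor(self) -> str:
        return f"{self.cue}{self.distractors[0]}{self.distractors[1]}{self.probe}"


@dataclass(frozen=True, slots=True)
class NbackTrial:
    """One 3-back trial: a letter plus its (recomputable) target flag."""

    letter: str
    is_target: bool
    correct_key: str

    @property
    def descriptor(self) -> str:
        return self.letter


@dataclass(frozen=True, slots=True)
class VSearchTrial:
    """One visual-search display: 11 rotated L/T glyphs on a 4x4 grid.

    ``placements`` holds (glyph, cell, rotation) triples; cells are distinct
    indices in 0..15 and rotations multiples of 90 degrees.  Exactly one
    glyph is a T when ``target_present``.
    """

    placements: tuple[tuple[str, int, int], ...]
    target_present: bool
    correct_key: str

    @property
    def descriptor(self) -> str:
        return "|".join(f"{g}@{c}r{r}" for g, c, r in self.placements)


@dataclass(frozen=True, slots=True)
class MRotTrial:
    """One mental-rotation trial referencing the cube-figure catalogue.

    ``stimulus_id`` follows the catalogue naming ``<object>_<angle>`` for
    matching pairs and ``<object>_<angle>_R`` for pseudo-mirror pairs.
    """

    stimulus_id: str
    base_object: int
    angle: int
    matching: bool
    correct_key: str

    @property
    def descriptor(self) -> str:
        return self.stimulus_id


def _check_n(n_trials: int) -> None:
    if n_trials < 0:
        raise ValueError(f"n_trials must be non-negative, got {n_trials}")


def gen_axcpt_trials(n_trials: int, seed: int) -> list[AxcptTrial]:
    """Generate an AX-CPT sequence with the 7/1/1/1 per-decade composition.

    Each consecutive non-overlapping decade of ten trials holds exactly seven
    AX targets and one each of BX, AY, BY, shuffled within the decade.  A
    trailing partial decade is the truncated prefix of a full shuffled decade.
    Cue and probe are never K or Y; "B"/"Y" role letters and distractors are
    drawn uniformly from the 22 letters excluding A, K, X, Y.
    """
    _check_n(n_trials)
    rng = np.random.default_rng(seed)
    pool = AXCPT_NEUTRAL_LETTERS
    trials: list[AxcptTrial] = []
    for _ in range(ceil(n_trials / 10)):
        types = list(_AXCPT_DECADE)
        rng.shuffle(types)
        draws = rng.integers(0, len(pool), size=(10, 4))
        for tt, d in zip(types, draws):
            cue = "A" if tt[0] == "A" else pool[d[0]]
            probe = "X" if tt[1] == "X" else pool[d[1]]
            trials.append(
                AxcptTrial(
                    cue=cue,
                    distractors=(pool[d[2]], pool[d[3]]),
                    probe=probe,
                    trial_type=tt,
                    correct_key=_KEY_FOR[tt == "AX"],
                )
            )
    return trials[:n_trials]


def gen_nback_trials(n_trials: int, seed: int) -> list[NbackTrial]:
    """Generate a 3-back letter sequence with 3 targets per decade.

    Targets are positions whose letter equals the letter three positions
    earlier.  Each non-overlapping decade receives exactly three targets,
    except that the first decade places its targets within indices 3..9
    (earlier positions have no lag-3 predecessor).  Non-target letters are
    drawn so they never accidentally match the letter three back; stored
    flags are therefore exactly recomputable from the letter sequence.
    """
    _check_n(n_trials)
    rng = np.random.default_rng(seed)
    n_dec = ceil(n_trials / 10)
    targets: set[int] = set()
    for d in range(n_dec):
        lo = d * 10
        eligible = [i for i in range(lo, lo + 10) if i >= 3]
        picks = rng.choice(len(eligible), size=3, replace=False)
        targets.update(eligible[j] for j in picks)

    letters: list[str] = []
    for i in range(n_dec * 10):
        if i in targets:
            letters.append(letters[i - 3])
        else:
            c = ALPHABET[rng.integers(26)]
            while i >= 3 and c == letters[i - 3]:
                c = ALPHABET[rng.integers(26)]
            letters.append(c)
    return [
        NbackTrial(letter=c, is_target=(i in targets), correct_key=_KEY_FOR[i in targets])
        for i, c in enumerate(letters[:n_trials])
    ]


def gen_vsearch_trials(n_trials: int, seed: int) -> list[VSearchTrial]:
    """Generate visual-search displays with 5 present / 5 absent per decade.

    Every display places 11 glyphs on distinct cells of the 4x4 grid with
    uniform rotations.  Target-present displays contain exactly one T among
    ten Ls; target-absent displays contain eleven Ls.
    """
    _check_n(n_trials)
    rng = np.random.default_rng(seed)
    trials: list[VSearchTrial] = []
    for _ in range(ceil(n_trials / 10)):
        flags = [True] * 5 + [False] * 5
        rng.shuffle(flags)
        for present in flags:
            cells = rng.choice(GRID_CELLS, size=N_SEARCH_ITEMS, replace=False)
            rots = rng.integers(0, 4, size=N_SEARCH_ITEMS)
            glyphs = ["L"] * N_SEARCH_ITEMS
            if present:
                glyphs[int(rng.integers(N_SEARCH_ITEMS))] = "T"
            placements = tuple(
                (g, int(c), ROTATIONS[r]) for g, c, r in zip(glyphs, cells, rots)
            )
            trials.append(
                VSearchTrial(
                    placements=placements,
                    target_present=present,
                    correct_key=_KEY_FOR[present],
                )
            )
    return trials[:n_trials]


def build_mrot_catalog() -> list[MRotTrial]:
    """Build the 96-entry mental-rotation stimulus catalogue.

    Twelve base cube objects x four angular disparities (0, 50, 100, 150
    degrees) x {matching, pseudo-mirror} = 96 entries.  Ids follow the
    ``<object>_<angle>`` / ``<object>_<angle>_R`` convention of the validated
    cube-figure set; the image bitmaps themselves are external and are
    referenced by id only.
    """
    catalog = []
    for obj in range(1, MROT_N_OBJECTS + 1):
        for angle in MROT_ANGLES:
            for matching in (True, False):
                sid = f"{obj}_{angle}" + ("" if matching else "_R")
                catalog.append(
                    MRotTrial(
                        stimulus_id=sid,
                        base_object=obj,
                        angle=angle,
                        matching=matching,
                        correct_key=_KEY_FOR[matching],
                    )
                )
    return catalog


def gen_mrot_trials(n_trials: int, seed: int) -> list[MRotTrial]:
    """Generate mental-rotation trials in full-coverage epochs.

    Trials are drawn epoch by epoch; each epoch is a fresh random permutation
    of the whole 96-stimulus catalogue and a new epoch starts only once the
    previous one is exhausted, so no stimulus repeats before every stimulus
    has been shown.
    """
    _check_n(n_trials)
    rng = np.random.default_rng(seed)
    catalog = build_mrot_catalog()
    trials: list[MRotTrial] = []
    while len(trials) < n_trials:
        trials.extend(catalog[i] for i in rng.permutation(len(catalog)))
    return trials[:n_trials]


def trial_duration(task_id: str, response_time_ms: int | float | None = None) -> int:
    """Full wall time of one trial in ms, given the response latency.

    ``response_time_ms`` is measured from stimulus onset (probe onset for the
    AX-CPT) and must lie within the task's response window; ``None`` means no
    response was given (an omission, or for visual search an invalid call
    since its window is unlimited).  Every trial ends with 1000 ms feedback
    and a 1200 ms inter-trial interval.  Fixed-pace phases: the AX-CPT shows
    cue and two distractors for 300 ms each, each followed by a 1200 ms
    blank; the 3-back letter stays up for its full 2000 ms regardless of
    when the response arrives.
    """
    if task_id not in TASK_IDS:
        raise ValueError(f"unknown task id {task_id!r}")
    window = RESPONSE_WINDOW_MS[task_id]
    if response_time_ms is not None:
        if response_time_ms < 0:
            raise ValueError("response_time_ms must be non-negative")
        if window is not None and response_time_ms > window:
            raise ValueError(
                f"response_time_ms {response_time_ms} exceeds the {task_id} "
                f"window of {window} ms"
            )
    tail = FEEDBACK_MS + ITI_MS
    if task_id == AXCPT:
        lead = 3 * (AXCPT_LETTER_MS + AXCPT_BLANK_MS)
        if response_time_ms is None:
            probe_phase = AXCPT_LETTER_MS + AXCPT_BLANK_MS
        else:
            probe_phase = response_time_ms
        return int(round(lead + probe_phase + tail))
    if task_id == NBACK:
        return NBACK_PRESENTATION_MS + tail
    if task_id == VSEARCH:
        if response_time_ms is None:
            raise ValueError("visual search has no response deadline; a response is required")
        return int(round(response_time_ms + tail))
    # MROT
    phase = MROT_WINDOW_MS if response_time_ms is None else response_time_ms
    return int(round(phase + tail))
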