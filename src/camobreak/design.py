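"""Randomised factorial session plans.

Each subject completes 10 practice trials followed by four blocks of 50
main trials.  A block is a uniform random permutation of 5 replicates of
each of the 10 cells of the 2 (square size) x 5 (treatment) factorial, so a
full session holds 20 replicates of every cell.

The stated practice composition ("two replicates of each treatment
combination" in 10 trials) cannot cover all 10 factorial cells; practice is
therefore two replicates of each of the five treatments with the square
size of each practice trial drawn at random.  Practice trials are flagged
and excluded from all analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .scene import TREATMENTS

__all__ = ["TrialSpec", "SessionPlan", "build_block", "build_session", "session_table"]

SQUARE_SIZES = ("small", "large")
TRIALS_PER_BLOCK = 50
N_BLOCKS = 4
REPLICATES_PER_BLOCK = 5
N_PRACTICE = 10


@dataclass(frozen=True)
class TrialSpec:
    block: int  # 0 = practice
    index_in_block: int
    treatment: str
    square_size: str
    scene_seed: int
    practice: bool


@dataclass(frozen=True)
class SessionPlan:
    subject_id: str
    trials: tuple[TrialSpec, ...]
    master_seed: int

    @property
    def main_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if not t.practice)


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    # scene seeds are user-facing; keep them in 32-bit range
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def build_block(
    block_no: int,
    rng: np.random.Generator | int,
    seed_stream: list[np.random.SeedSequence] | None = None,
    n_blocks_replicates: int = REPLICATES_PER_BLOCK,
) -> list[TrialSpec]:
    """One block: a uniform permutation of 5 replicates of all 10 cells."""
    if isinstance(rng, (int, np.integer)):
        ss = np.random.SeedSequence(int(rng))
        children = ss.spawn(TRIALS_PER_BLOCK + 1)
        rng = np.random.Generator(np.random.PCG64(children[0]))
        seed_stream = list(children[1:])
    assert seed_stream is not None
    cells = [
        (t, s)
        for t in TREATMENTS
        for s in SQUARE_SIZES
        for _ in range(n_blocks_replicates)
    ]
    order = rng.permutation(len(cells))
    return [
        TrialSpec(
            block=block_no,
            index_in_block=i + 1,
            treatment=cells[j][0],
            square_size=cells[j][1],
            scene_seed=_spawn_seed(seed_stream.pop()),
            practice=False,
        )
        for i, j in enumerate(order)
    ]


def build_session(
    subject_id: str,
    master_seed: int,
    n_blocks: int = N_BLOCKS,
    include_practice: bool = True,
) -> SessionPlan:
    """Practice trials followed by ``n_blocks`` randomised main blocks.

    Per-trial scene seeds are spawned from the master seed through a
    counter-based seed tree, so sessions are reproducible while scenes stay
    statistically independent.
    """
    ss = np.random.SeedSequence(master_seed)
    n_trials = n_blocks * TRIALS_PER_BLOCK + (N_PRACTICE if include_practice else 0)
    children = list(ss.spawn(n_trials + 1))
    rng = np.random.Generator(np.random.PCG64(children.pop(0)))
    trials: list[TrialSpec] = []
    if include_practice:
        practice_cells = [(t, rng.choice(SQUARE_SIZES)) for t in TREATMENTS for _ in range(2)]
        order = rng.permutation(N_PRACTICE)
        trials += [
            TrialSpec(
                block=0,
                index_in_block=i + 1,
                treatment=practice_cells[j][0],
                square_size=str(practice_cells[j][1]),
                scene_seed=_spawn_seed(children.pop()),
                practice=True,
            )
            for i, j in enumerate(order)
        ]
    for b in range(1, n_blocks + 1):
        trials += build_block(b, rng, children)
    return SessionPlan(subject_id=subject_id, trials=tuple(trials), master_seed=master_seed)


def session_table(plan: SessionPlan) -> pd.DataFrame:
    """Serialise a session plan to a tidy one-row-per-trial table."""
    df = pd.DataFrame([asdict(t) for t in plan.trials])
    df.insert(0, "subject_id", plan.subject_id)
    return df
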