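"""n-back block design: condition blocks with onsets/durations per session.

The layout emulated here is a working-memory paradigm of task blocks, each
containing the 0-back, 1-back and 2-back conditions (30 s each) in random
order, separated by 10-s intervals whose first 2 s display the instruction
for the upcoming condition. One task block therefore spans
30 + 10 + 30 + 10 + 30 = 110 s. The default session holds seven blocks and
two sessions are acquired back-to-back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Block", "TaskDesign", "generate_task_design", "CONDITIONS"]

CONDITIONS = ("0-back", "1-back", "2-back")

CONDITION_S = 30.0
INTERVAL_S = 10.0
INSTRUCTION_S = 2.0
BLOCK_S = 3 * CONDITION_S + 2 * INTERVAL_S  # 110 s


@dataclass(frozen=True)
class Block:
    label: str
    onset: float  # seconds from run start
    duration: float
    session: int


@dataclass
class TaskDesign:
    """Ordered, non-overlapping condition blocks with session bookkeeping."""

    blocks: list[Block] = field(default_factory=list)
    n_sessions: int = 1
    session_duration: float = 0.0  # seconds per session

    def __post_init__(self) -> None:
        last_end: dict[int, float] = {}
        for b in self.blocks:
            if b.duration <= 0:
                raise ValueError(f"non-positive duration in block {b}")
            if b.onset < last_end.get(b.session, -np.inf) - 1e-9:
                raise ValueError("blocks overlap or are out of order within a session")
            last_end[b.session] = b.onset + b.duration

    @property
    def total_duration(self) -> float:
        return self.n_sessions * self.session_duration

    def condition_windows(self, label: str, session: int | None = None) -> list[tuple[float, float]]:
        """(start, end) of every window with this label, in run-relative seconds.

        Onsets are stored per session; run-relative times offset each session
        by its duration so volumes of a concatenated run can be assigned.
        """
        out = []
        for b in self.blocks:
            if b.label != label:
                continue
            if session is not None and b.session != session:
                continue
            off = b.session * self.session_duration
            out.append((off + b.onset, off + b.onset + b.duration))
        return out

    def labels(self) -> list[str]:
        return sorted({b.label for b in self.blocks})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [b.label for b in self.blocks],
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "session": [b.session for b in self.blocks],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_sessions: int, session_duration: float) -> "TaskDesign":
        blocks = [
            Block(str(r.label), float(r.onset), float(r.duration), int(r.session))
            for r in df.itertuples()
        ]
        return cls(blocks=blocks, n_sessions=n_sessions, session_duration=session_duration)


def generate_task_design(
    n_blocks_per_session: int = 7,
    n_sessions: int = 2,
    rng_seed: int | np.random.Generator = 0,
    block_gap: float = 0.0,
) -> TaskDesign:
    """Build the n-back layout with seeded random condition order per block.

    Each task block holds the three conditions (30 s each, random order)
    separated by 10-s intervals whose first 2 s are instruction. Task blocks
    are laid back-to-back (``block_gap`` seconds apart, default 0), so the
    default configuration spans 7 × 110 s per session.
    """
    if n_blocks_per_session < 1 or n_sessions < 1:
        raise ValueError("block and session counts must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    blocks: list[Block] = []
    for ses in range(n_sessions):
        t = 0.0
        for _ in range(n_blocks_per_session):
            order = rng.permutation(len(CONDITIONS))
            start = t
            for k, idx in enumerate(order):
                blocks.append(Block(CONDITIONS[idx], t, CONDITION_S, ses))
                t += CONDITION_S
                if k < 2:
                    blocks.append(Block("instruction", t, INSTRUCTION_S, ses))
                    blocks.append(Block("interval", t + INSTRUCTION_S, INTERVAL_S - INSTRUCTION_S, ses))
                    t += INTERVAL_S
            assert abs((t - start) - BLOCK_S) < 1e-9
            t += block_gap
    session_duration = n_blocks_per_session * (BLOCK_S + block_gap)
    return TaskDesign(blocks=blocks, n_sessions=n_sessions, session_duration=session_duration)
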