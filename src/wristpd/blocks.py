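"""Block segmentation with double cover, timestamp validation, acceptance.

Recordings are cut into 65536-sample blocks (21.8 minutes at 50 Hz) with a
32768-sample hop, so every interior sample is covered by exactly two
blocks.  Blocks whose timestamps reveal sampling problems (gaps, clock
drift) are rejected before any spectral analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import AccelRecording

BLOCK_LEN = 65536
HOP = BLOCK_LEN // 2  # half-block hop => double cover


@dataclass
class Block:
    """One fixed-length segment of a recording."""

    subject_id: str
    start_time: float  # seconds
    start_index: int
    length: int
    t: np.ndarray  # (length,) timestamps
    data: np.ndarray  # (3, length) acceleration, g units
    sampling_rate: float
    valid: bool = True
    reject_reason: Optional[str] = None  # None | "gap" | "drift"

    def __post_init__(self) -> None:
        if self.length != self.t.size or self.data.shape != (3, self.length):
            raise ValueError("block shape inconsistent with declared length")
        if self.valid and self.reject_reason is not None:
            raise ValueError("valid block cannot carry a reject reason")


def block_duration_minutes(sampling_rate: float = 50.0,
                           length: int = BLOCK_LEN) -> float:
    """Nominal duration of one block in minutes (21.8 at 50 Hz)."""
    return round(length / sampling_rate / 60.0, 1)


def block_starts(n_samples: int, length: int = BLOCK_LEN, hop: int = HOP) -> np.ndarray:
    """Start indices of all complete blocks; trailing partials discarded."""
    if n_samples < length:
        return np.array([], dtype=int)
    count = (n_samples - length) // hop + 1
    return np.arange(count) * hop


def segment_blocks(recording: AccelRecording, length: int = BLOCK_LEN,
                   hop: int = HOP) -> list[Block]:
    """Cut a recording into half-overlapping fixed-length blocks."""
    starts = block_starts(recording.n_samples, length, hop)
    out = []
    for s in starts:
        sl = slice(int(s), int(s) + length)
        out.append(Block(
            subject_id=recording.subject_id,
            start_time=float(recording.t[s]),
            start_index=int(s),
            length=length,
            t=recording.t[sl],
            data=recording.xyz[sl].T,
            sampling_rate=recording.sampling_rate,
        ))
    return out


def validate_block(block: Block, gap_tol: float = 1.0,
                   drift_tol: float = 0.01) -> Block:
    """Flag blocks with timestamp gaps or sampling-rate drift.

    A block is rejected when any inter-sample interval exceeds ``gap_tol``
    seconds, or when its observed time span deviates from the nominal
    ``length / rate`` span by more than ``drift_tol`` (fractional).
    """
    dt = np.diff(block.t)
    if dt.size and float(dt.max()) > gap_tol:
        return replace(block, valid=False, reject_reason="gap")
    nominal = block.length / block.sampling_rate
    span = float(block.t[-1] - block.t[0])
    if abs(span - nominal) > drift_tol * nominal:
        return replace(block, valid=False, reject_reason="drift")
    return replace(block, valid=True, reject_reason=None)


def percent_accepted(n_accepted: int, n_total: int) -> Optional[int]:
    """Floor-rounded acceptance percentage; None when undefined (0 blocks)."""
    if n_total == 0:
        return None
    return (100 * n_accepted) // n_total


def acceptance_report(blocks: Sequence[Block]) -> dict:
    """Counts and floor-rounded percentage of accepted blocks."""
    n_total = len(blocks)
    n_accepted = sum(1 for b in blocks if b.valid)
    pct = percent_accepted(n_accepted, n_total)
    return {
        "n_total": n_total,
        "n_accepted": n_accepted,
        "percent_accepted": pct,
        "undefined": pct is None,
    }
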