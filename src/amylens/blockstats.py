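"""Block-analysis convergence statistics and the replica temperature ladder.

A trajectory is divided into equal consecutive blocks (six by default,
emulating a 600 ns run split into 100 ns blocks); reported statistics are
the mean and sample standard deviation of per-block means over the last
blocks (three by default). The temperature ladder reproduces the standard
replica-exchange construction: temperatures geometrically spaced between
the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_BLOCKS = 6
DEFAULT_LAST_K = 3


@dataclass(frozen=True)
class BlockPartition:
    """Equal consecutive index ranges covering ``n_frames`` frames.

    ``ranges`` holds half-open (start, stop) index pairs; sizes differ by
    at most one, with earlier blocks taking the remainder.
    """

    n_frames: int
    ranges: tuple[tuple[int, int], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.ranges)

    def sizes(self) -> tuple[int, ...]:
        return tuple(hi - lo for lo, hi in self.ranges)

    def last(self, k: int) -> tuple[tuple[int, int], ...]:
        if k > self.n_blocks:
            raise ValueError("fewer blocks than requested")
        return self.ranges[-k:]


def make_blocks(n_frames: int, n_blocks: int = DEFAULT_N_BLOCKS) -> BlockPartition:
    """Partition ``n_frames`` into ``n_blocks`` equal consecutive blocks."""
    if n_frames < n_blocks:
        raise ValueError(f"cannot split {n_frames} frames into {n_blocks} blocks")
    base, rem = divmod(n_frames, n_blocks)
    ranges = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < rem else 0)
        ranges.append((start, start + size))
        start += size
    return BlockPartition(n_frames, tuple(ranges))


def block_mean_std(values, partition: BlockPartition,
                   last_k: int = DEFAULT_LAST_K
                   ) -> tuple[float, float, np.ndarray]:
    """Mean and sample std of per-block means over the last ``last_k`` blocks.

    Returns ``(mean, std, per_block_means)`` where ``per_block_means``
    covers all blocks (for convergence inspection) and the reported
    mean/std use only the final ``last_k`` block means (std with divisor
    ``last_k - 1``).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != partition.n_frames:
        raise ValueError("one value per frame is required")
    if last_k > partition.n_blocks:
        raise ValueError("fewer blocks than last_k")
    if last_k < 2:
        raise ValueError("std over fewer than 2 blocks is undefined")
    per_block = np.array([values[lo:hi].mean() for lo, hi in partition.ranges])
    tail = per_block[-last_k:]
    return float(tail.mean()), float(tail.std(ddof=1)), per_block


def temperature_ladder(t_min: float = 270.0, t_max: float = 465.0,
                       n: int = 16) -> np.ndarray:
    """Geometrically spaced replica temperatures from t_min to t_max (K).

    T_i = t_min * (t_max / t_min)^(i / (n-1)); endpoints are exact and
    the ratio of consecutive temperatures is constant.
    """
    if not (t_max > t_min > 0):
        raise ValueError("need t_max > t_min > 0")
    if n < 2:
        raise ValueError("need at least 2 replicas")
    i = np.arange(n)
    ladder = t_min * (t_max / t_min) ** (i / (n - 1))
    ladder[0] = t_min
    ladder[-1] = t_max
    return ladder
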