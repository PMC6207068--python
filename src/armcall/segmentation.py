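"""Penalized least-squares changepoint segmentation.

Each chromosome of a normalized profile is partitioned into
constant-level segments by minimizing

    sum over segments of within-segment squared error
        + penalty * (number of segments),

solved *exactly* with the O(n^2) optimal-partitioning dynamic program.
This is a deterministic, automatic stand-in for interactive breakpoint
annotation tools: the pipeline equally accepts externally produced
segment tables and skips this stage.

The ``auto`` penalty is a BIC-flavored 2*sigma^2*log(n) with sigma
estimated robustly from successive probe differences, so isolated noise
spikes do not inflate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SegmentationError

logger = logging.getLogger(__name__)

_MIN_PENALTY = 1e-8


@dataclass
class SegmentationConfig:
    penalty: float | str = "auto"  # per-segment cost, or "auto"
    min_probes_per_segment: int = 1

    def __post_init__(self):
        if self.penalty != "auto" and float(self.penalty) < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_probes_per_segment < 1:
            raise ValueError("min_probes_per_segment must be >= 1")


def auto_penalty(values: np.ndarray) -> float:
    """Data-driven per-segment penalty 2*sigma^2*log(n).

    sigma is the Gaussian-consistent MAD estimate of the probe noise,
    computed on successive differences (robust to true copy-number
    steps): sigma = 1.4826 * MAD(diff) / sqrt(2).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise SegmentationError("auto penalty needs at least 3 probes")
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    if sigma == 0.0:
        return _MIN_PENALTY
    return float(2.0 * sigma**2 * np.log(n))


def _optimal_partition(values: np.ndarray, penalty: float, min_probes: int) -> list[int]:
    """Exact optimal-partitioning DP; returns changepoint indices.

    The returned list ``[b1, ..., bk, n]`` gives segment boundaries:
    segments are ``values[0:b1], values[b1:b2], ...``.
    """
    n = len(values)
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_probes, n + 1):
        i = np.arange(0, j - min_probes + 1)
        lengths = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / lengths
        cand = best[i] + sse + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = i[k]
    if not np.isfinite(best[n]):
        return [n]
    bounds = []
    j = n
    while j > 0:
        bounds.append(j)
        j = prev[j]
    return bounds[::-1]


def segment_profile(
    probes: pd.DataFrame,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Segment one sample's probe table into a segment table.

    Chromosomes are segmented independently. Segment bounds span the
    first to last member probe position (end = last position + 1);
    segment value is the mean of member probes.
    """
    config = config or SegmentationConfig()
    rows = []
    for (sample, chrom), grp in probes.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("position")
        values = grp.log2_ratio.to_numpy(dtype=float)
        positions = grp.position.to_numpy(dtype=int)
        n = len(values)
        if n < config.min_probes_per_segment:
            logger.warning(
                "chrom %s of sample %s has %d probes (< min_probes_per_segment); one segment",
                chrom, sample, n,
            )
            bounds = [n]
        else:
            if config.penalty == "auto":
                penalty = auto_penalty(values) if n >= 3 else _MIN_PENALTY
            else:
                penalty = float(config.penalty)
            bounds = _optimal_partition(values, penalty, config.min_probes_per_segment)
        start = 0
        for b in bounds:
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "start": int(positions[start]),
                    "end": int(positions[b - 1]) + 1,
                    "n_probes": b - start,
                    "log2_ratio": float(values[start:b].mean()),
                    "annotation": "",
                }
            )
            start = b
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio", "annotation"])


def partition_cost(values: np.ndarray, bounds: list[int], penalty: float) -> float:
    """Objective value of a given partition (for oracle comparisons)."""
    values = np.asarray(values, dtype=float)
    cost = penalty * len(bounds)
    start = 0
    for b in bounds:
        seg = values[start:b]
        cost += float(((seg - seg.mean()) ** 2).sum())
        start = b
    return cost
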