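"""Temporal alignment of visual frames with acoustic segments.

Two sampled streams rarely tick in lockstep: cameras capture frames at one
rate, recorders chunk audio at another.  Alignment constructs a mapping
``g`` from each visual timestamp to an acoustic timestamp that minimises the
mean absolute time difference, either independently per frame
(nearest-neighbour) or under a monotone non-decreasing constraint (dynamic
time warping).  A separate feature-space consistency check verifies that the
encoders agree on an aligned pair within a tolerance ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TimestampStreams", "AlignmentResult", "AlignConfig",
           "align_nearest", "align_dtw", "check_consistency",
           "calibrate_epsilon", "alignment_report"]


@dataclass
class TimestampStreams:
    t_visual: np.ndarray
    t_acoustic: np.ndarray

    def __post_init__(self):
        self.t_visual = np.asarray(self.t_visual, dtype=float)
        self.t_acoustic = np.asarray(self.t_acoustic, dtype=float)
        for name, arr in (("t_visual", self.t_visual),
                          ("t_acoustic", self.t_acoustic)):
            if arr.size == 0:
                raise ValueError(f"{name} is empty")
            if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class AlignmentResult:
    mapping: np.ndarray        # index into t_acoustic for each visual frame
    mean_abs_error: float      # seconds
    method: str


@dataclass
class AlignConfig:
    epsilon: float = 1.0       # feature-space consistency threshold
    method: str = "nearest"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.method not in ("nearest", "dtw"):
            raise ValueError("method must be 'nearest' or 'dtw'")


def align_nearest(streams: TimestampStreams) -> AlignmentResult:
    """Map each visual timestamp to the closest acoustic one (ties -> earlier)."""
    tv, ta = streams.t_visual, streams.t_acoustic
    pos = np.searchsorted(ta, tv)
    left = np.clip(pos - 1, 0, ta.size - 1)
    right = np.clip(pos, 0, ta.size - 1)
    d_left = np.abs(tv - ta[left])
    d_right = np.abs(tv - ta[right])
    mapping = np.where(d_left <= d_right, left, right)  # tie toward earlier
    mae = float(np.mean(np.abs(tv - ta[mapping])))
    return AlignmentResult(mapping.astype(int), mae, "nearest")


def align_dtw(streams: TimestampStreams) -> AlignmentResult:
    """Optimal monotone non-decreasing mapping by dynamic programming.

    Minimises sum |tv_i - ta_g(i)| subject to g(i) >= g(i-1) (match, repeat the
    acoustic index, or advance).  The prefix-minimum recurrence makes the DP
    O(Nv * Na); the result is the exact optimum over all monotone mappings.
    """
    tv, ta = streams.t_visual, streams.t_acoustic
    nv, na = tv.size, ta.size
    cost = np.abs(tv[:, None] - ta[None, :])
    acc = np.empty_like(cost)
    choice = np.empty((nv, na), dtype=int)
    acc[0] = cost[0]
    choice[0] = np.arange(na)
    for i in range(1, nv):
        # best previous column index j' <= j
        prefix_best = np.minimum.accumulate(acc[i - 1])
        argbest = np.zeros(na, dtype=int)
        best = acc[i - 1, 0]
        bi = 0
        for j in range(na):
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
                bi = j
            argbest[j] = bi
        acc[i] = cost[i] + prefix_best
        choice[i] = argbest
    j = int(np.argmin(acc[-1]))
    mapping = np.empty(nv, dtype=int)
    mapping[-1] = j
    for i in range(nv - 1, 0, -1):
        j = choice[i, j]
        mapping[i - 1] = j
    mae = float(np.mean(np.abs(tv - ta[mapping])))
    return AlignmentResult(mapping, mae, "dtw")


def check_consistency(fv: np.ndarray, fa: np.ndarray,
                      config: AlignConfig) -> tuple[bool, float]:
    """Cross-modal consistency: ||fv - fa||_2 <= epsilon."""
    fv = np.asarray(fv, dtype=float).ravel()
    fa = np.asarray(fa, dtype=float).ravel()
    if fv.shape != fa.shape:
        raise ValueError("feature dimensions differ")
    dist = float(np.linalg.norm(fv - fa))
    return dist <= config.epsilon, dist


def calibrate_epsilon(intra_pair_distances: np.ndarray,
                      percentile: float = 95.0) -> float:
    """Consistency threshold as a percentile of held-out intra-pair distances."""
    d = np.asarray(intra_pair_distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one calibration distance")
    return float(np.percentile(d, percentile))


def alignment_report(streams: TimestampStreams,
                     result: AlignmentResult) -> pd.DataFrame:
    """Per-frame alignment table (index, tv, ta, abs_error) for CSV export."""
    ta = streams.t_acoustic[result.mapping]
    return pd.DataFrame({
        "index": np.arange(streams.t_visual.size),
        "tv": streams.t_visual,
        "ta": ta,
        "abs_error": np.abs(streams.t_visual - ta),
    })
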