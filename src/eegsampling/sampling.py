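"""Segmentation and representative-sample selection for per-class recordings.

Long EEG recordings are nonstationary: their magnitude changes over time.
Each class recording is therefore partitioned into k contiguous,
nonoverlapping time segments, and representative time points are selected
within segments under one of two survey-sampling designs:

* Random sampling (RS): each segment is treated as its own finite
  population, its required sample size computed from the confidence-interval
  formula with finite-population correction, and points drawn uniformly
  without replacement.

* Optimum allocation sampling (OS): the required sample size m is computed
  once for the whole recording, then divided across segments in proportion
  to N_i * sqrt(sum_j s_ij^2) — the segment length times the root of the
  summed per-channel variances — so larger and more variable segments
  contribute more points.

The selected time indices are shared by every channel of a class, which
preserves cross-channel time alignment. The union of all per-segment draws
of a class forms its sample set (the "RS set" or "OS set"), from which the
statistical features are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import ClassDataset, RunConfig
from .errors import (
    DegenerateAllocationError,
    DomainError,
    InfeasibleAllocationError,
    InvalidPartitionError,
    OversampleError,
)


@dataclass(frozen=True)
class SegmentationPlan:
    """Half-open index intervals [start, end) covering a signal of length L.

    The first k-1 segments have size floor(L/k); the remainder is appended
    to the last segment (a 4097-point recording split 4 ways gives
    1024, 1024, 1024, 1025).
    """

    total_length: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(end - start for start, end in self.boundaries)


@dataclass(frozen=True)
class SamplingDesign:
    """Sample-size design parameters: z-value, proportion, margin of error."""

    scheme: str
    z: float
    p: float
    e: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise DomainError("z must be positive")
        if not 0 < self.p < 1:
            raise DomainError("p must lie in (0, 1)")
        if self.e <= 0:
            raise DomainError("e must be positive")


@dataclass(frozen=True)
class AllocationResult:
    """Integer per-segment sample sizes summing exactly to the budget m."""

    per_segment_sizes: tuple[int, ...]
    weights: tuple[float, ...]
    total: int

    def __post_init__(self) -> None:
        assert sum(self.per_segment_sizes) == self.total


@dataclass
class SampleSet:
    """Selected time indices and sampled values for every channel of a class."""

    class_label: str
    segment_indices: list[np.ndarray]  # global indices, one array per segment
    channel_ids: list[str]
    values: dict[str, np.ndarray]  # channel_id -> concatenated sampled values
    per_segment_sizes: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.per_segment_sizes = tuple(len(ix) for ix in self.segment_indices)
        n_total = sum(self.per_segment_sizes)
        for ch, v in self.values.items():
            if len(v) != n_total:
                raise DomainError(
                    f"channel {ch!r}: {len(v)} sampled values, expected {n_total}"
                )

    @property
    def n_sampled(self) -> int:
        return sum(self.per_segment_sizes)


def segment_signal(total_length: int, k: int) -> SegmentationPlan:
    """Partition [0, total_length) into k contiguous segments.

    The first k-1 segments have size floor(L/k); the last absorbs the
    remainder.
    """
    if k < 1 or k > total_length:
        raise InvalidPartitionError(
            f"cannot split a length-{total_length} signal into {k} segments"
        )
    base = total_length // k
    bounds = [(i * base, (i + 1) * base) for i in range(k - 1)]
    bounds.append(((k - 1) * base, total_length))
    return SegmentationPlan(total_length=total_length, boundaries=tuple(bounds))


def required_sample_size(popu: int, z: float, p: float, e: float) -> int:
    """Required sample size for a finite population of size ``popu``.

    The infinite-population size is SS = z^2 p (1-p) / e^2; the
    finite-population correction shrinks it to n = SS / (1 + (SS-1)/Popu),
    rounded up to the next integer. Always satisfies 1 <= n <= popu.
    """
    if popu < 1:
        raise DomainError(f"population size must be >= 1, got {popu}")
    design = SamplingDesign(scheme="RS", z=z, p=p, e=e)  # validates z, p, e
    ss = design.z**2 * design.p * (1.0 - design.p) / design.e**2
    n = math.ceil(ss / (1.0 + (ss - 1.0) / popu))
    return min(max(n, 1), popu)


def optimum_allocation(
    segment_sizes: Sequence[int],
    segment_channel_variances: np.ndarray,
    m: int,
) -> AllocationResult:
    """Divide a class-level budget m across segments by optimum allocation.

    The weight of segment i is w_i = N_i * sqrt(sum_j s_ij^2), where s_ij^2
    is the variance of channel j within segment i. Raw shares
    r_i = m * w_i / sum(w) are converted to integers by largest-remainder
    (Hamilton) rounding, which conserves the total exactly. A share capped
    at its segment size N_i releases its surplus for redistribution among
    the uncapped segments by the same rule.
    """
    sizes = np.asarray(segment_sizes, dtype=int)
    s2 = np.atleast_2d(np.asarray(segment_channel_variances, dtype=float))
    if s2.shape[0] != sizes.size:
        raise DomainError(
            f"variance matrix has {s2.shape[0]} rows for {sizes.size} segments"
        )
    if np.any(s2 < 0):
        raise DomainError("variances must be nonnegative")
    if m > int(sizes.sum()):
        raise InfeasibleAllocationError(
            f"budget m={m} exceeds total population {int(sizes.sum())}"
        )
    if m < 0:
        raise DomainError("budget m must be nonnegative")

    weights = sizes * np.sqrt(s2.sum(axis=1))
    if not np.any(weights > 0):
        raise DegenerateAllocationError("all allocation weights are zero")

    n_i = _largest_remainder_with_caps(weights, caps=sizes, total=m)
    return AllocationResult(
        per_segment_sizes=tuple(int(v) for v in n_i),
        weights=tuple(float(w) for w in weights),
        total=m,
    )


def _largest_remainder_with_caps(
    weights: np.ndarray, caps: np.ndarray, total: int
) -> np.ndarray:
    """Hamilton rounding of proportional shares with per-cell caps.

    Capped cells are fixed at their cap and the residual budget is
    re-apportioned among the rest until no cell exceeds its cap.
    """
    n = len(weights)
    out = np.zeros(n, dtype=int)  # holds only pinned (capped) cells
    free = np.ones(n, dtype=bool)
    while True:
        remaining = total - int(out[~free].sum())
        if remaining == 0:
            out[free] = 0
            return out
        w = np.where(free, weights, 0.0)
        wsum = w.sum()
        if wsum == 0:
            # no weight left: fill free cells by available room, low index first
            out[free] = 0
            for i in np.flatnonzero(free):
                take = min(remaining, int(caps[i]))
                out[i] = take
                remaining -= take
                if remaining == 0:
                    break
            return out
        raw = remaining * w / wsum
        base = np.floor(raw).astype(int)
        short = remaining - int(base[free].sum())
        frac = np.where(free, raw - base, -1.0)
        # largest fractional parts win the leftover units; ties -> lower index
        order = np.lexsort((np.arange(n), -frac))
        for i in order[:short]:
            base[i] += 1
        over = free & (base > caps)
        if not over.any():
            out[free] = base[free]
            return out
        # pin overfull segments at their cap, re-apportion the rest from scratch
        out[over] = caps[over]
        free[over] = False


def draw_sample_indices(
    plan: SegmentationPlan,
    sizes: Sequence[int],
    seed,
) -> list[np.ndarray]:
    """Draw sorted, unique time indices within each segment.

    Uniform without replacement inside each segment; fully determined by
    ``seed`` (an int or any ``numpy.random.SeedSequence``-compatible value).
    """
    if len(sizes) != plan.n_segments:
        raise DomainError(
            f"{len(sizes)} sizes given for {plan.n_segments} segments"
        )
    rng = np.random.default_rng(seed)
    picks: list[np.ndarray] = []
    for (start, end), n in zip(plan.boundaries, sizes):
        seg_len = end - start
        if n > seg_len:
            raise OversampleError(
                f"cannot draw {n} points without replacement from a "
                f"{seg_len}-point segment [{start}, {end})"
            )
        idx = rng.choice(seg_len, size=int(n), replace=False) + start
        picks.append(np.sort(idx))
    return picks


def segment_channel_variances(
    dataset: ClassDataset, plan: SegmentationPlan, ddof: int = 1
) -> np.ndarray:
    """Per-segment, per-channel sample variances (unbiased by default)."""
    X = dataset.values_matrix()  # (channels, samples)
    out = np.empty((plan.n_segments, dataset.n_channels))
    for i, (start, end) in enumerate(plan.boundaries):
        out[i] = X[:, start:end].var(axis=1, ddof=ddof)
    return out


def build_sample_set(
    dataset: ClassDataset, config: RunConfig, seed=None
) -> SampleSet:
    """Assemble the per-class sample set under the configured scheme.

    RS: each segment's size comes from the finite-population formula with
    the segment as its own population. OS: the class-level budget comes
    from the whole recording as one population, then optimum allocation
    splits it across segments using per-segment per-channel variances.
    One set of time indices per segment is shared by all channels.
    """
    if seed is None:
        seed = config.seed
    L = dataset.n_samples_per_channel
    plan = segment_signal(L, config.n_segments)
    z, p, e = config.confidence_z, config.proportion_p, config.margin_e

    if config.scheme == "RS":
        sizes = [required_sample_size(sz, z, p, e) for sz in plan.sizes]
    else:  # OS
        m = required_sample_size(L, z, p, e)
        s2 = segment_channel_variances(dataset, plan)
        sizes = list(optimum_allocation(plan.sizes, s2, m).per_segment_sizes)

    indices = draw_sample_indices(plan, sizes, seed)
    flat = np.concatenate(indices) if indices else np.array([], dtype=int)
    values = {r.channel_id: r.samples[flat] for r in dataset.records}
    return SampleSet(
        class_label=dataset.class_label,
        segment_indices=indices,
        channel_ids=[r.channel_id for r in dataset.records],
        values=values,
    )
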