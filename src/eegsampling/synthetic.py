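"""Synthetic multiclass EEG-like corpora for end-to-end testing.

Each channel is an order-1 autoregressive series driven by skewed
innovations whose standard deviation changes from segment to segment, so
recordings are nonstationary in amplitude the way long EEG traces are, and
the optimum-allocation weights differ across segments. Class identity is
controlled through the amplitude scale and the innovation skewness; a
five-class benchmark additionally gives the last class a much larger
amplitude, mimicking the visibly larger voltage swings of ictal (seizure)
activity relative to interictal and surface recordings.

This generator reproduces the corpus *layout* and the statistical contrasts
the pipeline exploits; it makes no attempt at physiological realism
(no spectral peaks or spike-wave morphology).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import skewnorm

from .datatypes import ClassDataset, SignalRecord
from .errors import DomainError
from .sampling import segment_signal


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters of one class.

    ``ar_coefficient`` is the lag-1 autoregression weight (|phi| < 1 keeps
    each segment stationary); ``amplitude_scale`` multiplies the innovation
    SD; ``skew`` is the skew-normal shape parameter of the innovations
    (sample skewness increases monotonically with it); the per-segment
    variance multipliers scale the innovation SD segment by segment.
    """

    label: str
    ar_coefficient: float = 0.5
    amplitude_scale: float = 1.0
    skew: float = 0.0
    segment_variance_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not abs(self.ar_coefficient) < 1:
            raise DomainError("|ar_coefficient| must be < 1")
        if self.amplitude_scale <= 0:
            raise DomainError("amplitude_scale must be positive")
        mults = np.asarray(self.segment_variance_multipliers, dtype=float)
        if mults.size == 0 or not np.all(np.isfinite(mults)) or np.any(mults <= 0):
            raise DomainError("variance multipliers must be finite and positive")


def _skewed_noise(rng: np.random.Generator, a: float, size: int) -> np.ndarray:
    """Standardized skew-normal innovations: mean 0, SD 1, shape ``a``."""
    raw = skewnorm.rvs(a, size=size, random_state=rng)
    mu, sd = skewnorm.stats(a, moments="mv")
    return (raw - float(mu)) / float(np.sqrt(sd))


def generate_class_signal(
    spec: ClassSpec,
    n_channels: int,
    n_samples: int,
    k_segments: int,
    seed,
) -> ClassDataset:
    """Generate one class: AR(1) channels with segment-wise innovation SD."""
    if n_channels < 1:
        raise DomainError("n_channels must be >= 1")
    if n_samples < k_segments or k_segments < 1:
        raise DomainError("need n_samples >= k_segments >= 1")
    plan = segment_signal(n_samples, k_segments)
    mults = np.asarray(spec.segment_variance_multipliers, dtype=float)
    # cycle the multiplier profile if it is shorter than k_segments
    seg_sd = np.empty(n_samples)
    for i, (start, end) in enumerate(plan.boundaries):
        seg_sd[start:end] = spec.amplitude_scale * mults[i % mults.size]
    rng = np.random.default_rng(seed)
    records = []
    for ch in range(n_channels):
        eps = _skewed_noise(rng, spec.skew, n_samples) * seg_sd
        # x_t = phi * x_{t-1} + eps_t
        x = lfilter([1.0], [1.0, -spec.ar_coefficient], eps)
        records.append(
            SignalRecord(
                channel_id=f"{spec.label}{ch + 1:03d}",
                class_label=spec.label,
                samples=x,
            )
        )
    return ClassDataset(class_label=spec.label, records=records)


DEFAULT_LABELS = ("Z", "O", "N", "F", "S")
#: rotated per class so optimum allocation is nontrivial everywhere
_BASE_MULTIPLIERS = (1.0, 1.2, 1.5, 3.0)


def benchmark_specs(n_classes: int, separation: float) -> list[ClassSpec]:
    """Class specs spaced by ``separation`` in amplitude scale and skew.

    ``separation=0`` yields identical specs (a pure null corpus). With five
    classes the last one is 'seizure-like': its amplitude grows several
    times faster with separation than the others'.
    """
    if n_classes < 2:
        raise DomainError("n_classes must be >= 2")
    labels = (
        list(DEFAULT_LABELS)
        if n_classes == 5
        else [f"C{i + 1}" for i in range(n_classes)]
    )
    specs = []
    for c in range(n_classes):
        seizure_like = n_classes == 5 and c == n_classes - 1
        scale_step = 5.0 * separation if seizure_like else separation * c / 2.0
        mults = tuple(np.roll(_BASE_MULTIPLIERS, c))
        specs.append(
            ClassSpec(
                label=labels[c],
                ar_coefficient=0.5,
                amplitude_scale=1.0 + scale_step,
                skew=separation * (c - (n_classes - 1) / 2.0),
                segment_variance_multipliers=mults if separation > 0 else _BASE_MULTIPLIERS,
            )
        )
    return specs


def generate_benchmark(
    n_classes: int,
    n_channels: int,
    n_samples: int,
    seed,
    separation: float = 2.0,
    k_segments: int = 4,
) -> list[ClassDataset]:
    """A full corpus: ``n_classes`` datasets with controllable separation."""
    specs = benchmark_specs(n_classes, separation)
    return [
        generate_class_signal(
            spec,
            n_channels=n_channels,
            n_samples=n_samples,
            k_segments=k_segments,
            seed=(_stable_seed(seed), c),
        )
        for c, spec in enumerate(specs)
    ]


def _stable_seed(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    raise DomainError("seed must be an integer")
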