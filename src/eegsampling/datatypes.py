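"""Core domain types: raw signals, per-class datasets, and run configuration.

A recording corpus is organised by class: each class holds a set of
single-channel amplitude series of identical length (the reference layout is
5 classes x 100 channels x 4097 samples at 173.61 Hz). Amplitudes are treated
as unitless reals after analog-to-digital conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, EmptyInputError, RaggedDataError

DEFAULT_SAMPLING_RATE_HZ = 173.61


@dataclass
class SignalRecord:
    """One channel of one class: an amplitude series plus identity metadata."""

    channel_id: str
    class_label: str
    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise EmptyInputError(
                f"channel {self.channel_id!r}: samples must be nonempty"
            )
        if not np.all(np.isfinite(self.samples)):
            raise DomainError(
                f"channel {self.channel_id!r}: samples must be finite"
            )
        if self.sampling_rate_hz <= 0:
            raise DomainError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class ClassDataset:
    """All channels of one class; every channel has the same sample count."""

    class_label: str
    records: list[SignalRecord]
    n_samples_per_channel: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError(
                f"class {self.class_label!r}: needs at least one record"
            )
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            offenders = sorted(
                (r.channel_id, len(r)) for r in self.records
            )
            raise RaggedDataError(
                f"class {self.class_label!r}: unequal channel lengths {offenders}"
            )
        for r in self.records:
            if r.class_label != self.class_label:
                raise DomainError(
                    f"record {r.channel_id!r} labelled {r.class_label!r}, "
                    f"expected {self.class_label!r}"
                )
        self.n_samples_per_channel = lengths.pop()

    @property
    def n_channels(self) -> int:
        return len(self.records)

    def values_matrix(self) -> np.ndarray:
        """Stack channels into an (n_channels, n_samples) array."""
        return np.stack([r.samples for r in self.records])


SCHEMES = ("RS", "OS")
CLASSIFIERS = ("knn", "mlr", "svm")
NORMALIZATIONS = ("minmax", "zscore", "none")


@dataclass
class RunConfig:
    """Everything one experiment run depends on.

    The sample-size design defaults (z = 2.58 for 99% confidence, assumed
    proportion p = 0.5, margin of error e = 0.01) reproduce the reference
    per-segment sizes for 1024/1025-point segments (965/966) and the
    class-level optimum-allocation total (3288 from a 4097-point recording).
    """

    n_segments: int = 4
    scheme: str = "RS"
    confidence_z: float = 2.58
    proportion_p: float = 0.5
    margin_e: float = 0.01
    classifier: str = "knn"
    n_folds: int = 10
    n_repetitions: int = 20
    seed: int = 0
    # classifier hyperparameters
    knn_k: Optional[int] = None  # None -> automatic selection in 1..knn_k_max
    knn_k_max: int = 30
    ridge_lambda: float = 1e-8
    svm_c: float = 1.0
    svm_gamma: Optional[float] = None  # None -> 1 / n_features
    mlr_tolerance: float = 1e-6
    mlr_max_iter: int = 500
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise DomainError("n_segments must be >= 1")
        if self.scheme not in SCHEMES:
            raise DomainError(f"scheme must be one of {SCHEMES}")
        if self.classifier not in CLASSIFIERS:
            raise DomainError(f"classifier must be one of {CLASSIFIERS}")
        if self.normalization not in NORMALIZATIONS:
            raise DomainError(f"normalization must be one of {NORMALIZATIONS}")
        if self.n_folds < 2:
            raise DomainError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise DomainError("n_repetitions must be >= 1")
        if self.confidence_z <= 0:
            raise DomainError("confidence_z must be positive")
        if not 0 < self.proportion_p < 1:
            raise DomainError("proportion_p must lie in (0, 1)")
        if self.margin_e <= 0:
            raise DomainError("margin_e must be positive")
        if self.ridge_lambda < 0:
            raise DomainError("ridge_lambda must be >= 0")
        if self.svm_c <= 0:
            raise DomainError("svm_c must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
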