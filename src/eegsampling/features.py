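"""The 11 statistical features summarising a channel's sampled amplitudes.

Each channel's sample set is condensed into mean, median, mode, first and
third quartiles, interquartile range, standard deviation, skewness, excess
kurtosis, minimum, and maximum. The five-number summary (min, Q1, median,
Q3, max) captures location and spread robustly; skewness and kurtosis
describe the asymmetry and tail weight of the amplitude distribution; the
mode is the peak of an equal-width histogram.

Conventions (the estimators are not uniquely determined by the feature
names, so they are fixed here):

* quantiles: linear interpolation between order statistics at rank (n-1)q;
* standard deviation: n-1 denominator;
* skewness g1 = m3 / m2^(3/2) and EXCESS kurtosis g2 = m4 / m2^2 - 3 with
  biased central moments m_r = (1/n) sum (x - mean)^r, so a normal
  distribution has kurtosis 0; a constant series has g1 = g2 = 0;
* mode: midpoint of the fullest of ceil(sqrt(n)) equal-width bins over
  [min, max]; ties go to the lowest bin; a zero-width range returns the
  common value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, LabelCollisionError
from .sampling import SampleSet

FEATURE_NAMES = (
    "X_Mean",
    "X_Me",
    "X_Mo",
    "X_Q1",
    "X_Q3",
    "X_IQR",
    "X_SD",
    "X_beta1",
    "X_beta2",
    "X_Min",
    "X_Max",
)

#: canonical on-disk / in-memory column order for a feature matrix
MATRIX_COLUMNS = ("class", "channel") + FEATURE_NAMES


@dataclass(frozen=True)
class FeatureVector:
    X_Mean: float
    X_Me: float
    X_Mo: float
    X_Q1: float
    X_Q3: float
    X_IQR: float
    X_SD: float
    X_beta1: float
    X_beta2: float
    X_Min: float
    X_Max: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def _validate(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("values must be nonempty")
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    return x


def quantile(values: Sequence[float], q: float) -> float:
    """Quantile by linear interpolation at rank h = (n-1) * q."""
    x = _validate(values)
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(x, q, method="linear"))


def mode_estimate(values: Sequence[float]) -> float:
    """Histogram-peak mode: fullest of ceil(sqrt(n)) equal-width bins."""
    x = _validate(values)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo
    n_bins = math.ceil(math.sqrt(x.size))
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))  # argmax takes the lowest bin on ties
    return float((edges[peak] + edges[peak + 1]) / 2.0)


def compute_features(values: Sequence[float]) -> FeatureVector:
    """All 11 statistics of one sampled amplitude sequence."""
    x = _validate(values)
    n = x.size
    xmin, xmax = float(x.min()), float(x.max())
    if xmin == xmax:  # constant series: every location feature is the value
        c = xmin
        return FeatureVector(
            X_Mean=c, X_Me=c, X_Mo=c, X_Q1=c, X_Q3=c, X_IQR=0.0,
            X_SD=0.0, X_beta1=0.0, X_beta2=0.0, X_Min=c, X_Max=c,
        )
    # summation rounding can push the mean a ulp outside [min, max]
    mean = min(max(float(x.mean()), xmin), xmax)
    centered = x - mean
    m2 = float(np.mean(centered**2))
    if m2 > 0.0:
        g1 = float(np.mean(centered**3)) / m2**1.5
        g2 = float(np.mean(centered**4)) / m2**2 - 3.0
    else:
        g1 = g2 = 0.0
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    q1 = quantile(x, 0.25)
    q3 = quantile(x, 0.75)
    return FeatureVector(
        X_Mean=mean,
        X_Me=quantile(x, 0.5),
        X_Mo=mode_estimate(x),
        X_Q1=q1,
        X_Q3=q3,
        X_IQR=q3 - q1,
        X_SD=sd,
        X_beta1=g1,
        X_beta2=g2,
        X_Min=xmin,
        X_Max=xmax,
    )


def build_feature_matrix(sample_sets: Sequence[SampleSet]) -> pd.DataFrame:
    """One labelled feature row per (class, channel).

    Rows appear in class-then-channel order; each row summarises the
    channel's full sampled value sequence. The reference corpus (5 classes
    x 100 channels) yields a 500 x 11 matrix.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for ss in sample_sets:
        for ch in ss.channel_ids:
            key = (ss.class_label, ch)
            if key in seen:
                raise LabelCollisionError(
                    f"duplicate (class, channel) label {key}"
                )
            seen.add(key)
            fv = compute_features(ss.values[ch])
            rows.append((ss.class_label, ch) + fv.as_tuple())
    return pd.DataFrame(rows, columns=list(MATRIX_COLUMNS))
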