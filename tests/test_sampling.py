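import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegsampling import (
    RunConfig,
    build_sample_set,
    draw_sample_indices,
    optimum_allocation,
    required_sample_size,
    segment_signal,
)
from eegsampling.errors import (
    DegenerateAllocationError,
    DomainError,
    InfeasibleAllocationError,
    InvalidPartitionError,
    OversampleError,
)


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,k,sizes",
        [
            (4097, 4, (1024, 1024, 1024, 1025)),
            (8, 4, (2, 2, 2, 2)),
            (10, 4, (2, 2, 2, 4)),  # remainder goes to the last segment
            (5, 1, (5,)),
            (5, 5, (1, 1, 1, 1, 1)),
        ],
    )
    def test_sizes(self, length, k, sizes):
        plan = segment_signal(length, k)
        assert plan.sizes == sizes

    @pytest.mark.parametrize("length,k", [(4, 5), (4, 0), (4, -1)])
    def test_invalid_partition(self, length, k):
        with pytest.raises(InvalidPartitionError):
            segment_signal(length, k)

    @given(L=st.integers(1, 10_000), k=st.integers(1, 50))
    def test_partition_covers_signal(self, L, k):
        if k > L:
            return
        plan = segment_signal(L, k)
        assert plan.boundaries[0][0] == 0
        assert plan.boundaries[-1][1] == L
        for (s0, e0), (s1, e1) in zip(plan.boundaries, plan.boundaries[1:]):
            assert e0 == s1
        assert all(sz == L // k for sz in plan.sizes[:-1])


class TestRequiredSampleSize:
    @pytest.mark.parametrize(
        "popu,z,p,e,expected",
        [
            (1024, 2.58, 0.5, 0.01, 965),
            (1025, 2.58, 0.5, 0.01, 966),
            (4097, 2.58, 0.5, 0.01, 3288),
            (1, 2.58, 0.5, 0.01, 1),  # correction forces n = Popu
            (100, 1.96, 0.5, 0.5, 4),  # SS=3.8416 -> 3.736, rounded up
        ],
    )
    def test_values(self, popu, z, p, e, expected):
        assert required_sample_size(popu, z, p, e) == expected

    def test_rejects_empty_population(self):
        with pytest.raises(DomainError):
            required_sample_size(0, 2.58, 0.5, 0.01)

    @given(
        popu=st.integers(1, 100_000),
        z=st.floats(0.1, 5),
        p=st.floats(0.01, 0.99),
        e=st.floats(0.001, 0.9),
    )
    @settings(max_examples=200)
    def test_bounds_and_monotonicity(self, popu, z, p, e):
        n = required_sample_size(popu, z, p, e)
        ss = z**2 * p * (1 - p) / e**2
        assert 1 <= n <= popu
        assert n <= math.ceil(ss) or n == popu
        if ss >= popu:
            # a sample size demand at or beyond the population takes it all
            assert n == popu or n == math.ceil(ss / (1 + (ss - 1) / popu))
        # nondecreasing in population size
        assert required_sample_size(popu + 1, z, p, e) >= n
        # nonincreasing in the error margin
        assert required_sample_size(popu, z, p, min(e * 2, 0.99)) <= n


def brute_force_shares(sizes, s2, m):
    """Direct evaluation of the allocation formula, no vectorization."""
    weights = []
    for i, N in enumerate(sizes):
        total = 0.0
        for v in s2[i]:
            total += v
        weights.append(N * math.sqrt(total))
    wsum = sum(weights)
    return [m * w / wsum for w in weights]


class TestOptimumAllocation:
    @pytest.mark.parametrize(
        "sizes,s2,m,expected",
        [
            ((100, 100), [[1.0], [1.0]], 40, (20, 20)),
            ((100, 200), [[4.0], [1.0]], 10, (5, 5)),
            ((10, 30), [[1.0], [1.0]], 8, (2, 6)),
        ],
    )
    def test_examples(self, sizes, s2, m, expected):
        res = optimum_allocation(sizes, np.array(s2), m)
        assert res.per_segment_sizes == expected
        assert res.total == m

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DegenerateAllocationError):
            optimum_allocation((10, 10), np.zeros((2, 3)), 5)

    def test_infeasible_budget_rejected(self):
        with pytest.raises(InfeasibleAllocationError):
            optimum_allocation((5, 5), np.ones((2, 1)), 11)

    def test_caps_respected_with_redistribution(self):
        # huge variance in a tiny segment: its share is capped at N_i
        res = optimum_allocation((3, 100), np.array([[1e6], [1.0]]), 50)
        assert res.per_segment_sizes[0] == 3
        assert sum(res.per_segment_sizes) == 50

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 6))
            p = int(rng.integers(1, 4))
            sizes = rng.integers(5, 200, size=k)
            s2 = rng.uniform(0, 10, size=(k, p))
            if not np.any(sizes * np.sqrt(s2.sum(axis=1)) > 0):
                continue
            m = int(rng.integers(1, sizes.sum() + 1))
            res = optimum_allocation(sizes, s2, m)
            shares = brute_force_shares(sizes, s2, m)
            np.testing.assert_allclose(
                np.array(res.weights) / sum(res.weights) * m, shares, atol=1e-12
            )
            assert sum(res.per_segment_sizes) == m
            assert all(
                0 <= n <= N for n, N in zip(res.per_segment_sizes, sizes)
            )
            # integerization stays within 1 of the (uncapped) raw share
            if all(s <= N for s, N in zip(shares, sizes)):
                for n, r in zip(res.per_segment_sizes, shares):
                    assert abs(n - r) < 1 + 1e-9

    def test_scale_invariance_of_variances(self, rng):
        sizes = (50, 80, 120)
        s2 = rng.uniform(0.1, 5.0, size=(3, 4))
        a = optimum_allocation(sizes, s2, 60).per_segment_sizes
        b = optimum_allocation(sizes, 17.3 * s2, 60).per_segment_sizes
        assert a == b


class TestDrawSampleIndices:
    def test_exhaustive_sample_returns_all(self):
        plan = segment_signal(5, 1)
        (idx,) = draw_sample_indices(plan, [5], seed=0)
        assert idx.tolist() == [0, 1, 2, 3, 4]

    def test_seed_determinism(self):
        plan = segment_signal(1000, 1)
        a = draw_sample_indices(plan, [10], seed=42)
        b = draw_sample_indices(plan, [10], seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_oversample_rejected(self):
        plan = segment_signal(10, 2)
        with pytest.raises(OversampleError):
            draw_sample_indices(plan, [6, 3], seed=0)

    def test_unique_sorted_in_range(self, rng):
        for _ in range(1000):
            start = int(rng.integers(0, 500))
            length = int(rng.integers(1, 200))
            plan = segment_signal(start + length, 1)
            n = int(rng.integers(1, length + 1))
            (idx,) = draw_sample_indices(plan, [n], seed=int(rng.integers(2**31)))
            assert len(idx) == n
            assert len(np.unique(idx)) == n
            assert np.all(np.diff(idx) > 0)
            assert idx.min() >= 0 and idx.max() < start + length

    def test_indices_within_their_segments(self, rng):
        plan = segment_signal(200, 4)
        picks = draw_sample_indices(plan, [10, 10, 10, 10], seed=3)
        for (s, e), idx in zip(plan.boundaries, picks):
            assert np.all((idx >= s) & (idx < e))


class TestBuildSampleSet:
    def test_rs_reference_length(self, small_corpus):
        # 4097-sample signals, 4 segments, default design -> 965*3 + 966
        from eegsampling import ClassSpec, generate_class_signal

        ds = generate_class_signal(
            ClassSpec(label="Z"), n_channels=2, n_samples=4097, k_segments=4, seed=0
        )
        cfg = RunConfig(scheme="RS", n_segments=4)
        ss = build_sample_set(ds, cfg)
        assert ss.per_segment_sizes == (965, 965, 965, 966)
        assert ss.n_sampled == 3861

    def test_os_reference_length(self):
        from eegsampling import ClassSpec, generate_class_signal

        ds = generate_class_signal(
            ClassSpec(label="Z"), n_channels=2, n_samples=4097, k_segments=4, seed=0
        )
        cfg = RunConfig(scheme="OS", n_segments=4)
        ss = build_sample_set(ds, cfg)
        assert ss.n_sampled == 3288

    def test_equal_variance_allocation_near_proportional(self):
        # identical innovation variance everywhere -> allocation ~ N_i
        from eegsampling import ClassSpec, generate_class_signal

        ds = generate_class_signal(
            ClassSpec(
                label="Z",
                ar_coefficient=0.0,
                segment_variance_multipliers=(1.0,),
            ),
            n_channels=5,
            n_samples=4000,
            k_segments=4,
            seed=1,
        )
        cfg = RunConfig(scheme="OS", n_segments=4)
        ss = build_sample_set(ds, cfg, seed=2)
        sizes = np.array(ss.per_segment_sizes)
        proportional = ss.n_sampled / 4
        assert np.all(np.abs(sizes - proportional) < 0.03 * proportional)

    def test_indices_shared_across_channels(self, tiny_dataset, fast_config):
        cfg = RunConfig(scheme="RS", n_segments=2, margin_e=0.2)
        ss = build_sample_set(tiny_dataset, cfg, seed=4)
        flat = np.concatenate(ss.segment_indices)
        for rec in tiny_dataset.records:
            np.testing.assert_array_equal(
                ss.values[rec.channel_id], rec.samples[flat]
            )
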