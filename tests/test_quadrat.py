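"""Quadrat counting, pooled dispersion statistics, KL divergence,
fractions and the radial distribution function."""

import numpy as np
import pytest

from swimquad import (
    ArenaSpec,
    PartitionSpec,
    PlacementConfig,
    PointFrame,
    area_fraction,
    count_quadrats,
    kl_divergence,
    pooled_histogram,
    radial_distribution,
    simulate_frames,
    vmr_curve,
    volume_fraction,
)


def brute_force_counts(points, a, m):
    """Independent oracle: explicit point-in-rectangle checks with the
    right/upper boundary rule."""
    grid = np.zeros((m, m), dtype=int)
    w = a / m
    for x, y in points:
        for i in range(m):
            for j in range(m):
                lo_x, hi_x = i * w, (i + 1) * w
                lo_y, hi_y = j * w, (j + 1) * w
                in_x = (lo_x <= x < hi_x) or (i == m - 1 and x == a)
                in_y = (lo_y <= y < hi_y) or (j == m - 1 and y == a)
                if in_x and in_y:
                    grid[i, j] += 1
    return grid


class TestCounting:
    def test_single_point_at_origin(self, arena):
        grid = count_quadrats(PointFrame(0, [[0.0, 0.0]]), arena, PartitionSpec(4))
        assert grid[0, 0] == 1 and grid.sum() == 1

    def test_boundary_point_goes_right(self, arena):
        # a center exactly on an internal boundary belongs to the
        # right/upper compartment
        x = arena.a / 4
        grid = count_quadrats(PointFrame(0, [[x, 10.0]]), arena, PartitionSpec(4))
        assert grid[1, 0] == 1

    def test_upper_boundary_and_window_edge(self, arena):
        pts = [[10.0, arena.a / 2], [arena.a, arena.a]]
        grid = count_quadrats(PointFrame(0, pts), arena, PartitionSpec(2))
        assert grid[0, 1] == 1  # on internal y-boundary -> upper row
        assert grid[1, 1] == 1  # exactly at the window corner -> clamped

    def test_matches_brute_force_oracle(self, arena):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, arena.a, size=(45, 2))
        frame = PointFrame(0, pts)
        for m in (3, 4, 7):
            np.testing.assert_array_equal(
                count_quadrats(frame, arena, PartitionSpec(m)),
                brute_force_counts(pts, arena.a, m),
            )

    def test_count_conservation_and_nesting(self, arena):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.uniform(0, arena.a, size=(rng.integers(0, 200), 2))
            frame = PointFrame(0, pts)
            g2 = count_quadrats(frame, arena, PartitionSpec(2))
            g4 = count_quadrats(frame, arena, PartitionSpec(4))
            assert g2.sum() == g4.sum() == len(pts)
            # m=2 counts equal block sums of m=4 counts
            blocks = g4.reshape(2, 2, 2, 2).sum(axis=(1, 3))
            np.testing.assert_array_equal(g2, blocks)

    def test_point_outside_window_rejected(self, arena):
        with pytest.raises(ValueError, match="outside"):
            count_quadrats(PointFrame(3, [[-1.0, 5.0]]), arena, PartitionSpec(2))


class TestPooledHistogram:
    def test_constant_frames_single_section(self, arena):
        rng = np.random.default_rng(0)
        frames = [PointFrame(i, rng.uniform(0, arena.a, (185, 2))) for i in range(50)]
        h = pooled_histogram(frames, arena, PartitionSpec(1))
        assert h.mean == 185.0 and h.variance == 0.0
        assert h.counts_per_bin == {185: 50}

    def test_two_frame_hand_arithmetic(self, arena):
        f1 = PointFrame(0, [[1.0, 1.0]])
        f2 = PointFrame(1, [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        h = pooled_histogram([f1, f2], arena, PartitionSpec(1))
        assert h.mean == 2.0 and h.variance == 2.0 and h.vmr == 1.0

    def test_empty_frame_list_rejected(self, arena):
        with pytest.raises(ValueError):
            pooled_histogram([], arena, PartitionSpec(2))

    def test_vmr_invariant_under_frame_relabeling(self, arena):
        rng = np.random.default_rng(5)
        frames = [PointFrame(i, rng.uniform(0, arena.a, (40, 2))) for i in range(10)]
        h1 = pooled_histogram(frames, arena, PartitionSpec(3))
        h2 = pooled_histogram(frames[::-1], arena, PartitionSpec(3))
        assert h1.vmr == h2.vmr and h1.counts_per_bin == h2.counts_per_bin


class TestVmrCurve:
    def test_binomial_null_tracks_closed_form(self, arena):
        frames = simulate_frames(PlacementConfig(n_total=185, d=0.0, n_frames=900, seed=0))
        curve = vmr_curve(frames, arena, range(2, 11))
        for _, row in curve.iterrows():
            assert row["vmr"] == pytest.approx(1 - 1 / row["N"], abs=0.03)

    def test_repeated_frame_reproduces_population_vmr(self, arena):
        # pooling a frozen frame 900 times leaves the count multiset
        # unchanged, so the pooled (ddof=1) variance converges to the
        # frame's population variance
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, arena.a, (60, 2))
        many = vmr_curve([PointFrame(i, pts) for i in range(900)], arena, [2, 4])
        for _, row in many.iterrows():
            m = int(row["m"])
            counts = count_quadrats(PointFrame(0, pts), arena, PartitionSpec(m)).ravel()
            pop_vmr = counts.var(ddof=0) / counts.mean()
            assert row["vmr"] == pytest.approx(pop_vmr, rel=1e-3)
        np.testing.assert_allclose(many["mean"], [15.0, 3.75])

    def test_empty_m_list_rejected(self, arena):
        with pytest.raises(ValueError):
            vmr_curve([PointFrame(0, [[1, 1]])], arena, [])
        with pytest.raises(ValueError):
            vmr_curve([PointFrame(0, [[1, 1]])], arena, [0])


class TestKL:
    def test_zero_for_identical_distributions(self, arena):
        h = pooled_histogram(
            [PointFrame(0, [[1.0, 1.0]]), PointFrame(1, [[1.0, 1.0], [600.0, 600.0]])],
            arena, PartitionSpec(1),
        )
        # empirical {1: 0.5, 2: 0.5}
        assert kl_divergence(h, {1: 0.5, 2: 0.5}) == pytest.approx(0.0, abs=1e-15)

    def test_single_term_closed_form(self, arena):
        h = pooled_histogram([PointFrame(0, np.empty((0, 2)))], arena, PartitionSpec(1))
        assert kl_divergence(h, {0: 0.5, 1: 0.5}) == pytest.approx(np.log(2), rel=1e-12)

    def test_missing_model_mass_is_infinite(self, arena):
        h = pooled_histogram([PointFrame(0, [[1.0, 1.0]])], arena, PartitionSpec(1))
        with pytest.warns(UserWarning, match="infinite"):
            assert kl_divergence(h, {0: 1.0}) == np.inf

    def test_unnormalized_model_rejected(self, arena):
        h = pooled_histogram([PointFrame(0, [[1.0, 1.0]])], arena, PartitionSpec(1))
        with pytest.raises(ValueError, match="sums to"):
            kl_divergence(h, {1: 0.5})


class TestFractions:
    def test_area_fraction_standard_density(self, arena):
        assert area_fraction(185.18, arena) == pytest.approx(0.011, abs=5e-4)

    def test_area_fraction_low_density(self, arena):
        mean_cells = 80.04 * 1.3225  # number density per mm^2 times window mm^2
        assert area_fraction(mean_cells, arena) == pytest.approx(0.006, abs=5e-4)

    def test_zero_cells(self, arena):
        assert area_fraction(0.0, arena) == 0.0

    def test_volume_fraction_formula(self, arena):
        # n (4/3) pi r^3 / (a^2 t) at unit-checkable numbers
        got = volume_fraction(185.18, arena, thickness=10.0)
        expect = 185.18 * (4 / 3) * np.pi * 125.0 / (1150.0**2 * 10.0)
        assert got == pytest.approx(expect, rel=1e-12)
        with pytest.raises(ValueError):
            volume_fraction(10.0, arena, thickness=0.0)


class TestRdf:
    def test_two_points_single_bin(self, arena):
        frames = [PointFrame(0, [[500.0, 500.0], [550.0, 500.0]])]
        table = radial_distribution(frames, arena, r_max=100.0, bin_width=5.0)
        nz = table[table["g"] > 0]
        assert len(nz) == 1
        assert nz["r"].iloc[0] == pytest.approx(52.5)  # bin [50, 55)

    def test_csr_baseline_is_flat(self, arena):
        frames = simulate_frames(PlacementConfig(n_total=185, d=0.0, n_frames=100, seed=4))
        table = radial_distribution(frames, arena, r_max=200.0, bin_width=5.0)
        sel = table[(table["r"] > 20) & (table["r"] < 200)]
        assert sel["g"].mean() == pytest.approx(1.0, abs=0.05)

    def test_hard_core_gap(self, arena):
        frames = simulate_frames(PlacementConfig(n_total=185, d=10.0, n_frames=40, seed=4))
        table = radial_distribution(frames, arena, r_max=100.0, bin_width=2.0)
        below = table[table["r"] + 1.0 <= 10.0]  # bins entirely below d
        assert (below["g"] == 0).all()

    def test_degenerate_frames_warn(self, arena):
        frames = [PointFrame(0, [[1.0, 1.0]]),
                  PointFrame(1, [[100.0, 100.0], [200.0, 200.0]])]
        with pytest.warns(UserWarning, match="skipped"):
            radial_distribution(frames, arena, r_max=200.0, bin_width=10.0)

    def test_parameter_validation(self, arena):
        with pytest.raises(ValueError):
            radial_distribution([PointFrame(0, [[1, 1]])], arena, r_max=600.0, bin_width=5.0)
        with pytest.raises(ValueError):
            radial_distribution([PointFrame(0, [[1, 1]])], arena, r_max=100.0, bin_width=0.0)
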