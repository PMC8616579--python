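from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import synaptodetect as sd
from synaptodetect.quantify import SessionStats, session_stats_from_synapses


def _syn(voxels, id_=1):
    arr = np.array(sorted(voxels), dtype=float)
    return sd.Synapse3D(id_, frozenset(voxels), tuple(arr.mean(axis=0)), 0.0)


class TestSynapseIntensity:
    def test_uniform_footprint(self):
        vol = sd.ImageVolume(np.full((2, 5, 5), 2.0))
        syn = _syn({(0, 1, 1), (0, 1, 2), (1, 1, 1), (1, 2, 2)} | {(0, y, 4) for y in range(5)})
        assert len(syn.voxels) == 9  # one voxel listed twice collapses
        assert sd.synapse_intensity(vol, syn) == pytest.approx(18.0)

    def test_zero_volume(self):
        vol = sd.ImageVolume(np.zeros((2, 4, 4)))
        assert sd.synapse_intensity(vol, _syn({(0, 1, 1)})) == 0.0

    def test_matches_per_voxel_loop(self):
        rng = np.random.default_rng(6)
        data = rng.random((3, 10, 10))
        vox = {(int(z), int(y), int(x)) for z, y, x in rng.integers(0, 3, size=(20, 3)) * [1, 3, 3]}
        syn = _syn(vox)
        expect = sum(data[v] for v in vox)
        assert sd.synapse_intensity(sd.ImageVolume(data), syn) == pytest.approx(expect)

    def test_additive_over_disjoint_partition(self):
        rng = np.random.default_rng(7)
        data = rng.random((2, 8, 8))
        vol = sd.ImageVolume(data)
        a = {(0, 1, 1), (0, 1, 2)}
        b = {(1, 4, 4), (1, 5, 5), (1, 6, 6)}
        total = sd.synapse_intensity(vol, _syn(a | b))
        assert total == pytest.approx(
            sd.synapse_intensity(vol, _syn(a)) + sd.synapse_intensity(vol, _syn(b))
        )

    def test_out_of_bounds_voxel_error(self):
        vol = sd.ImageVolume(np.zeros((2, 4, 4)))
        with pytest.raises(IndexError):
            sd.synapse_intensity(vol, _syn({(5, 0, 0)}))


class TestSynapseMaxArea:
    def test_max_over_planes(self):
        vox = {(0, y, x) for y in range(5) for x in range(6)}  # 30 px
        vox |= {(1, y, x) for y in range(5) for x in range(9)}  # 45 px
        vox |= {(2, y, x) for y in range(4) for x in range(5)}  # 20 px
        assert sd.synapse_max_area(_syn(vox)) == 45.0

    def test_single_plane(self):
        assert sd.synapse_max_area(_syn({(0, 0, 0), (0, 0, 1)})) == 2.0

    def test_physical_units(self):
        vox = {(0, y, x) for y in range(5) for x in range(9)}
        px, um2 = sd.synapse_max_area(_syn(vox), voxel_size=(1.0, 0.096, 0.096))
        assert px == 45.0
        assert um2 == pytest.approx(45 * 0.096**2)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            sd.synapse_max_area(sd.Synapse3D(1, frozenset(), (0, 0, 0), 0.0))


class TestNormalizeToBaseline:
    def test_single_baseline_mean_one(self):
        s = SessionStats(0, [2.0, 4.0, 6.0])
        out = sd.normalize_to_baseline([s], [0])
        assert np.mean(out[0].intensity_values) == pytest.approx(1.0)

    def test_doubled_session_normalises_to_two(self):
        s0 = SessionStats(0, [1.0, 2.0, 3.0])
        s1 = SessionStats(1, [2.0, 4.0, 6.0])
        out = sd.normalize_to_baseline([s0, s1], [0])
        assert out[1].mean_intensity == pytest.approx(2.0)

    def test_pooled_unequal_baselines_use_weighted_mean(self):
        s0 = SessionStats(0, [1.0])
        s1 = SessionStats(1, [4.0, 4.0, 4.0])
        s2 = SessionStats(2, [13.0])
        out = sd.normalize_to_baseline([s0, s1, s2], [0, 1])
        pooled_mean = (1.0 + 4.0 * 3) / 4
        assert out[2].intensity_values[0] == pytest.approx(13.0 / pooled_mean)

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError):
            sd.normalize_to_baseline([SessionStats(0, [0.0])], [0])


def _enumeration_p(a, b):
    """Two-sided exact p by counting extreme arrangements, written from the
    pairwise-comparison definition of U (independent of the implementation)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    idx = range(len(pooled))

    def u_of(sel):
        sel_vals = [pooled[i] for i in sel]
        rest = [pooled[i] for i in idx if i not in sel]
        u = 0.0
        for x in sel_vals:
            for y in rest:
                u += (x > y) + 0.5 * (x == y)
        return u

    mu = n_a * (len(pooled) - n_a) / 2.0
    u_obs = u_of(set(range(n_a)))
    extreme = total = 0
    for sel in combinations(idx, n_a):
        total += 1
        if abs(u_of(set(sel)) - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return u_obs, extreme / total


class TestMannWhitney:
    def test_textbook_separated_samples(self):
        u, p = sd.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_single_tied_pair(self):
        u, p = sd.mann_whitney_u([1.0], [1.0])
        assert p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(5), rng.random(7)
        u_ab, p_ab = sd.mann_whitney_u(a, b)
        u_ba, p_ba = sd.mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    @pytest.mark.parametrize("n_a,n_b", [(na, nb) for na in range(1, 7) for nb in range(na, 7)])
    def test_exact_p_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(100 * n_a + n_b)
        # half the draws include ties via rounding
        a = np.round(rng.random(n_a), 1)
        b = np.round(rng.random(n_b), 1)
        u, p = sd.mann_whitney_u(a, b)
        u_expect, p_expect = _enumeration_p(a, b)
        assert u == pytest.approx(u_expect)
        assert p == pytest.approx(p_expect)

    def test_large_sample_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.4, 1, 80)
        u, p = sd.mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            sd.mann_whitney_u([], [1.0])


class TestAlignment:
    def test_self_alignment_is_zero(self):
        rng = np.random.default_rng(2)
        vol = sd.ImageVolume(rng.random((5, 30, 30)))
        assert sd.align_translation(vol, vol, (2, 5, 5)) == (0, 0, 0)

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(3)
        ref = sd.ImageVolume(rng.random((6, 40, 40)))
        moving = sd.apply_translation(ref, (1, 3, -2))
        shift = sd.align_translation(ref, moving, (2, 5, 5))
        assert shift == (-1, -3, 2)
        realigned = sd.apply_translation(moving, shift)
        inner = (slice(2, 4), slice(8, 32), slice(8, 32))
        np.testing.assert_allclose(realigned.voxels[inner], ref.voxels[inner])

    def test_pure_noise_deterministic(self):
        rng = np.random.default_rng(4)
        a = sd.ImageVolume(rng.random((4, 20, 20)))
        b = sd.ImageVolume(rng.random((4, 20, 20)))
        s1 = sd.align_translation(a, b, (1, 3, 3))
        s2 = sd.align_translation(a, b, (1, 3, 3))
        assert s1 == s2
        assert all(abs(v) <= m for v, m in zip(s1, (1, 3, 3)))

    def test_shape_mismatch_error(self):
        a = sd.ImageVolume(np.zeros((2, 8, 8)))
        b = sd.ImageVolume(np.zeros((3, 8, 8)))
        with pytest.raises(ValueError):
            sd.align_translation(a, b, (1, 2, 2))

    def test_excessive_max_shift_error(self):
        a = sd.ImageVolume(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError):
            sd.align_translation(a, a, (2, 2, 2))


class TestLongitudinal:
    def test_replicated_sessions_stable(self, family):
        from synaptodetect.synthetic import GeneratorParams, generate_longitudinal

        base = sd.generate_volume((12, 128, 128), 12, GeneratorParams(amp_sigma_log=0.0), seed=3)
        sessions = generate_longitudinal(base, n_sessions=2, seed=5)
        stats, report = sd.longitudinal_report(
            [s.volume for s in sessions],
            sd.DetectionConfig(rng_seed=3),
            baseline_ids=[0],
            max_shift=(1, 4, 4),
            family=family,
        )
        assert stats[0].mean_intensity == pytest.approx(1.0)
        assert abs(stats[1].mean_intensity - 1.0) < 0.1
        assert report["p_values"][1] > 0.05
        assert report["shifts"][1] == (0, 0, 0)

    def test_needs_two_sessions(self):
        with pytest.raises(ValueError):
            sd.longitudinal_report([sd.ImageVolume(np.zeros((2, 8, 8)))])

    def test_session_stats_counts(self, small_gt, small_detection):
        synapses, _ = small_detection
        stats = session_stats_from_synapses(0, small_gt.volume, synapses)
        assert stats.n_synapses == len(synapses)
        assert len(stats.intensity_values) == stats.n_synapses
        assert stats.mean_area_px > 0
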