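import warnings

import numpy as np
import pytest

from latticectx.averaging import (
    AlignmentRound,
    AlignmentSchedule,
    apply_symmetry,
    bin_volume,
    extract_subtomograms,
    fsc,
    fsc_shell_counts,
    remove_duplicates,
    resolution_at,
    rotated_wedge_mask,
    run_tube_average,
    seed_tube_poses,
    soft_mask,
    split_half_sets,
    threshold_cc,
    weighted_average,
)
from latticectx.geometry import EulerTriplet, UnitAnnotation
from latticectx.io_formats import DensityVolume
from latticectx.matching import bandpass_filter
from latticectx.synthetic import (
    WedgeSpec,
    build_tube,
    default_templates,
    render_density,
    render_unit_template,
    wedge_mask,
)


def unit_at(pos, cc=1.0):
    return UnitAnnotation(position=np.asarray(pos, float),
                          euler=EulerTriplet(0, 0, 0), cc=cc)


class TestStackHandling:
    def test_extraction_centers_unit(self):
        g = np.zeros((32, 32, 32), np.float32)
        g[10, 20, 14] = 7.0
        vol = DensityVolume(g, 4.0)
        stack = extract_subtomograms(vol, [unit_at([10, 20, 14])], 9)
        assert len(stack) == 1
        cube, _ = stack[0]
        assert cube[4, 4, 4] == 7.0

    def test_out_of_bounds_skipped_with_warning(self):
        vol = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        with pytest.warns(UserWarning):
            stack = extract_subtomograms(vol, [unit_at([1, 8, 8])], 9)
        assert stack == []

    def test_empty_table_empty_stack(self):
        vol = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        assert extract_subtomograms(vol, [], 9) == []

    def test_binning_halves_coordinates(self):
        rng = np.random.default_rng(0)
        vol = DensityVolume(rng.normal(size=(32, 32, 32)), 4.0)
        binned = bin_volume(vol, 2)
        assert binned.grid.shape == (16, 16, 16)
        assert binned.voxel_size == 8.0
        # a feature at voxel p sits at p/2 after binning: physical position
        # p * 4 A == (p/2) * 8 A
        assert 16 * binned.voxel_size == 32 * vol.voxel_size


class TestFiltering:
    def test_greedy_duplicate_removal_keeps_higher_cc(self):
        a = unit_at([0, 0, 0], cc=0.8)
        b = unit_at([0.5, 0, 0], cc=0.9)  # 2 A away at 4 A voxels
        out = remove_duplicates([a, b], cutoff=20.0, voxel_size=4.0)
        assert len(out) == 1
        assert out[0].cc == 0.9

    def test_oversampled_tube_dedup_recovers_unit_count(self, tube_graph):
        seeds = seed_tube_poses(tube_graph, oversample=4.0)
        assert len(seeds) >= 2 * len(tube_graph)
        # snap each seed to its nearest true site (ideal alignment), then
        # dedup must leave one survivor per site
        from scipy.spatial import cKDTree

        T = tube_graph.positions()
        tree = cKDTree(T)
        rng = np.random.default_rng(0)
        snapped = []
        for s in seeds:
            _, i = tree.query(s.position)
            v = s.copy()
            v.position = T[i] + rng.normal(0, 0.25, 3)
            v.cc = float(rng.uniform(0.5, 1.0))
            snapped.append(v)
        out = remove_duplicates(snapped, cutoff=40.0, voxel_size=1.0)
        assert abs(len(out) - len(tube_graph)) <= 0.02 * len(tube_graph)

    def test_cc_threshold_can_empty_table(self):
        units = [unit_at([0, 0, 0], cc=0.1), unit_at([9, 0, 0], cc=0.2)]
        assert threshold_cc(units, 0.5) == []
        assert len(threshold_cc(units, 0.15)) == 1


class TestSymmetry:
    def test_c1_identity(self):
        rng = np.random.default_rng(0)
        v = DensityVolume(rng.normal(size=(17, 17, 17)), 4.0)
        assert np.array_equal(apply_symmetry(v, 1).grid, v.grid)

    def test_projection_property(self):
        rng = np.random.default_rng(1)
        v = DensityVolume(rng.normal(size=(33, 33, 33)), 4.0)
        s = apply_symmetry(v, 2)
        assert np.abs(apply_symmetry(s, 2).grid - s.grid).max() < 1e-6

    def test_symmetrized_map_invariant_under_group_rotation(self):
        rng = np.random.default_rng(2)
        v = DensityVolume(rng.normal(size=(33, 33, 33)), 4.0)
        s = apply_symmetry(v, 4)
        from latticectx.matching import rotate_volume

        rot = rotate_volume(s.grid.astype(np.float64),
                            EulerTriplet(0, 0, 90), order=1)
        assert np.abs(rot - s.grid).max() < 1e-6


class TestWeightedAverage:
    def test_full_coverage_equals_plain_mean(self):
        rng = np.random.default_rng(0)
        cubes = [rng.normal(size=(16, 16, 16)) for _ in range(3)]
        full = np.ones_like(np.fft.rfftn(cubes[0]).real, dtype=bool)
        avg, cov = weighted_average(cubes, [full] * 3, coverage_floor=1.0)
        assert cov == 1.0
        assert np.allclose(avg, np.mean(cubes, axis=0), atol=1e-10)

    def test_complementary_wedges_recover_signal(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(32, 32, 32))
        m1 = wedge_mask((32, 32, 32), WedgeSpec("x", -90, 0), rfft=True)
        m2 = ~m1
        avg, cov = weighted_average([g, g], [m1, m2])
        assert cov == 1.0
        assert np.abs(avg - g).max() < 1e-10

    def test_single_subtomogram_inside_its_wedge(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=(32, 32, 32))
        m = wedge_mask((32, 32, 32), WedgeSpec("x", -60, 60), rfft=True)
        avg, cov = weighted_average([g], [m])
        import scipy.fft

        ft = scipy.fft.rfftn(avg)
        assert np.abs(ft[~m]).max() < 1e-8
        assert cov < 1.0

    def test_rotated_wedge_mask_identity_rotation(self):
        m0 = wedge_mask((16, 16, 16), WedgeSpec("x", -60, 60), rfft=True)
        mr = rotated_wedge_mask((16, 16, 16), WedgeSpec("x", -60, 60),
                                np.eye(3))
        assert np.array_equal(m0, mr)


class TestFSC:
    def test_map_with_itself_is_one(self):
        rng = np.random.default_rng(0)
        v = DensityVolume(rng.normal(size=(48, 48, 48)), 4.0)
        curve = fsc(v, v)
        assert np.allclose(curve.values, 1.0, atol=1e-9)
        res, flagged = resolution_at(curve)
        assert flagged  # no crossing: Nyquist-limited

    def test_independent_noise_in_null_band(self):
        rng = np.random.default_rng(3)
        a = DensityVolume(rng.normal(size=(64, 64, 64)), 4.0)
        b = DensityVolume(rng.normal(size=(64, 64, 64)), 4.0)
        curve = fsc(a, b)
        counts = fsc_shell_counts((64, 64, 64))
        ok = np.abs(curve.values) < 3.0 / np.sqrt(counts)
        assert np.mean(ok) >= 0.95

    def test_bandlimited_signal_crosses_at_its_limit(self):
        # common signal strictly band-limited at 20 A plus independent
        # noise per half-map: the 0.143 crossing sits at the band limit
        import scipy.fft

        rng = np.random.default_rng(4)
        raw = rng.normal(size=(64, 64, 64))
        fx = np.fft.fftfreq(64)[:, None, None]
        fy = np.fft.fftfreq(64)[None, :, None]
        fz = np.fft.rfftfreq(64)[None, None, :]
        k = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2) / 4.0
        hard = (k <= 1.0 / 20.0)  # strict band limit at 20 A
        s = scipy.fft.irfftn(scipy.fft.rfftn(raw) * hard, s=raw.shape)
        s /= s.std()
        h1 = DensityVolume(s + 0.25 * rng.normal(size=s.shape), 4.0)
        h2 = DensityVolume(s + 0.25 * rng.normal(size=s.shape), 4.0)
        res, flagged = resolution_at(fsc(h1, h2))
        assert not flagged
        assert 18.0 <= res <= 22.0

    def test_shape_mismatch_rejected(self):
        a = DensityVolume(np.zeros((16, 16, 16)), 4.0)
        b = DensityVolume(np.zeros((16, 16, 8)), 4.0)
        with pytest.raises(ValueError):
            fsc(a, b)


class TestHalfSets:
    def test_split_is_balanced_partition(self):
        graphs = [build_tube(10, n, 80.0) for n in (3, 4, 5, 6)]
        h1, h2 = split_half_sets(graphs)
        assert len(h1) + len(h2) == 4
        n1 = sum(len(g) for g in h1)
        n2 = sum(len(g) for g in h2)
        assert abs(n1 - n2) <= 10
        ids = [id(g) for g in h1 + h2]
        assert len(ids) == len(set(ids))


@pytest.fixture(scope="module")
def tube_average_result():
    g = build_tube(10, 5, 80.0)
    vol, truth = render_density(g, 4.0, (128, 128, 96))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_tube_average(vol, truth, box=25, symmetry=2,
                               oversample=4.0)
    return res, truth


def _masked_corr(a, b):
    # mask-weighted Pearson correlation (a flat map scores 0)
    w = soft_mask(a.shape, 0.35).ravel()
    x, y = a.ravel(), b.ravel()
    x = x - (w * x).sum() / w.sum()
    y = y - (w * y).sum() / w.sum()
    cov = (w * x * y).sum()
    return float(cov / np.sqrt((w * x * x).sum() * (w * y * y).sum()))


def _render_local_scene(truth, box, voxel):
    """Analytic oracle: central hexamer plus its ring, canonical frame."""
    from latticectx.synthetic import _splat

    center = next(i for i in range(len(truth))
                  if len(truth.neighbors(i)) == 6)
    u = truth.units[center]
    Ra = u.rotation
    grid = np.zeros((box, box, box), dtype=np.float64)
    bc = np.full(3, box // 2, dtype=float)
    tmpls = default_templates()
    for j in [center] + truth.neighbors(center):
        v = truth.units[j]
        rel = Ra.T @ (v.position - u.position)
        Rrel = Ra.T @ v.rotation
        t = tmpls[v.unit_type]
        _splat(grid, (t.points @ Rrel.T) / voxel + bc + rel, t.weights,
               t.sigma / voxel)
    return grid


class TestTubePipeline:
    def test_average_matches_hexamer_density(self, tube_average_result):
        from scipy import ndimage

        res, truth = tube_average_result
        # C2-symmetrized analytic local scene is the converged solution;
        # reference-based alignment leaves one gauge freedom (a common
        # offset along the unit normal = canonical z), so the comparison
        # maximizes over that single shift
        scene = DensityVolume(_render_local_scene(truth, 25, 4.0), 4.0)
        scene = apply_symmetry(scene, 2)
        tmpl = render_unit_template(default_templates()["hexamer_C2"],
                                    4.0, 25)

        def gauge_corr(target):
            vals = []
            for dz in np.arange(-2.0, 2.01, 0.25):
                shifted = ndimage.shift(target.astype(np.float64),
                                        (0, 0, dz), order=1)
                vals.append(_masked_corr(res["average"].grid, shifted))
            return max(vals)

        assert gauge_corr(scene.grid) > 0.95
        # the central unit itself dominates the masked region
        assert gauge_corr(tmpl.grid) > 0.85

    def test_survivor_count_near_truth(self, tube_average_result):
        res, truth = tube_average_result
        assert abs(len(res["units"]) - len(truth.units)) \
            <= max(1, 0.02 * len(truth.units))

    def test_shuffled_poses_give_featureless_average(self, tube_average_result):
        from latticectx.averaging import _average_stack

        res, truth = tube_average_result
        rng = np.random.default_rng(0)
        g = build_tube(10, 5, 80.0)
        vol, truth2 = render_density(g, 4.0, (128, 128, 96))
        shuffled = []
        for u in truth2.units:
            v = u.copy()
            v.position = rng.uniform(30, 66, 3)  # interior, off-lattice
            v.euler = EulerTriplet(*rng.uniform(0, 360, 3))
            shuffled.append(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            avg = _average_stack(vol, shuffled, 25, 2)
        tmpl = render_unit_template(default_templates()["hexamer_C2"],
                                    4.0, 25)
        assert _masked_corr(avg.grid, tmpl.grid) < 0.3

    def test_schedule_validates_binning_order(self):
        with pytest.raises(ValueError):
            AlignmentSchedule([AlignmentRound(binning=1),
                               AlignmentRound(binning=2)])
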