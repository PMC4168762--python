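"""Streamline propagation, stopping rules, pruning, probability maps."""

import numpy as np
import pytest

from mirrortract import phantom as ph
from mirrortract import tracking as tk
from mirrortract.peaks import OrientationField
from mirrortract.volumes import GridSpec, MaskVolume


def uniform_field(grid, direction, fa=0.8, where=None):
    f = OrientationField.empty(grid)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    sel = np.ones(grid.shape, bool) if where is None else where
    f.peaks[sel, 0] = d
    f.n_peaks[sel] = 1
    f.anisotropy.data[sel] = fa
    return f


def full_brain(grid, inset=0):
    data = np.ones(grid.shape, bool)
    if inset:
        data[:] = False
        data[inset:-inset, inset:-inset, inset:-inset] = True
    return MaskVolume(grid, data)


def reference_integrator(field, brain, seed, direction, step=0.05,
                         max_turn_deg=60.0, fa_min=0.2, max_len=200.0):
    """Independent fine-step tracker: plain python loop re-implementing the
    propagation rules from their definition (oracle for the main kernel)."""
    grid = field.grid
    shape = np.array(grid.shape)
    halves = []
    for sgn in (1.0, -1.0):
        p = np.asarray(seed, dtype=float).copy()
        d = sgn * np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        pts = [p.copy()]
        for _ in range(int(max_len / step / 2)):
            v = np.floor(grid.world_to_voxel(p) + 0.5).astype(int)
            if np.any(v < 0) or np.any(v >= shape) \
                    or not brain.data[v[0], v[1], v[2]]:
                break
            if field.anisotropy.data[v[0], v[1], v[2]] < fa_min \
                    or field.n_peaks[v[0], v[1], v[2]] == 0:
                break
            pk = field.peaks[v[0], v[1], v[2],
                             :field.n_peaks[v[0], v[1], v[2]]]
            dots = pk @ d
            q = int(np.argmax(np.abs(dots)))
            nd = np.sign(dots[q]) * pk[q] if dots[q] != 0 else pk[q]
            if nd @ d < np.cos(np.deg2rad(max_turn_deg)):
                break
            p = p + step * nd
            d = nd
            pts.append(p.copy())
        halves.append(np.array(pts))
    return np.vstack([halves[1][:0:-1], halves[0]])


class TestPropagate:
    def test_uniform_slab_yields_straight_spanning_line(self):
        g = GridSpec.create((40, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        brain = full_brain(g)
        s = tk.propagate(f, brain, (20.0, 10.0, 10.0), (1, 0, 0))
        assert s.termination_reasons == ("out_of_brain", "out_of_brain")
        assert np.allclose(s.points[:, 1:], [10.0, 10.0])
        assert s.length_mm() >= 38.0
        steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.allclose(steps, steps[0], atol=1e-6)

    def test_sharp_turn_above_60_degrees_stops(self):
        g = GridSpec.create((40, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        # beyond x=20 the field bends by 61 degrees across the boundary
        bent = np.zeros(g.shape, bool)
        bent[20:] = True
        a = np.deg2rad(61.0)
        f.peaks[bent, 0] = [np.cos(a), np.sin(a), 0.0]
        s = tk.propagate(f, full_brain(g), (10.0, 10.0, 10.0), (1, 0, 0))
        assert "sharp_turn" in s.termination_reasons
        assert s.points[:, 0].max() < 21.0

    def test_turn_of_59_degrees_continues(self):
        g = GridSpec.create((40, 40, 20))
        f = uniform_field(g, (1, 0, 0))
        bent = np.zeros(g.shape, bool)
        bent[20:] = True
        a = np.deg2rad(59.0)
        f.peaks[bent, 0] = [np.cos(a), np.sin(a), 0.0]
        s = tk.propagate(f, full_brain(g), (10.0, 10.0, 10.0), (1, 0, 0))
        assert "sharp_turn" not in s.termination_reasons

    def test_subthreshold_anisotropy_stops(self):
        g = GridSpec.create((40, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        f.anisotropy.data[25:] = 0.19
        s = tk.propagate(f, full_brain(g), (10.0, 10.0, 10.0), (1, 0, 0))
        assert s.termination_reasons[1] == "low_anisotropy"
        assert 24.0 <= s.points[-1][0] <= 26.0

    def test_seed_without_peak_degenerate(self):
        g = GridSpec.create((10, 10, 10))
        f = OrientationField.empty(g)
        s = tk.propagate(f, full_brain(g), (5.0, 5.0, 5.0), (1, 0, 0))
        assert len(s.points) == 1
        assert s.termination_reasons == ("low_anisotropy", "low_anisotropy")

    def test_curved_field_endpoints_match_fine_step_oracle(self):
        grid = ph.default_grid()
        theta = np.linspace(0, np.pi / 2, 40)
        pts = np.column_stack([np.full_like(theta, 16.0),
                               32.0 - 20.0 * np.cos(theta),
                               12.0 + 20.0 * np.sin(theta)])
        b = ph.synth_bundle(grid, ph.BundleSpec(pts, radius=2.5))
        field = ph.paint_bundles(grid, [b])
        brain = full_brain(grid, inset=2)
        rng = np.random.default_rng(11)
        # interior seeds: rim voxels terminate on a knife edge where any
        # integrator's exit point is ill-conditioned
        centers = grid.voxel_to_world(b.voxels.astype(float))
        dist = np.linalg.norm(
            centers[:, None, :] - pts[None, ::4, :], axis=2).min(axis=1)
        interior = np.nonzero(dist <= 1.3)[0]
        picks = rng.choice(interior, size=8, replace=False)
        for i in picks:
            seed = grid.voxel_to_world(b.voxels[i].astype(float))
            d = b.peak_dirs[i]
            fast = tk.propagate(field, brain, seed, d)
            ref = reference_integrator(field, brain, seed, d)
            for e_fast, e_ref in ((fast.points[0], ref[0]),
                                  (fast.points[-1], ref[-1])):
                assert np.linalg.norm(e_fast - e_ref) <= 1.0 + 1e-6


class TestSeeding:
    def test_one_launch_per_voxel_peak_pair(self):
        g = GridSpec.create((20, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        sel = np.zeros(g.shape, bool)
        sel[5, 5:15, 10] = True  # 10 seed voxels
        f.peaks[sel, 1] = [0.0, 1.0, 0.0]  # second peak everywhere in seed
        f.n_peaks[sel] = 2
        t = tk.track_from_mask(f, full_brain(g), MaskVolume(g, sel))
        assert t.provenance["launched"] == 20

    def test_seed_mask_without_peaks_yields_empty(self):
        g = GridSpec.create((10, 10, 10))
        f = OrientationField.empty(g)
        sel = np.zeros(g.shape, bool)
        sel[4, 4, 4] = True
        t = tk.track_from_mask(f, full_brain(g), MaskVolume(g, sel))
        assert len(t) == 0

    def test_deterministic_repeatability_bitwise(self, null_case):
        a = tk.track_from_mask(null_case.field, null_case.brain_mask,
                               null_case.lesion_mask)
        b = tk.track_from_mask(null_case.field, null_case.brain_mask,
                               null_case.lesion_mask)
        assert len(a) == len(b)
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa.points, sb.points)

    def test_whole_brain_count_matches_launch_enumeration(self, null_case):
        t = tk.track_whole_brain(null_case.field, null_case.brain_mask)
        launches = int(null_case.field.n_peaks[
            null_case.brain_mask.data].sum())
        assert t.provenance["launched"] == launches
        assert len(t) == launches - t.provenance["discarded_short"]

    def test_whole_brain_superset_of_mask_seeded(self, null_case):
        whole = tk.track_whole_brain(null_case.field, null_case.brain_mask)
        sub = tk.track_from_mask(null_case.field, null_case.brain_mask,
                                 null_case.lesion_mask)
        assert len(whole) >= len(sub)


class TestPruning:
    @pytest.fixture()
    def straight_tracto(self):
        g = GridSpec.create((40, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        t = tk.track_whole_brain(f, full_brain(g, inset=2))
        # terminal points sit one voxel beyond the brain boundary (x=1, 38)
        roi_a = MaskVolume(g, np.zeros(g.shape, bool))
        roi_a.data[:2] = True
        roi_b = MaskVolume(g, np.zeros(g.shape, bool))
        roi_b.data[38:] = True
        return g, t, roi_a, roi_b

    def test_empty_roi_prunes_everything(self, straight_tracto):
        g, t, roi_a, _ = straight_tracto
        empty = MaskVolume(g, np.zeros(g.shape, bool))
        assert len(tk.prune_by_endpoints(t, roi_a, empty)) == 0

    def test_retained_matches_bruteforce_endpoint_test(self, straight_tracto):
        g, t, roi_a, roi_b = straight_tracto
        pruned = tk.prune_by_endpoints(t, roi_a, roi_b)
        expect = 0
        for s in t.streamlines:
            va, vb = tk.voxel_of(g, s.points[[0, -1]])
            ina = lambda m, v: bool(np.all(v >= 0)
                                    and np.all(v < np.array(g.shape))
                                    and m.data[v[0], v[1], v[2]])
            if (ina(roi_a, va) and ina(roi_b, vb)) or \
                    (ina(roi_a, vb) and ina(roi_b, va)):
                expect += 1
        assert len(pruned) == expect > 0

    def test_pruning_idempotent(self, straight_tracto):
        g, t, roi_a, roi_b = straight_tracto
        once = tk.prune_by_endpoints(t, roi_a, roi_b)
        twice = tk.prune_by_endpoints(once, roi_a, roi_b)
        assert len(twice) == len(once)


class TestConnectionProbability:
    def test_single_streamline_unit_probability(self):
        g = GridSpec.create((10, 10, 10))
        pts = np.column_stack([np.linspace(1, 8, 15),
                               np.full(15, 5.0), np.full(15, 5.0)])
        t = tk.Tractogram([tk.Streamline(pts, (1, 5, 5), ("none", "none"))],
                          {})
        m = tk.connection_probability_map(t, g)
        assert m.data.max() == 1.0
        assert set(np.unique(m.data)) == {0.0, 1.0}

    def test_two_disjoint_streamlines_half_each(self):
        g = GridSpec.create((10, 10, 10))
        mk = lambda y: tk.Streamline(
            np.column_stack([np.linspace(1, 8, 15), np.full(15, float(y)),
                             np.full(15, 5.0)]), (1, y, 5), ("none", "none"))
        m = tk.connection_probability_map(
            tk.Tractogram([mk(2), mk(7)], {}), g)
        assert set(np.unique(m.data)) == {0.0, 0.5}

    def test_map_matches_bruteforce_visitation(self, null_case):
        t = tk.track_from_mask(null_case.field, null_case.brain_mask,
                               null_case.lesion_mask)
        g = null_case.field.grid
        m = tk.connection_probability_map(t, g)
        counts = np.zeros(g.shape)
        for s in t.streamlines:
            vis = set(map(tuple, tk.voxel_of(g, s.points)))
            for v in vis:
                if all(0 <= v[d] < g.shape[d] for d in range(3)):
                    counts[v] += 1
        assert np.allclose(m.data, counts / len(t))

    def test_empty_tractogram_rejected(self):
        g = GridSpec.create((4, 4, 4))
        with pytest.raises(ValueError):
            tk.connection_probability_map(tk.Tractogram([], {}), g)


class TestProbabilistic:
    def test_launch_count_is_iterations_times_deterministic(self):
        g = GridSpec.create((20, 10, 10))
        sel = np.zeros(g.shape, bool)
        sel[8:12, 4:6, 4:6] = True
        f = uniform_field(g, (1, 0, 0), where=sel)
        brain = full_brain(g)
        det = tk.track_whole_brain(f, brain)
        prob = tk.probabilistic_tracts(f, brain, iterations=7, rng_seed=0)
        assert prob.provenance["launched"] == 7 * det.provenance["launched"]

    def test_seed_reproducibility(self):
        g = GridSpec.create((20, 10, 10))
        sel = np.zeros(g.shape, bool)
        sel[8:12, 4:6, 4:6] = True
        f = uniform_field(g, (1, 0, 0), where=sel)
        brain = full_brain(g)
        a = tk.probabilistic_tracts(f, brain, iterations=3, rng_seed=42)
        b = tk.probabilistic_tracts(f, brain, iterations=3, rng_seed=42)
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa.points, sb.points)

    def test_large_kappa_converges_to_deterministic(self):
        g = GridSpec.create((40, 20, 20))
        f = uniform_field(g, (1, 0, 0))
        brain = full_brain(g)
        params = tk.TrackingParams(kappa=1e6)
        det = tk.propagate(f, brain, (20.0, 10.0, 10.0), (1, 0, 0))
        prob = tk.probabilistic_tracts(f, brain, params, iterations=1,
                                       rng_seed=1)
        match = [s for s in prob.streamlines if s.seed_index == (20, 10, 10)]
        assert match
        gap = min(np.linalg.norm(match[0].points[-1] - det.points[-1]),
                  np.linalg.norm(match[0].points[0] - det.points[-1]))
        assert gap <= 1.0

    def test_invalid_kappa_rejected(self, null_case):
        params = tk.TrackingParams(kappa=0.0)
        with pytest.raises(ValueError):
            tk.probabilistic_tracts(null_case.field, null_case.brain_mask,
                                    params, iterations=1)


class TestTrkIO:
    def test_round_trip(self, tmp_path, null_case):
        t = tk.track_from_mask(null_case.field, null_case.brain_mask,
                               null_case.lesion_mask)
        assert len(t) > 0
        path = tmp_path / "tracts.trk"
        tk.save_trk(t, null_case.field.grid, path)
        back = tk.load_trk(path)
        assert len(back) == len(t)
        assert np.allclose(back[0].points, t.streamlines[0].points,
                           atol=1e-4)
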