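import numpy as np
import pytest

from hippoquant import (Blob, Calibration, CellTrack, DetectionParams,
                        classify_cells, detect_debris, extract_blobs,
                        link_layers, preprocess, refine_mask, run_detector,
                        threshold_layer)

from conftest import ISO_1UM, ISO_HALF, disk_mask
from helpers_oracles import (boundary_of, brute_feret, exhaustive_link,
                             random_blob_layers)


def _stub_blob(feret_um: float, layer: int = 0, label: int = 1) -> Blob:
    return Blob(layer_index=layer, label=label, coords=np.array([[1, 1]]),
                contour=np.array([[1.0, 1.0]]), area_um2=1.0,
                feret_um=feret_um, centroid_um=(1.0, 1.0),
                touches_border=False, lin=np.array([0]), shape=(10, 10))


def _row_blob(layer: int, col0: int, col1: int, cal: Calibration,
              shape=(10, 200), row: int = 5) -> Blob:
    """A 1-px-tall horizontal bar blob, cols [col0, col1]."""
    mask = np.zeros(shape, dtype=bool)
    mask[row, col0:col1 + 1] = True
    (blob,) = extract_blobs(mask, cal, exclude_border=False, layer_index=layer)
    return blob


class TestParams:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(min_overlap_frac=0.0)
        with pytest.raises(ValueError):
            DetectionParams(min_layer_support=1)
        with pytest.raises(ValueError):
            DetectionParams(debris_diag_um=(2.5, 5.0))  # != cell threshold
        with pytest.raises(ValueError):
            DetectionParams(blur_sigma_um=-0.5)

    def test_params_echo_roundtrip(self):
        d = DetectionParams().to_dict()
        assert d["min_overlap_frac"] == 0.6
        assert d["debris_diag_um"] == [2.5, 6.5]


class TestPreprocess:
    def test_constant_raster_unchanged(self):
        layer = np.full((32, 32), 7.5)
        out = preprocess(layer, ISO_1UM, DetectionParams())
        assert np.allclose(out, layer)

    def test_single_bright_pixel_mass_conserved(self):
        layer = np.zeros((41, 41))
        layer[20, 20] = 100.0
        out = preprocess(layer, ISO_1UM, DetectionParams())
        assert out.sum() == pytest.approx(100.0, rel=1e-6)
        assert out.max() < 100.0

    def test_white_noise_variance_reduced(self):
        params = DetectionParams()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            layer = rng.normal(50, 5, size=(64, 64))
            assert preprocess(layer, ISO_1UM, params).var() < layer.var()

    def test_sigma_converted_per_axis(self):
        # anisotropic pixels: an impulse must spread farther (in px) along
        # the finer-sampled axis
        cal = Calibration(um_per_px_x=1.0, um_per_px_y=0.25, z_step_um=5.0)
        layer = np.zeros((81, 81))
        layer[40, 40] = 1.0
        out = preprocess(layer, cal, DetectionParams(blur_sigma_um=2.0))
        row_profile = out[:, 40]
        col_profile = out[40, :]
        row_width = (row_profile > row_profile.max() / 2).sum()
        col_width = (col_profile > col_profile.max() / 2).sum()
        assert row_width > 2 * col_width


class TestThreshold:
    def test_constant_raster_gives_empty_mask(self):
        layer = np.full((64, 64), 42.0)
        assert not threshold_layer(layer, ISO_1UM, DetectionParams()).any()

    def test_disk_on_flat_background_recovered_within_2px(self):
        truth = disk_mask((80, 80), 40, 40, 8)
        layer = np.where(truth, 60.0, 10.0)
        params = DetectionParams()
        mask = threshold_layer(preprocess(layer, ISO_1UM, params), ISO_1UM, params)
        from scipy import ndimage as ndi
        inner = ndi.binary_erosion(truth, iterations=2)
        outer = ndi.binary_dilation(truth, iterations=2)
        assert (mask & inner).sum() == inner.sum()   # mask covers eroded disk
        assert not (mask & ~outer).any()             # mask inside dilated disk

    def test_adaptive_beats_global_threshold_on_gradient(self):
        """A background ramp steeper than the object contrast defeats any
        single global threshold, while the local-mean rule still segments
        the disk."""
        h, w = 120, 200
        ramp = np.linspace(0, 60, w)[np.newaxis, :] * np.ones((h, 1))
        truth = disk_mask((h, w), 60, 100, 8)
        layer = ramp + np.where(truth, 12.0, 0.0)
        params = DetectionParams()
        adaptive = threshold_layer(preprocess(layer, ISO_1UM, params),
                                   ISO_1UM, params)
        inter = (adaptive & truth).sum()
        union = (adaptive | truth).sum()
        assert inter / union > 0.5

        def f1(mask):
            tp = (mask & truth).sum()
            return 2 * tp / (mask.sum() + truth.sum()) if mask.sum() else 0.0

        best_global = max(f1(layer > t) for t in np.linspace(0, 75, 151))
        assert best_global < 0.5
        assert f1(adaptive) > best_global

    def test_mask_invariant_to_intensity_shift(self):
        rng = np.random.default_rng(0)
        layer = rng.random((50, 50)) * 30
        params = DetectionParams()
        m1 = threshold_layer(layer, ISO_1UM, params)
        m2 = threshold_layer(layer + 123.4, ISO_1UM, params)
        assert np.array_equal(m1, m2)

    def test_block_below_3px_rejected(self):
        coarse = Calibration(um_per_px_x=50.0, um_per_px_y=50.0, z_step_um=5.0)
        with pytest.raises(ValueError, match="block"):
            threshold_layer(np.zeros((10, 10)), coarse, DetectionParams())


class TestRefineMask:
    def test_empty_mask_stays_empty(self):
        out = refine_mask(np.zeros((20, 20), dtype=bool), ISO_1UM,
                          DetectionParams())
        assert not out.any()

    def test_single_pixel_speckle_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        out = refine_mask(mask, ISO_HALF, DetectionParams())  # 0.8 um > 1 px
        assert not out.any()

    def test_idempotent_on_random_masks(self):
        params = DetectionParams()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mask = rng.random((48, 48)) > 0.6
            once = refine_mask(mask, ISO_HALF, params)
            assert np.array_equal(refine_mask(once, ISO_HALF, params), once)


class TestExtractBlobs:
    def test_known_disk_measurements(self):
        # 10 um disk at 0.5 um/px: radius 10 px
        mask = disk_mask((60, 60), 30, 30, 10)
        (blob,) = extract_blobs(mask, ISO_HALF)
        assert blob.feret_um == pytest.approx(10.0, abs=2 * 0.5)
        assert blob.area_um2 == pytest.approx(np.pi * 25.0, rel=0.10)
        assert not blob.touches_border

    def test_two_disjoint_disks_give_two_blobs(self):
        mask = disk_mask((60, 90), 30, 22, 8) | disk_mask((60, 90), 30, 65, 8)
        assert len(extract_blobs(mask, ISO_1UM)) == 2

    def test_border_blobs_flagged_and_droppable(self):
        mask = disk_mask((40, 40), 0, 20, 6)
        assert extract_blobs(mask, ISO_1UM, exclude_border=True) == []
        (blob,) = extract_blobs(mask, ISO_1UM, exclude_border=False)
        assert blob.touches_border

    def test_feret_and_area_match_bruteforce_oracle(self):
        cal = Calibration(um_per_px_x=0.7, um_per_px_y=0.4, z_step_um=5.0)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            mask = np.zeros((48, 48), dtype=bool)
            for _ in range(rng.integers(1, 5)):
                mask |= disk_mask((48, 48), rng.uniform(8, 40),
                                  rng.uniform(8, 40), rng.uniform(2, 6))
            for blob in extract_blobs(mask, cal, exclude_border=False):
                boundary = boundary_of(blob.coords, blob.shape)
                assert blob.feret_um == pytest.approx(
                    brute_feret(boundary, cal.um_per_px_y, cal.um_per_px_x))
                assert blob.area_um2 == pytest.approx(
                    len(blob.coords) * cal.px_area_um2)


class TestLinking:
    def test_identical_masks_link_into_full_span_tracks(self):
        mask = disk_mask((50, 50), 25, 25, 7) | disk_mask((50, 50), 12, 38, 4)
        layers = {k: extract_blobs(mask, ISO_1UM, layer_index=k) for k in range(3)}
        tracks = link_layers(layers, DetectionParams())
        assert len(tracks) == 2
        assert all(t.layer_span == 3 for t in tracks)

    def test_overlap_below_threshold_never_links(self):
        cal = Calibration(um_per_px_x=0.1, um_per_px_y=0.1, z_step_um=5.0)
        a = _row_blob(0, 0, 99, cal)     # 100 px bar
        b = _row_blob(1, 41, 140, cal)   # 59/100 = 0.59 overlap
        tracks = link_layers({0: [a], 1: [b]}, DetectionParams())
        assert all(t.layer_span == 1 for t in tracks)

    def test_overlap_at_61_percent_links(self):
        cal = Calibration(um_per_px_x=0.1, um_per_px_y=0.1, z_step_um=5.0)
        a = _row_blob(0, 0, 99, cal)
        b = _row_blob(1, 39, 138, cal)   # 61/100 = 0.61 overlap
        tracks = link_layers({0: [a], 1: [b]}, DetectionParams())
        assert [t.layer_span for t in tracks] == [2]

    def test_duplicate_blob_identity_rejected(self):
        blob = _stub_blob(5.0)
        with pytest.raises(ValueError, match="duplicate"):
            link_layers({0: [blob], 1: [blob]}, DetectionParams())

    def test_each_blob_in_exactly_one_track(self):
        rng = np.random.default_rng(1)
        layers = random_blob_layers(rng)
        tracks = link_layers(layers, DetectionParams())
        seen = [id(b) for t in tracks for b in t.blobs]
        assert len(seen) == len(set(seen)) == sum(len(v) for v in layers.values())

    def test_matches_exhaustive_oracle_on_random_scenes(self):
        params = DetectionParams()
        for seed in range(30):
            rng = np.random.default_rng(seed)
            layers = random_blob_layers(rng)
            got = {tuple(id(b) for b in t.blobs)
                   for t in link_layers(layers, params)}
            assert got == exhaustive_link(layers, params.min_overlap_frac)


class TestClassification:
    def test_feret_exactly_at_threshold_is_not_a_cell(self):
        track = CellTrack(blobs=[_stub_blob(6.5, 0), _stub_blob(6.5, 1, 2)])
        classify_cells([track], DetectionParams())
        assert track.is_cell is False

    def test_feret_just_above_threshold_with_support_is_a_cell(self):
        track = CellTrack(blobs=[_stub_blob(6.6, 0), _stub_blob(6.2, 1, 2)])
        classify_cells([track], DetectionParams())
        assert track.is_cell is True

    def test_single_layer_large_blob_is_not_a_cell(self):
        track = CellTrack(blobs=[_stub_blob(12.0, 0)])
        classify_cells([track], DetectionParams())
        assert track.is_cell is False

    def test_sixpointsix_micron_bar_at_61_percent_overlap_is_a_cell(self):
        cal = Calibration(um_per_px_x=0.1, um_per_px_y=0.1, z_step_um=5.0)
        a = _row_blob(0, 0, 66, cal)    # 67 px -> Feret 6.6 um
        b = _row_blob(1, 26, 92, cal)   # 41/67 = 0.612 overlap
        assert a.feret_um == pytest.approx(6.6)
        tracks = classify_cells(link_layers({0: [a], 1: [b]},
                                            DetectionParams()),
                                DetectionParams())
        assert [t.is_cell for t in tracks] == [True]

    def test_sixpointfive_micron_bar_is_never_a_cell(self):
        cal = Calibration(um_per_px_x=0.1, um_per_px_y=0.1, z_step_um=5.0)
        a = _row_blob(0, 0, 65, cal)    # 66 px -> Feret exactly 6.5 um
        b = _row_blob(1, 0, 65, cal)    # full overlap
        assert a.feret_um == pytest.approx(6.5)
        tracks = classify_cells(link_layers({0: [a], 1: [b]},
                                            DetectionParams()),
                                DetectionParams())
        assert [t.is_cell for t in tracks] == [False]


class TestDebris:
    def _fragment_and_tracks(self, cal=ISO_HALF):
        mask = disk_mask((60, 60), 30, 30, 4)  # 4 um fragment at 0.5 um/px
        (blob,) = extract_blobs(mask, cal)
        tracks = classify_cells(link_layers({0: [blob]}, DetectionParams()),
                                DetectionParams())
        return blob, tracks

    def test_fully_ringed_fragment_accepted(self):
        blob, tracks = self._fragment_and_tracks()
        gfap = np.ones((60, 60), dtype=bool)
        (particle,) = detect_debris([blob], [gfap], tracks,
                                    DetectionParams(), ISO_HALF)
        assert particle.accepted and particle.encirclement == pytest.approx(1.0)

    def test_fragment_without_any_gfap_rejected(self):
        blob, tracks = self._fragment_and_tracks()
        gfap = np.zeros((60, 60), dtype=bool)
        (particle,) = detect_debris([blob], [gfap], tracks,
                                    DetectionParams(), ISO_HALF)
        assert not particle.accepted and particle.encirclement == 0.0

    def test_cell_member_blobs_are_never_debris(self):
        # a track that IS a cell: its blobs are excluded from candidacy even
        # if individual cross-sections fall in the debris size range
        cal = ISO_HALF
        big = disk_mask((80, 80), 40, 40, 8)     # 8 um cross-section
        small = disk_mask((80, 80), 40, 40, 5)   # 5 um cross-section above it
        (a,) = extract_blobs(big, cal, layer_index=0)
        (b,) = extract_blobs(small, cal, layer_index=1)
        tracks = classify_cells(link_layers({0: [a], 1: [b]},
                                            DetectionParams()),
                                DetectionParams())
        assert tracks[0].is_cell
        gfap = np.ones((80, 80), dtype=bool)
        particles = detect_debris([a, b], [gfap, gfap], tracks,
                                  DetectionParams(), cal)
        assert particles == []

    def test_mismatched_mask_dimensions_rejected(self):
        blob, tracks = self._fragment_and_tracks()
        with pytest.raises(ValueError, match="dimensions"):
            detect_debris([blob], [np.zeros((10, 10), dtype=bool)], tracks,
                          DetectionParams(), ISO_HALF)


class TestFullPipeline:
    def test_empty_scene_yields_zero_counts(self):
        from hippoquant import SceneSpec, generate_scene
        spec = SceneSpec(n_neurons=0, n_astrocytes=0, n_microglia=0,
                         n_debris=0, n_debris_decoys=0, seed=0)
        stack, _ = generate_scene(spec)
        res = run_detector(stack, "NeuN", DetectionParams(), gfap_channel="GFAP")
        assert res.n_cells == 0 and res.n_debris == 0

    def test_deterministic_for_fixed_inputs(self, small_scene):
        stack, _ = small_scene
        r1 = run_detector(stack, "NeuN", DetectionParams(), gfap_channel="GFAP")
        r2 = run_detector(stack, "NeuN", DetectionParams(), gfap_channel="GFAP")
        assert r1.n_cells == r2.n_cells and r1.n_debris == r2.n_debris
        assert np.array_equal(r1.masks, r2.masks)

    def test_counts_invariant_to_intensity_shift_and_scale(self, small_scene,
                                                           small_result):
        from hippoquant import ZStack
        stack, _ = small_scene
        shifted = ZStack(stack.data + 37.0, stack.channels, stack.calibration)
        res_shift = run_detector(shifted, "NeuN", DetectionParams(),
                                 gfap_channel="GFAP")
        assert res_shift.n_cells == small_result.n_cells
        assert res_shift.n_debris == small_result.n_debris
        scaled = ZStack(stack.data * 2.0, stack.channels, stack.calibration)
        res_scale = run_detector(scaled, "NeuN", DetectionParams(),
                                 gfap_channel="GFAP")
        assert res_scale.n_cells == small_result.n_cells

    def test_no_blob_is_both_cell_member_and_debris(self, small_result):
        cell_blob_ids = {id(b) for t in small_result.cells for b in t.blobs}
        debris_blob_ids = {id(p.blob) for p in small_result.accepted_debris}
        assert not (cell_blob_ids & debris_blob_ids)

    def test_cells_counted_once_per_track_not_per_blob(self, small_result):
        n_member_blobs = sum(t.layer_span for t in small_result.cells)
        assert n_member_blobs >= small_result.n_cells
        assert small_result.n_cells == len(small_result.cells)

    def test_accepted_debris_sit_near_true_fragments(self, small_scene,
                                                     small_result):
        _, truth = small_scene
        true_debris = truth.of_kind("debris")
        for p in small_result.accepted_debris:
            dists = [np.hypot(p.blob.centroid_um[0] - t.x_um,
                              p.blob.centroid_um[1] - t.y_um)
                     for t in true_debris]
            assert min(dists) < 3.0
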