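"""Image quantification: background subtraction, nuclei segmentation,
Ki-67 calling, the 2000 um^2 cluster rule, and full-tile composition."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from dogscreen.quantify import (
    quantify_ki67,
    quantify_tile,
    segment_cyto_objects,
    segment_nuclei,
    subtract_background,
)
from dogscreen.simulate import NoiseConfig, TileRaster, TileTruth, render_tile


PX = 2.0  # um/px used throughout these fixtures


def _disk_image(shape, centers, radius_px, amp):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2] = amp
    return img


def _grid_centers(shape, n, margin=30, spacing=40):
    centers = []
    cols = int(np.ceil(np.sqrt(n)))
    for k in range(n):
        centers.append(
            (margin + (k % cols) * spacing, margin + (k // cols) * spacing)
        )
    assert all(c[0] < shape[1] - margin and c[1] < shape[0] - margin
               for c in centers)
    return centers


def _truth_raster(n_cells=50, ki67_frac=0.4, seed=0, noise=None,
                  cyto_area=800.0, shape_um=(1741.0, 1298.0)):
    """Non-touching planted cells on a regular grid, rendered to a raster."""
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n_cells)))
    pitch = min((shape_um[0] - 120) / cols, (shape_um[1] - 120) / cols)
    xs, ys = [], []
    for k in range(n_cells):
        xs.append(60 + (k % cols) * pitch)
        ys.append(60 + (k // cols) * pitch)
    n_pos = int(round(ki67_frac * n_cells))
    ki = np.zeros(n_cells, int)
    ki[rng.permutation(n_cells)[:n_pos]] = 1
    cells = pd.DataFrame({
        "tile_i": 0, "tile_j": 0, "cell_id": range(n_cells),
        "x_um": xs, "y_um": ys,
        "nucleus_r_um": rng.uniform(4, 6, n_cells),
        "cyto_area_um2": cyto_area, "ki67": ki, "cluster_id": -1,
    })
    from dogscreen.gradients import MaterialPoint

    truth = TileTruth((0, 0), MaterialPoint(0, 0, 50, 40), 0, 100 * ki67_frac,
                      0, 0, cells)
    raster = render_tile(truth, noise or NoiseConfig.noiseless(), seed=seed,
                         pixel_size_um=PX, tile_um=shape_um)
    return truth, raster


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(np.full((200, 200), 500.0), PX)
        np.testing.assert_allclose(out, 0.0)

    def test_blob_on_ramp_preserved_and_ramp_removed(self):
        shape = (300, 300)
        ramp = np.linspace(0, 400, shape[1])[None, :] * np.ones((shape[0], 1))
        blob = _disk_image(shape, [(150, 150)], radius_px=int(5 / PX) + 1,
                           amp=1000.0)
        out = subtract_background(ramp + blob, PX, radius_um=50)
        interior = out[100:200, 100:200]
        assert out[150, 150] == pytest.approx(1000.0, rel=0.05)
        background_region = out[50:100, 50:100]
        assert np.abs(background_region).max() < 0.05 * 400

    def test_output_never_negative(self, rng):
        img = rng.normal(1000, 200, size=(128, 128))
        assert subtract_background(img, PX).min() >= 0.0

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError, match="2 px"):
            subtract_background(np.zeros((50, 50)), pixel_size_um=2.0,
                                radius_um=2.0)


class TestSegmentNuclei:
    def test_recovers_planted_nontouching_nuclei_exactly(self):
        truth, raster = _truth_raster(n_cells=50)
        mask = segment_nuclei(raster.nuclei, PX)
        assert mask.n_objects == 50

    def test_blank_image_zero_objects(self):
        assert segment_nuclei(np.zeros((300, 300)), PX).n_objects == 0

    def test_noise_only_image_zero_objects(self, rng):
        noisy = rng.normal(2000, 0.02 * 65535, size=(400, 400)).clip(0)
        assert segment_nuclei(noisy, PX).n_objects == 0

    def test_small_specks_removed(self):
        img = _disk_image((200, 200), [(50, 50)], radius_px=0, amp=30000)
        # a single-pixel speck (4 um^2 at 2 um/px) is below the 20 um^2 minimum
        assert segment_nuclei(img, PX, min_area_um2=20).n_objects == 0
        big = _disk_image((200, 200), [(100, 100)], radius_px=4, amp=30000)
        assert segment_nuclei(big, PX, min_area_um2=20).n_objects == 1

    def test_labels_consecutive_from_one(self):
        _, raster = _truth_raster(n_cells=12)
        mask = segment_nuclei(raster.nuclei, PX)
        present = np.unique(mask.labels)
        np.testing.assert_array_equal(present, np.arange(0, 13))


class TestQuantifyKi67:
    @pytest.mark.parametrize("planted", [0.2, 0.4, 0.8])
    def test_recovers_planted_fraction_within_5_points(self, planted):
        truth, raster = _truth_raster(n_cells=100, ki67_frac=planted,
                                      noise=NoiseConfig())
        mask = segment_nuclei(raster.nuclei, PX)
        pos, pct = quantify_ki67(mask, raster.proliferation)
        assert pct == pytest.approx(100 * planted, abs=5.0)

    def test_all_dark_channel_zero_positives(self):
        _, raster = _truth_raster(n_cells=30, ki67_frac=0.0)
        mask = segment_nuclei(raster.nuclei, PX)
        pos, pct = quantify_ki67(mask, np.zeros_like(raster.proliferation))
        assert pos == 0 and pct == 0.0

    def test_no_nuclei_reports_missing(self):
        mask = segment_nuclei(np.zeros((100, 100)), PX)
        pos, pct = quantify_ki67(mask, np.zeros((100, 100)))
        assert pos == 0 and pct is None

    def test_shape_mismatch_rejected(self):
        _, raster = _truth_raster(n_cells=10)
        mask = segment_nuclei(raster.nuclei, PX)
        with pytest.raises(ValueError):
            quantify_ki67(mask, np.zeros((10, 10)))

    def test_positives_never_exceed_total(self, rng):
        truth, raster = _truth_raster(n_cells=40, ki67_frac=1.0,
                                      noise=NoiseConfig())
        mask = segment_nuclei(raster.nuclei, PX)
        pos, _ = quantify_ki67(mask, raster.proliferation)
        assert pos <= mask.n_objects


class TestSegmentCytoObjects:
    def test_cluster_and_singles_partitioned(self):
        shape = (400, 500)
        # one merged object of ~4000 um^2 (r = 36 um) and 10 disjoint cells
        big = _disk_image(shape, [(250, 200)], radius_px=int(36 / PX),
                          amp=20000)
        singles = _disk_image(
            shape, _grid_centers(shape, 10, margin=40, spacing=60),
            radius_px=int(16 / PX), amp=20000,
        )
        clusters, single_mask = segment_cyto_objects(big + singles, PX)
        assert clusters.n_objects == 1
        assert single_mask.n_objects == 10
        assert clusters.table["area_um2"].iloc[0] > 2000

    def test_exact_threshold_area_is_cluster(self):
        # a 2000 um^2 rectangle (40 x 50 um -> 20 x 25 px at 2 um/px)
        img = np.zeros((200, 200))
        img[80:105, 60:80] = 20000.0
        clusters, singles = segment_cyto_objects(img, PX)
        assert clusters.n_objects == 1 and singles.n_objects == 0
        assert clusters.table["area_um2"].iloc[0] == pytest.approx(2000.0)

    def test_empty_tile(self):
        clusters, singles = segment_cyto_objects(np.zeros((200, 200)), PX)
        assert clusters.n_objects == 0 and singles.n_objects == 0

    def test_sub_minimum_objects_discarded(self):
        img = _disk_image((200, 200), [(100, 100)], radius_px=2, amp=20000)
        clusters, singles = segment_cyto_objects(img, PX, min_object_um2=100)
        assert clusters.n_objects == 0 and singles.n_objects == 0

    def test_every_retained_object_in_exactly_one_class(self):
        _, raster = _truth_raster(n_cells=60, noise=NoiseConfig())
        clusters, singles = segment_cyto_objects(raster.cytoskeleton, PX)
        overlap = (clusters.labels > 0) & (singles.labels > 0)
        assert not overlap.any()


class TestQuantifyTile:
    def test_density_arithmetic_on_published_tile_area(self):
        truth, raster = _truth_raster(n_cells=226)
        q = quantify_tile(raster, analyzed_area_mm2=2.26)
        assert q.nuclei_count == 226
        assert q.cell_density_per_mm2 == pytest.approx(100.0)

    def test_noiseless_tile_recovers_planted_count(self):
        truth, raster = _truth_raster(n_cells=80)
        assert quantify_tile(raster).nuclei_count == 80

    def test_blank_tile_missing_safe(self):
        blank = TileRaster(
            nuclei=np.zeros((300, 300), np.uint16),
            cytoskeleton=np.zeros((300, 300), np.uint16),
            proliferation=np.zeros((300, 300), np.uint16),
            pixel_size_um=PX, origin_mm=(0, 0),
        )
        q = quantify_tile(blank)
        assert q.nuclei_count == 0
        assert q.ki67_pct is None and q.area_per_cell_um2 is None
        assert q.mean_cluster_area_um2 is None
        assert q.cell_density_per_mm2 == 0.0

    def test_area_scale_consistency_across_pixel_sizes(self):
        """Halving the pixel size changes object areas by < 3%."""
        results = {}
        for px in (2.0, 1.0):
            truth, _ = _truth_raster(n_cells=30)
            raster = render_tile(truth, NoiseConfig.noiseless(), seed=1,
                                 pixel_size_um=px)
            q = quantify_tile(raster)
            results[px] = q.area_per_cell_um2
        assert results[1.0] == pytest.approx(results[2.0], rel=0.03)

    def test_adding_a_cell_never_decreases_count(self):
        truth, raster = _truth_raster(n_cells=20)
        base = quantify_tile(raster).nuclei_count
        cells = truth.cells.copy()
        extra = cells.iloc[[0]].assign(x_um=1500.0, y_um=1100.0, cell_id=99)
        bigger = TileTruth(truth.index, truth.material, 0, 0, 0, 0,
                           pd.concat([cells, extra], ignore_index=True))
        raster2 = render_tile(bigger, NoiseConfig.noiseless(), seed=0,
                              pixel_size_um=PX)
        assert quantify_tile(raster2).nuclei_count >= base
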