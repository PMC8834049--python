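"""Stain unmixing, segmentation, membrane measurement and composite score.

The synthetic renderer composes stains in OD space, so it serves as an
exact oracle for the deconvolution step and a geometric oracle for the
completeness operator.
"""

import numpy as np
import pandas as pd
import pytest

from sstr2dia import membrane, synthetic
from sstr2dia.membrane import DAB, HEMATOXYLIN


def render_pixel(c_hema: float, c_dab: float) -> np.ndarray:
    """1x1 RGB image with the given stain coefficients, quantized to 8 bit."""
    od = c_hema * HEMATOXYLIN.array + c_dab * DAB.array
    return np.rint(255.0 * 10.0 ** -od).astype(np.uint8).reshape(1, 1, 3)


class TestDeconvolution:
    def test_white_pixel_has_zero_od(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert membrane.deconvolve_dab(img).max() == 0.0

    @pytest.mark.parametrize("coef", [0.2, 0.5, 0.8])
    def test_recovers_rendered_dab_coefficient(self, coef):
        dab_map = membrane.deconvolve_dab(render_pixel(0.0, coef))
        assert dab_map[0, 0] == pytest.approx(coef, abs=0.02)

    def test_hematoxylin_pixel_unmixes_to_negligible_dab(self):
        # raw projection onto the DAB vector would give ~0.8*0.5 = 0.4 here;
        # matrix unmixing must suppress the cross-talk below the 0.15 threshold
        dab_map = membrane.deconvolve_dab(render_pixel(0.5, 0.0))
        assert dab_map[0, 0] < 0.15

    def test_mixed_pixel_recovers_both_coefficients(self):
        img = render_pixel(0.4, 0.3)
        hema, dab = membrane.unmix_stains(img)
        assert hema[0, 0] == pytest.approx(0.4, abs=0.02)
        assert dab[0, 0] == pytest.approx(0.3, abs=0.02)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            membrane.deconvolve_dab(np.zeros((4, 4)))

    def test_stain_vector_normalized(self):
        v = membrane.StainVector((2.0, 0.0, 0.0))
        assert v.od_rgb == (1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            membrane.StainVector((0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            membrane.stain_matrix(membrane.StainVector((1, 1, 1)),
                                  membrane.StainVector((2, 2, 2)))


class TestSegmentation:
    def test_counts_match_generator_truth(self):
        spec = synthetic.ImageSpec(n_cells=150)
        image, truth = synthetic.generate_ihc_image(spec, seed=11)
        seg = membrane.segment_cells(image)
        assert abs(seg.n_cells - 150) <= 5

    def test_blank_image_yields_no_cells(self):
        blank = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert membrane.segment_cells(blank).n_cells == 0

    def test_close_nuclei_merge_deterministically(self):
        # two disks 3 px apart with min_distance 10: a single distance peak,
        # so they merge into one nucleus, stably across runs
        od = np.zeros((40, 40, 3))
        yy, xx = np.mgrid[:40, :40]
        for cc in (17, 20):
            od[(yy - 20) ** 2 + (xx - cc) ** 2 <= 16] = 0.5 * HEMATOXYLIN.array
        img = np.rint(255.0 * 10.0 ** -od).astype(np.uint8)
        seg1 = membrane.segment_cells(img, min_distance=10)
        seg2 = membrane.segment_cells(img, min_distance=10)
        assert seg1.n_cells == 1
        assert np.array_equal(seg1.cell_labels, seg2.cell_labels)

    def test_deterministic_on_synthetic_field(self):
        image, _ = synthetic.generate_ihc_image(
            synthetic.ImageSpec(n_cells=40), seed=5)
        a = membrane.segment_cells(image)
        b = membrane.segment_cells(image)
        assert np.array_equal(a.cell_labels, b.cell_labels)
        pd.testing.assert_frame_equal(a.cells, b.cells)


def _measure(image, **kwargs):
    seg = membrane.segment_cells(image)
    dab_map = membrane.deconvolve_dab(image)
    return membrane.measure_membrane(seg, dab_map, **kwargs)


class TestMembraneMeasurement:
    def test_fully_stained_ring(self):
        spec = synthetic.ImageSpec(n_cells=30, membrane_completeness=100.0,
                                   membrane_od=0.4)
        image, _ = synthetic.generate_ihc_image(spec, seed=2)
        cells = _measure(image)
        assert len(cells) == 30
        assert (cells["membrane_completeness"] == 100.0).all()
        assert cells["membrane_mean_od"].mean() == pytest.approx(0.4, rel=0.1)

    def test_unstained_ring(self):
        spec = synthetic.ImageSpec(n_cells=30, membrane_completeness=0.0,
                                   membrane_od=0.0)
        image, _ = synthetic.generate_ihc_image(spec, seed=2)
        cells = _measure(image)
        assert (cells["membrane_completeness"] == 0.0).all()
        assert (cells["membrane_mean_od"] == 0.0).all()
        assert not cells["is_positive"].any()

    def test_half_arc_completeness(self):
        spec = synthetic.ImageSpec(n_cells=20, membrane_completeness=50.0,
                                   membrane_od=0.4, noise_sigma=0.0)
        image, _ = synthetic.generate_ihc_image(spec, seed=9)
        cells = _measure(image, n_sectors=36)
        assert np.all(np.abs(cells["membrane_completeness"] - 50.0) <= 100.0 / 36 + 1e-9)


class TestClassifyPositive:
    def test_strict_threshold_boundaries(self):
        df = pd.DataFrame({
            "membrane_completeness": [0.0, 30.0, 50.0, 51.0],
            "is_positive": [False] * 4,
        })
        at0 = membrane.classify_positive(df, 0.0)
        assert at0["is_positive"].tolist() == [False, True, True, True]
        at50 = membrane.classify_positive(df, 50.0)
        assert at50["is_positive"].tolist() == [False, False, False, True]

    def test_positive_count_monotone_in_threshold(self, rng):
        df = pd.DataFrame({
            "membrane_completeness": rng.uniform(0, 100, 200),
            "is_positive": False,
        })
        counts = [membrane.classify_positive(df, t)["is_positive"].sum()
                  for t in [0, 10, 25, 50, 75, 100]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # min=0 and min=100 bracket every other setting
        assert counts[0] == max(counts) and counts[-1] == min(counts)

    def test_bounds_validated(self):
        df = pd.DataFrame({"membrane_completeness": [10.0], "is_positive": [False]})
        with pytest.raises(ValueError):
            membrane.classify_positive(df, 101)


def _cells_df(pct_positive, od, comp, n=10):
    n_pos = int(round(n * pct_positive / 100))
    return pd.DataFrame({
        "membrane_mean_od": [od] * n_pos + [0.0] * (n - n_pos),
        "membrane_completeness": [comp] * n_pos + [0.0] * (n - n_pos),
        "is_positive": [True] * n_pos + [False] * (n - n_pos),
    })


class TestCompositeScore:
    def test_no_positive_cells_scores_zero(self):
        r = membrane.composite_score(_cells_df(0, 0, 0))
        assert r.composite_score == 0.0 and r.pct_positive_cells == 0.0

    def test_arithmetic(self):
        r = membrane.composite_score(_cells_df(80, 0.35, 90))
        assert r.composite_score == pytest.approx(2520.0)
        assert r.table_value == 2520

    def test_monotone_in_each_factor(self):
        base = membrane.composite_score(_cells_df(50, 0.3, 60)).composite_score
        assert membrane.composite_score(_cells_df(60, 0.3, 60)).composite_score > base
        assert membrane.composite_score(_cells_df(50, 0.4, 60)).composite_score > base
        assert membrane.composite_score(_cells_df(50, 0.3, 80)).composite_score > base

    def test_scale_bound(self):
        # pct and completeness on 0-100, OD <= 1 -> composite <= 10,000
        r = membrane.composite_score(_cells_df(100, 1.0, 100))
        assert r.composite_score <= 10_000

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            membrane.composite_score(_cells_df(0, 0, 0, n=0))


def _scatter_cells(rng, n, extent, od_range=(0.2, 0.6)):
    comp = rng.choice([0.0, 50.0, 100.0], size=n)
    od = np.where(comp > 0, rng.uniform(*od_range, n), 0.0)
    return pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "centroid_row": rng.uniform(0, extent, n),
        "centroid_col": rng.uniform(0, extent, n),
        "membrane_mean_od": od,
        "membrane_completeness": comp,
        "is_positive": comp > 0,
    })


class TestHotspot:
    def test_matches_exhaustive_sweep(self, rng):
        cells = _scatter_cells(rng, 120, extent=100)
        window, stride, mn, mx = 40, 10, 10, 60
        spot = membrane.select_hotspot(cells, (100, 100), window=window,
                                       stride=stride, min_cells=mn, max_cells=mx)
        best = None
        for r0 in range(0, 61, stride):
            for c0 in range(0, 61, stride):
                sel = cells[(cells.centroid_row >= r0) & (cells.centroid_row < r0 + window)
                            & (cells.centroid_col >= c0) & (cells.centroid_col < c0 + window)]
                if not (mn <= len(sel) <= mx):
                    continue
                score = membrane.composite_score(sel).composite_score
                key = (-score, (r0, c0))
                if best is None or key < best[0]:
                    best = (key, (r0, c0))
        assert not spot.degraded
        assert spot.origin == best[1]

    def test_uniform_staining_tie_breaks_to_smallest_origin(self):
        # a regular grid of identical cells: every full window scores the same
        rows, cols = np.mgrid[5:96:10, 5:96:10]
        n = rows.size
        cells = pd.DataFrame({
            "cell_id": np.arange(1, n + 1),
            "centroid_row": rows.ravel().astype(float),
            "centroid_col": cols.ravel().astype(float),
            "membrane_mean_od": 0.4,
            "membrane_completeness": 100.0,
            "is_positive": True,
        })
        spot = membrane.select_hotspot(cells, (100, 100), window=50, stride=25,
                                       min_cells=5, max_cells=n)
        assert spot.origin == (0, 0)

    def test_too_few_cells_degrades_to_all(self, rng):
        cells = _scatter_cells(rng, 400, extent=500)
        spot = membrane.select_hotspot(cells, (500, 500), window=512, stride=128,
                                       min_cells=1000, max_cells=2000)
        assert spot.degraded
        assert spot.n_cells == 400

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            membrane.select_hotspot(_scatter_cells(np.random.default_rng(0), 0, 10),
                                    (10, 10))

    def test_finds_strongly_stained_cluster(self, rng):
        cells = _scatter_cells(rng, 100, extent=200, od_range=(0.15, 0.25))
        cluster = pd.DataFrame({
            "cell_id": np.arange(101, 131),
            "centroid_row": rng.uniform(150, 190, 30),
            "centroid_col": rng.uniform(150, 190, 30),
            "membrane_mean_od": 0.9,
            "membrane_completeness": 100.0,
            "is_positive": True,
        })
        all_cells = pd.concat([cells, cluster], ignore_index=True)
        spot = membrane.select_hotspot(all_cells, (200, 200), window=60,
                                       stride=20, min_cells=5, max_cells=80)
        assert spot.origin[0] >= 120 and spot.origin[1] >= 120
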