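"""Boundary extraction, snake refinement, thickness and classification."""

import numpy as np
import pytest

import retscreen as rs
from retscreen import oct_rnfl as orn
from retscreen import phantoms as ph


class TestAnteriorAreaThreshold:
    def test_reference_geometry_is_158(self):
        assert orn.anterior_area_threshold((329, 689)) == 158

    def test_scales_with_pixel_count(self):
        assert orn.anterior_area_threshold((658, 689)) == int(0.0007 * 658 * 689)

    def test_rounds_down(self):
        # 100 x 103 -> 7210 * 0.0007 = 7.21 % ... floor(7.21) = 7
        assert orn.anterior_area_threshold((100, 103)) == 7


class TestFillMissingCubic:
    def test_recovers_generating_cubic_exactly(self):
        cols = np.arange(120, dtype=float)
        true = 40 + 0.3 * cols - 4e-3 * cols**2 + 1.5e-5 * cols**3
        rows = true.copy()
        rows[40:70] = np.nan  # 30-column gap
        filled = orn.fill_missing_cubic(rs.BoundaryTrace(rows))
        np.testing.assert_allclose(filled.rows, true, atol=1e-8)

    def test_underdetermined_raises(self):
        rows = np.full(50, np.nan)
        rows[[3, 10, 17]] = 5.0
        with pytest.raises(rs.BoundaryEstimationError):
            orn.fill_missing_cubic(rs.BoundaryTrace(rows))

    def test_defined_columns_untouched(self):
        rows = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        filled = orn.fill_missing_cubic(rs.BoundaryTrace(rows))
        np.testing.assert_array_equal(filled.rows[[0, 1, 3, 4, 5]], [1, 2, 4, 5, 6])


class TestInitialAnterior:
    def test_noiseless_recovery_within_one_px(self, oct_noiseless):
        img, ant_t, _ = oct_noiseless
        trace = orn.initial_anterior(img)
        assert trace.fully_defined
        assert np.max(np.abs(trace.rows - ant_t.rows)) <= 1.0

    def test_gap_filled_with_cubic(self):
        spec = ph.OctPhantomSpec(
            anterior_coeffs=(70.0, 0.08, 2e-4, -3e-7),
            looks=None,
            gap_cols=((300, 330),),
        )
        img, ant_t, _ = ph.make_oct_phantom(spec)
        trace = orn.initial_anterior(img)
        assert trace.fully_defined
        # the generating anterior is itself a cubic, so the filled values
        # must land on it (within the 1 px discretization of the edge)
        assert np.max(np.abs(trace.rows[300:330] - ant_t.rows[300:330])) <= 1.5

    def test_flat_image_raises(self):
        with pytest.raises(rs.BoundaryEstimationError):
            orn.initial_anterior(rs.OctImage(np.full((100, 200), 0.5)))


@pytest.fixture(scope="module")
def step_img():
    px = np.full((80, 120), 0.1)
    px[40:, :] = 0.9
    return rs.OctImage(px)


class TestGreedySnake:
    def test_fixed_point_on_edge_image_terms_only(self, step_img):
        init = rs.BoundaryTrace(np.full(120, 39.0))  # on the max-gradient row
        p = rs.SnakeParams(alpha=0.0, beta=0.0, gamma=1.0, search_window=7)
        out = orn.greedy_snake(step_img, init, p)
        np.testing.assert_array_equal(out.rows, init.rows)

    def test_offset_init_converges_within_one_px(self, step_img):
        init = rs.BoundaryTrace(np.full(120, 36.0))  # 3 px above the edge
        out = orn.greedy_snake(step_img, init, rs.SnakeParams(search_window=7))
        assert np.max(np.abs(out.rows - 39.5)) <= 1.0

    def test_energy_non_increasing_each_iteration(self, step_img):
        rng = np.random.default_rng(0)
        init_rows = np.clip(39 + rng.integers(-5, 6, 120), 0, 79).astype(float)
        p = rs.SnakeParams(search_window=7, max_iter=1)
        trace = rs.BoundaryTrace(init_rows)
        energies = [orn.snake_total_energy(step_img, trace, p)]
        for _ in range(10):
            trace = orn.greedy_snake(step_img, trace, p)
            energies.append(orn.snake_total_energy(step_img, trace, p))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_returned_energy_not_above_initial(self, step_img):
        init = rs.BoundaryTrace(np.full(120, 33.0))
        p = rs.SnakeParams()
        out = orn.greedy_snake(step_img, init, p)
        assert orn.snake_total_energy(step_img, out, p) <= orn.snake_total_energy(
            step_img, init, p
        ) + 1e-9

    def test_window_exceeding_height_raises(self, step_img):
        with pytest.raises(rs.ParameterError):
            orn.greedy_snake(
                step_img, rs.BoundaryTrace(np.full(120, 39.0)), rs.SnakeParams(search_window=81)
            )

    def test_partial_init_rejected(self, step_img):
        rows = np.full(120, 39.0)
        rows[5] = np.nan
        with pytest.raises(rs.BoundaryEstimationError):
            orn.greedy_snake(step_img, rs.BoundaryTrace(rows))


class TestEstimatePosterior:
    def test_noiseless_two_band_recovery(self, oct_noiseless):
        img, ant_t, post_t = oct_noiseless
        anterior = orn.initial_anterior(img)
        post = orn.estimate_posterior(img, anterior)
        assert np.max(np.abs(post.rows - post_t.rows)) <= 1.0

    def test_rpe_edge_rejected(self, oct_noiseless):
        # the RPE band sits 80 px below the anterior; the recovered posterior
        # must track the 28 px RNFL bottom, never the RPE
        img, ant_t, post_t = oct_noiseless
        post = orn.estimate_posterior(img, orn.initial_anterior(img))
        assert np.all(post.rows - ant_t.rows < 60)

    def test_undefined_anterior_rejected(self, oct_noiseless):
        img, _, _ = oct_noiseless
        rows = np.full(img.shape[1], 80.0)
        rows[0] = np.nan
        with pytest.raises(rs.BoundaryEstimationError):
            orn.estimate_posterior(img, rs.BoundaryTrace(rows))

    def test_empty_candidate_field_raises(self):
        img = rs.OctImage(np.full((100, 200), 0.5))
        anterior = rs.BoundaryTrace(np.full(200, 10.0))
        with pytest.raises(rs.BoundaryEstimationError):
            orn.estimate_posterior(img, anterior)


class TestMedianFilterTrace:
    def test_single_column_spike_removed(self):
        rows = np.full(200, 50.0)
        rows[100] = 70.0  # +20 px one-column spike
        out = orn.median_filter_trace(rows, points=50)
        assert out[100] == pytest.approx(50.0)

    def test_window_shrinks_at_ends(self):
        rows = np.arange(100, dtype=float)
        out = orn.median_filter_trace(rows, points=50)
        assert out[0] == pytest.approx(0.0)  # width-1 window at the border
        assert np.isfinite(out).all()


class TestRnflThickness:
    def test_one_pixel_separation_is_six_microns(self):
        ant = rs.BoundaryTrace(np.full(689, 100.0))
        post = rs.BoundaryTrace(np.full(689, 101.0))
        report = orn.rnfl_thickness(ant, post, 6.0)
        assert report.mean_thickness_um == pytest.approx(6.0)

    def test_identical_traces_zero(self):
        t = rs.BoundaryTrace(np.full(50, 42.0))
        assert orn.rnfl_thickness(t, t, 6.0).mean_thickness_um == 0.0

    def test_28_px_separation_is_168_um(self):
        ant = rs.BoundaryTrace(np.full(100, 60.0))
        post = rs.BoundaryTrace(np.full(100, 88.0))
        assert orn.rnfl_thickness(ant, post, 6.0).mean_thickness_um == pytest.approx(168.0)

    def test_linear_in_axial_pitch(self, rng):
        ant = rs.BoundaryTrace(np.full(64, 30.0))
        post = rs.BoundaryTrace(30.0 + rng.integers(1, 40, 64).astype(float))
        a = orn.rnfl_thickness(ant, post, 6.0)
        b = orn.rnfl_thickness(ant, post, 12.0)
        np.testing.assert_allclose(b.thickness_um, 2.0 * a.thickness_um)

    def test_negative_differences_clipped_with_warning(self):
        ant = rs.BoundaryTrace(np.full(30, 50.0))
        post = rs.BoundaryTrace(np.full(30, 45.0))
        with pytest.warns(UserWarning):
            report = orn.rnfl_thickness(ant, post, 6.0)
        assert (report.thickness_um >= 0).all()

    def test_length_mismatch_error(self):
        with pytest.raises(rs.ParameterError):
            orn.rnfl_thickness(
                rs.BoundaryTrace(np.zeros(10)), rs.BoundaryTrace(np.zeros(11)), 6.0
            )


class TestClassifyGlaucoma:
    def test_below_threshold_glaucomatous(self):
        assert orn.classify_glaucoma(104.9) == "glaucomatous"

    def test_healthy_example(self):
        assert orn.classify_glaucoma(168.06) == "non_glaucomatous"

    def test_exact_threshold_is_healthy(self):
        assert orn.classify_glaucoma(105.0) == "non_glaucomatous"

    def test_accepts_report(self):
        report = rs.RnflReport(
            thickness_um=np.full(10, 90.0), mean_thickness_um=90.0, label="glaucomatous"
        )
        assert orn.classify_glaucoma(report) == "glaucomatous"
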