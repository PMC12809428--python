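"""Match engine: search, significance, peak extraction."""

import numpy as np
import pytest
from scipy.special import erfc

from tm2d import (
    MatchResultMaps,
    SearchSpace,
    defocus_planes,
    detection_threshold,
    euler_to_matrix,
    extract_peaks,
    fp_probability,
    make_micrograph,
    run_match,
    uniform_grid,
)
from tm2d._exceptions import ParameterError, PixelSizeMismatchError
from tm2d.containers import Micrograph
from tm2d.geometry import C1, OrientationGrid, rotation_angle_between


def erfc_bisection_threshold(n, fp, lo=0.0, hi=40.0):
    """Independent oracle: solve n * erfc(z/sqrt(2))/2 = fp by bisection."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if n * 0.5 * erfc(mid / np.sqrt(2.0)) > fp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestDefocusPlanes:
    def test_published_schedule_has_13_planes(self):
        assert len(defocus_planes(-1200, 1200, 200)) == 13

    def test_inclusive_endpoints(self):
        assert np.allclose(defocus_planes(-100, 100, 20),
                           np.arange(-100, 101, 20))

    def test_bad_step(self):
        with pytest.raises(ParameterError):
            defocus_planes(0, 100, 0)


class TestSearchSpace:
    def test_cardinality(self):
        g = uniform_grid(90, 90)
        s = SearchSpace(grid=g, defocus_offsets=[-200, 0, 200])
        assert s.n_per_pixel == len(g) * 3

    def test_unsorted_offsets_rejected(self):
        with pytest.raises(ParameterError):
            SearchSpace(grid=uniform_grid(90, 90), defocus_offsets=[200, 0])


class TestDetectionThreshold:
    def test_single_comparison_0p005(self):
        z = detection_threshold(1, 0.005)
        assert z == pytest.approx(2.5758, abs=1e-3)
        assert z == pytest.approx(erfc_bisection_threshold(1, 0.005), abs=1e-9)

    def test_ten_million_comparisons(self):
        z = detection_threshold(1e7, 1.0)
        assert z == pytest.approx(5.199, abs=1e-3)
        assert z == pytest.approx(erfc_bisection_threshold(1e7, 1.0), abs=1e-9)

    def test_monotonic_in_n(self):
        zs = [detection_threshold(10.0**k, 1.0) for k in range(2, 9)]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ParameterError):
            detection_threshold(0, 1.0)
        with pytest.raises(ParameterError):
            detection_threshold(10, 0.0)


class TestFpProbability:
    def test_expectation_one_poissonizes(self):
        n = 123_456
        z = detection_threshold(n, 1.0)
        assert fp_probability(z, n) == pytest.approx(1 - np.exp(-1), rel=1e-3)

    def test_single_comparison(self):
        assert fp_probability(2.5758, 1) == pytest.approx(0.005, rel=1e-3)

    def test_strictly_decreasing_in_z(self):
        zs = np.linspace(1.0, 8.0, 100)
        ps = fp_probability(zs, 1e6)
        assert np.all(np.diff(ps) <= 0)
        # strictly decreasing wherever not saturated at 1 in double precision
        un = ps < 1.0
        assert np.all(np.diff(ps[un]) < 0)


@pytest.fixture(scope="module")
def tiny_setup(sharp_template, ctf):
    """Signal-dominated single particle (z >> background) on a tiny grid."""
    grid = uniform_grid(90.0, 90.0)
    space = SearchSpace(grid=grid, defocus_offsets=[0.0])
    planted = grid.orientations[17]
    pose = [{"x": 48, "y": 44, "phi": planted[0], "theta": planted[1],
             "psi": planted[2], "defocus": 0.0}]
    field = make_micrograph(sharp_template, pose, ctf, noise_sigma=1.0,
                            seed=1, shape=(96, 96), snr=500.0)
    return field, space, planted


class TestRunMatch:
    def test_self_match_peaks_at_planted_pose(self, tiny_setup,
                                              sharp_template, ctf):
        field, space, planted = tiny_setup
        maps = run_match(field.micrograph, sharp_template, ctf, space)
        y, x = np.unravel_index(np.argmax(maps.scaled_mip), maps.shape)
        assert (x, y) == (48, 44)
        best = (maps.best_phi[y, x], maps.best_theta[y, x], maps.best_psi[y, x])
        assert np.allclose(best, planted)
        assert maps.best_defocus[y, x] == 0.0

    def test_determinism_bitwise(self, tiny_setup, sharp_template, ctf):
        field, space, _ = tiny_setup
        a = run_match(field.micrograph, sharp_template, ctf, space)
        b = run_match(field.micrograph, sharp_template, ctf, space)
        for name in a.named_maps():
            assert np.array_equal(a.named_maps()[name], b.named_maps()[name])

    def test_shrinking_grid_never_increases_mip(self, tiny_setup,
                                                sharp_template, ctf):
        field, space, _ = tiny_setup
        full = run_match(field.micrograph, sharp_template, ctf, space)
        sub_grid = OrientationGrid(psi_step=90.0, theta_step=90.0, symmetry=C1,
                                   orientations=space.grid.orientations[::2])
        sub = run_match(field.micrograph, sharp_template, ctf,
                        SearchSpace(grid=sub_grid, defocus_offsets=[0.0]))
        assert np.all(sub.mip <= full.mip + 1e-5)

    def test_scaled_mip_consistent_with_mean_variance(self, tiny_setup,
                                                      sharp_template, ctf):
        field, space, _ = tiny_setup
        m = run_match(field.micrograph, sharp_template, ctf, space)
        sd = np.sqrt(np.maximum(m.corr_variance, 1e-12))
        assert np.allclose(m.scaled_mip, (m.mip - m.corr_mean) / sd, atol=1e-8)

    def test_pixel_size_mismatch_names_remedy(self, default_template, ctf):
        mic = Micrograph(data=np.zeros((96, 96), np.float32) + 1.0, pixel_size=1.1)
        with pytest.raises(PixelSizeMismatchError, match="optimize"):
            run_match(mic, default_template, ctf,
                      SearchSpace(grid=uniform_grid(90, 90), defocus_offsets=[0.0]))

    def test_nan_input_rejected(self, default_template, ctf):
        bad = np.ones((96, 96), np.float32)
        bad[0, 0] = np.nan
        with pytest.raises(ParameterError):
            run_match(Micrograph(data=bad, pixel_size=1.0), default_template, ctf,
                      SearchSpace(grid=uniform_grid(90, 90), defocus_offsets=[0.0]))

    def test_template_larger_than_image_rejected(self, default_template, ctf):
        mic = Micrograph(data=np.ones((32, 32), np.float32), pixel_size=1.0)
        with pytest.raises(ParameterError):
            run_match(mic, default_template, ctf,
                      SearchSpace(grid=uniform_grid(90, 90), defocus_offsets=[0.0]))


def synthetic_maps(scaled, box=16, n_total=10**6):
    shape = scaled.shape
    z = np.zeros(shape)
    return MatchResultMaps(
        mip=scaled.copy(), scaled_mip=scaled.astype(float), best_phi=z, best_theta=z,
        best_psi=z, best_defocus=z, corr_mean=z, corr_variance=np.ones(shape),
        n_total=n_total, n_per_pixel=1, template_box=box, pixel_size=1.0)


class TestExtractPeaks:
    def test_empty_below_threshold(self):
        maps = synthetic_maps(np.full((64, 64), 2.0))
        assert extract_peaks(maps, z_threshold=5.0) == []

    def test_greedy_suppression_keeps_higher_of_close_pair(self):
        scaled = np.zeros((64, 64))
        scaled[30, 30] = 8.0
        scaled[30, 33] = 9.0  # 3 px away, higher
        maps = synthetic_maps(scaled)
        peaks = extract_peaks(maps, z_threshold=5.0, exclusion_radius=5)
        assert len(peaks) == 1 and (peaks[0].x, peaks[0].y) == (33, 30)

    def test_distant_peaks_both_kept_and_sorted(self):
        scaled = np.zeros((64, 64))
        scaled[20, 20] = 7.0
        scaled[45, 40] = 9.0
        peaks = extract_peaks(synthetic_maps(scaled), 5.0, exclusion_radius=5)
        assert [(p.x, p.y) for p in peaks] == [(40, 45), (20, 20)]
        assert peaks[0].z_score > peaks[1].z_score
        assert 0 < peaks[0].fp_probability < 1

    def test_edge_band_excluded(self):
        scaled = np.zeros((64, 64))
        scaled[4, 4] = 20.0  # inside the half-box edge band for box 16
        assert extract_peaks(synthetic_maps(scaled), 5.0) == []

    def test_recovered_poses_match_planted(self, planted_field, coarse_space):
        field, maps = planted_field
        thr = detection_threshold(maps.n_total, 1.0)
        peaks = extract_peaks(maps, thr, micrograph_id="planted")
        found = 0
        for t in field.truth.itertuples():
            near = [p for p in peaks if (p.x - t.x) ** 2 + (p.y - t.y) ** 2 <= 2]
            if not near:
                continue
            p = near[0]
            ang = rotation_angle_between(
                euler_to_matrix((p.phi, p.theta, p.psi)),
                euler_to_matrix((t.phi, t.theta, t.psi)))
            if ang <= coarse_space.grid.theta_step + 1e-6:
                found += 1
        assert found >= 19  # at least 95% of 20
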