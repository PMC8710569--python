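"""Synthetic generators: scene sets, field-defect masks, perimetry grids,
and the Gaussian binary-choice observer."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scenefield import synthetic as syn
from scenefield.degrade import rasterize_perimetry
from scenefield.sdt import compute_bfi, compute_dprime
from scenefield.types import circular_aperture


class TestSceneGeneration:
    def test_count_labels_and_determinism(self):
        pa = syn.SceneParams.cardinal(64)
        pb = syn.SceneParams.oblique(64)
        imgs1 = syn.generate_scene_set(pa, pb, 50, seed=3)
        imgs2 = syn.generate_scene_set(pa, pb, 50, seed=3)
        assert len(imgs1) == 100
        assert sum(im.label == 0 for im in imgs1) == 50
        assert sum(im.label == 1 for im in imgs1) == 50
        for a, b in zip(imgs1, imgs2):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_pixels_in_unit_range(self):
        img = syn.generate_scene_set(
            syn.SceneParams(size_px=64), syn.SceneParams(size_px=64), 1, seed=0
        )[0]
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_cardinal_profile_boosts_cardinal_band_energy(self):
        """Cardinal-dominant categories carry more Fourier power in the two
        cardinal orientation bands than in the obliques (band-energy oracle)."""
        params = syn.SceneParams.cardinal(128, strength=2.0)
        rng = np.random.default_rng(11)
        energies = np.zeros(8)
        for _ in range(5):
            energies += syn.orientation_band_energy(
                syn.synthesize_scene(params, rng), 8
            )
        cardinal = energies[[0, 4]].mean()
        oblique = energies[[2, 6]].mean()
        assert cardinal > oblique

    @pytest.mark.parametrize("alpha", [0.8, 1.0, 1.2])
    def test_radial_amplitude_slope_matches_exponent(self, alpha):
        """Log-log slope of the radially averaged amplitude spectrum follows
        the configured falloff exponent within 0.15 (periodogram fit)."""
        params = syn.SceneParams(size_px=128, spectral_exponent=alpha)
        rng = np.random.default_rng(29)
        slopes = []
        for _ in range(4):
            img = syn.synthesize_scene(params, rng)
            slopes.append(_radial_amplitude_slope(img - img.mean()))
        assert abs(np.mean(slopes) + alpha) < 0.15

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            syn.generate_scene_set(
                syn.SceneParams(size_px=64), syn.SceneParams(size_px=128), 5, 0
            )
        with pytest.raises(ValueError):
            syn.generate_scene_set(
                syn.SceneParams(size_px=64), syn.SceneParams(size_px=64), 0, 0
            )
        with pytest.raises(ValueError):
            syn.SceneParams(size_px=65)
        with pytest.raises(ValueError):
            syn.SceneParams(orientation_profile=np.array([1.0, -0.5]))


def _radial_amplitude_slope(img):
    """Independent periodogram oracle: radially binned amplitude regression,
    excluding DC and the top 10% of frequencies."""
    n = img.shape[0]
    amp = np.abs(np.fft.fft2(img))
    fr = np.hypot(*np.meshgrid(np.fft.fftfreq(n), np.fft.fftfreq(n)))
    mask = (fr > 0) & (fr < 0.45)
    bins = np.geomspace(fr[mask].min(), 0.45, 25)
    idx = np.digitize(fr[mask], bins)
    xs, ys = [], []
    for b in range(1, len(bins)):
        sel = idx == b
        if sel.sum() > 3:
            xs.append(np.log(fr[mask][sel].mean()))
            ys.append(np.log(amp[mask][sel].mean()))
    return np.polyfit(xs, ys, 1)[0]


class TestVFDMasks:
    @pytest.mark.parametrize(
        "kind,fraction",
        [("none", 0.0), ("hemi_left", 0.5), ("hemi_right", 0.5),
         ("quad_left_up", 0.25), ("quad_left_down", 0.25),
         ("quad_right_up", 0.25), ("quad_right_down", 0.25)],
    )
    def test_occluded_aperture_fraction(self, kind, fraction):
        size = 256
        vfd = syn.generate_vfd(kind, size)
        tol = size / circular_aperture(size).sum()  # ~one pixel row
        assert vfd.occluded_fraction() == pytest.approx(fraction, abs=tol)

    def test_none_mask_is_empty_with_zero_bfi(self):
        vfd = syn.generate_vfd("none", 128)
        assert vfd.raster.sum() == 0
        assert compute_bfi(vfd).bfi == 0.0

    def test_hemifield_respects_meridian(self):
        vfd = syn.generate_vfd("hemi_left", 128)
        right_half = vfd.raster[:, 64:]
        assert right_half.sum() == 0

    def test_unknown_kind_and_odd_size(self):
        with pytest.raises(ValueError):
            syn.generate_vfd("central", 128)
        with pytest.raises(ValueError):
            syn.generate_vfd("none", 127)


class TestPerimetry:
    def test_lattice_is_76_points_offset_from_meridians(self):
        pts = syn.humphrey_30_2_lattice()
        assert pts.shape == (76, 2)
        # 6 degree spacing, 3 degrees off both meridians
        assert np.all(np.abs(pts) % 6 == 3)
        assert not np.any(pts == 0)

    def test_full_field_defect_reads_floor_everywhere(self):
        full = syn.VFDMap(raster=circular_aperture(128).astype(np.uint8))
        grid = syn.generate_perimetry_grid(full, floor_db=0.0, ceiling_db=30.0)
        assert (grid["sensitivity_db"] == 0.0).all()

    def test_hemifield_geometry_without_jitter(self):
        vfd = syn.generate_vfd("hemi_left", 256)
        grid = syn.generate_perimetry_grid(vfd, floor_db=0.0, ceiling_db=30.0)
        assert (grid.loc[grid.x_deg < 0, "sensitivity_db"] == 0.0).all()
        assert (grid.loc[grid.x_deg > 0, "sensitivity_db"] == 30.0).all()

    def test_hemifield_round_trip_recovers_half_field_loss(self):
        """grid -> rasterize -> BFI lands near -0.5 (interpolation tolerance
        across the 6-degree lattice)."""
        vfd = syn.generate_vfd("hemi_left", 256)
        grid = syn.generate_perimetry_grid(vfd)
        recovered = rasterize_perimetry(grid, 256)
        assert compute_bfi(recovered).bfi == pytest.approx(-0.5, abs=0.05)

    def test_unsupported_grid_errors(self):
        vfd = syn.generate_vfd("none", 64)
        with pytest.raises(ValueError):
            syn.generate_perimetry_grid(vfd, grid="humphrey_24_2")

    def test_csv_round_trip(self, tmp_path):
        vfd = syn.generate_vfd("quad_right_up", 128)
        grid = syn.generate_perimetry_grid(vfd, jitter_db=1.0, seed=4)
        path = tmp_path / "perimetry.csv"
        syn.write_perimetry_csv(grid, path)
        back = syn.read_perimetry_csv(path)
        pd.testing.assert_frame_equal(grid, back)


class TestObserver:
    def _stimuli(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return {"c": syn.balanced_trial_labels(n, rng)}

    def test_unbiased_zero_sensitivity_gives_half_rates(self):
        spec = syn.ObserverSpec(dprime=0.0, criterion=0.0, seed=1)
        table = syn.simulate_observer(spec, self._stimuli(4000))
        c = table["c"]
        hr = c.hits / (c.hits + c.misses)
        far = c.false_alarms / (c.false_alarms + c.correct_rejections)
        assert hr == pytest.approx(0.5, abs=0.03)
        assert far == pytest.approx(0.5, abs=0.03)

    def test_conservative_criterion_matches_gaussian_tail(self):
        """With d' = 0 and c = +1 both response rates approach Phi(-1)."""
        spec = syn.ObserverSpec(dprime=0.0, criterion=1.0, seed=2)
        table = syn.simulate_observer(spec, self._stimuli(8000))
        c = table["c"]
        hr = c.hits / (c.hits + c.misses)
        far = c.false_alarms / (c.false_alarms + c.correct_rejections)
        expected = norm.cdf(-1.0)
        assert hr == pytest.approx(expected, abs=0.02)
        assert far == pytest.approx(expected, abs=0.02)

    def test_dprime_recovery_within_confidence_interval(self):
        """compute_dprime recovers the generative d' = 1.5 inside its 95%
        interval in at least 90% of seeded replicates (n = 2000/condition)."""
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            spec = syn.ObserverSpec(dprime=1.5, criterion=0.3, seed=100 + rep)
            table = syn.simulate_observer(spec, self._stimuli(2000, seed=rep))
            c = table["c"]
            est = compute_dprime(c)
            hr = c.hits / (c.hits + c.misses)
            far = c.false_alarms / (c.false_alarms + c.correct_rejections)
            # delta-method standard error of d'
            var = (hr * (1 - hr) / ((c.hits + c.misses) * norm.pdf(norm.ppf(hr)) ** 2)
                   + far * (1 - far) / ((c.false_alarms + c.correct_rejections)
                                        * norm.pdf(norm.ppf(far)) ** 2))
            if abs(est.d_prime - 1.5) < 1.96 * np.sqrt(var):
                covered += 1
        assert covered >= 0.9 * n_rep

    def test_recovery_is_consistent_at_large_n(self):
        spec = syn.ObserverSpec(dprime=1.5, criterion=0.0, seed=9)
        table = syn.simulate_observer(spec, self._stimuli(10_000))
        assert compute_dprime(table["c"]).d_prime == pytest.approx(1.5, abs=0.1)

    def test_determinism_and_missing_label_error(self):
        spec = syn.ObserverSpec(dprime=1.0, seed=5)
        t1 = syn.simulate_observer(spec, self._stimuli(100))
        t2 = syn.simulate_observer(spec, self._stimuli(100))
        assert t1["c"] == t2["c"]
        with pytest.raises(ValueError):
            syn.simulate_observer(spec, {"c": np.ones(10, dtype=int)})
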