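import dataclasses

import numpy as np
import pytest

from gbsi.boundary_regions import BoundaryRegion
from gbsi.bsi import clip, integrate, integrate_double_window, pbvc, run_bsi
from gbsi.config import PipelineConfig
from gbsi.errors import DegenerateInputError, StageError
from gbsi.phantom import PhantomSpec, make_phantom
from gbsi.tissue_norm import IntensityWindow

from conftest import make_grid, make_mask


class TestClip:
    @pytest.mark.parametrize(
        "value,expected", [(150, 0.5), (50, 0.0), (250, 1.0), (120, 0.2)]
    )
    def test_values(self, value, expected):
        w = IntensityWindow(100, 200)
        assert clip(value, w) == pytest.approx(expected)

    def test_array_and_bounds(self, rng):
        w = IntensityWindow(100, 200)
        out = clip(rng.uniform(0, 300, (5, 5, 5)), w)
        assert out.min() >= 0 and out.max() <= 1


class TestIntegrate:
    def test_single_voxel(self):
        base = make_grid(np.full((1, 1, 1), 300.0))
        rep = make_grid(np.full((1, 1, 1), 50.0))
        region = BoundaryRegion(weights=np.ones((1, 1, 1)), variant="binary_xor")
        w = IntensityWindow(100, 200)
        assert integrate(base, rep, region, w) == pytest.approx(1.0)

    def test_identical_images_zero(self, rng):
        data = rng.uniform(0, 300, (4, 4, 4))
        g = make_grid(data)
        region = BoundaryRegion(weights=rng.uniform(size=(4, 4, 4)), variant="binary_xor")
        assert integrate(g, make_grid(data.copy()), region, IntensityWindow(100, 200)) == 0.0

    def test_hand_computed_weighted_sum(self):
        # 3 voxels, weights (1, 0.5, 0), clip differences (0.4, 0.4, 0.9), D = 2
        w = IntensityWindow(0, 1)
        base = make_grid(
            np.array([0.4, 0.4, 0.9]).reshape(1, 1, 3), voxel_size=(2, 1, 1)
        )
        rep = make_grid(np.zeros((1, 1, 3)), voxel_size=(2, 1, 1))
        region = BoundaryRegion(
            weights=np.array([1, 0.5, 0]).reshape(1, 1, 3), variant="binary_xor"
        )
        assert integrate(base, rep, region, w) == pytest.approx(1.2)

    def test_antisymmetry_exact(self, rng):
        base = make_grid(rng.uniform(0, 300, (5, 5, 5)))
        rep = make_grid(rng.uniform(0, 300, (5, 5, 5)))
        region = BoundaryRegion(weights=rng.uniform(size=(5, 5, 5)), variant="binary_xor")
        w = IntensityWindow(100, 200)
        assert integrate(base, rep, region, w) == -integrate(rep, base, region, w)

    def test_additive_over_disjoint_region_split(self, rng):
        base = make_grid(rng.uniform(0, 300, (6, 6, 6)))
        rep = make_grid(rng.uniform(0, 300, (6, 6, 6)))
        weights = rng.uniform(size=(6, 6, 6))
        half = np.zeros((6, 6, 6), bool)
        half[:3] = True
        w = IntensityWindow(100, 200)
        total = integrate(base, rep, BoundaryRegion(weights=weights, variant="binary_xor"), w)
        part1 = integrate(
            base, rep, BoundaryRegion(weights=np.where(half, weights, 0), variant="binary_xor"), w
        )
        part2 = integrate(
            base, rep, BoundaryRegion(weights=np.where(~half, weights, 0), variant="binary_xor"), w
        )
        assert total == pytest.approx(part1 + part2, rel=1e-12)

    def test_per_voxel_contribution_bounded_by_voxel_volume(self, rng):
        from gbsi.bsi import contribution_map

        base = make_grid(rng.uniform(0, 300, (5, 5, 5)), voxel_size=(1.5, 1.0, 1.0))
        rep = make_grid(rng.uniform(0, 300, (5, 5, 5)), voxel_size=(1.5, 1.0, 1.0))
        region = BoundaryRegion(weights=rng.uniform(size=(5, 5, 5)), variant="binary_xor")
        c = contribution_map(base, rep, region, IntensityWindow(100, 200))
        D = base.voxel_volume
        assert (np.abs(c) <= D + 1e-12).all()


class TestDoubleWindow:
    def _shell_fields(self, delta_out, delta_in):
        """Concentric-sphere GM shell; borders move by the given shifts (mm)."""
        n = 40
        coords = np.indices((n, n, n)) - (n - 1) / 2.0
        r = np.sqrt((coords**2).sum(axis=0))
        r1, r2 = 8.0, 15.0

        def image(r1_, r2_):
            # CSF 20 outside r2, GM 100 between, WM 160 inside r1, with a
            # 1-voxel linear ramp at each border
            f_out = np.clip(r2_ + 0.5 - r, 0, 1)
            f_in = np.clip(r1_ + 0.5 - r, 0, 1)
            return 20 + 80 * f_out + 60 * f_in

        base = make_grid(image(r1, r2))
        rep = make_grid(image(r1 + delta_in, r2 - delta_out))
        region = BoundaryRegion(weights=np.ones((n, n, n)), variant="binary_xor")
        w1 = IntensityWindow(40, 80)   # CSF-GM band
        w2 = IntensityWindow(120, 140)  # GM-WM band
        return base, rep, region, w1, w2, r1, r2

    def test_outer_border_only_equals_single_window(self):
        base, rep, region, w1, w2, _, _ = self._shell_fields(delta_out=0.3, delta_in=0.0)
        total = integrate_double_window(base, rep, region, w1, w2)
        single = integrate(base, rep, region, w1)
        assert total == pytest.approx(single)

    def test_identical_images_zero(self):
        base, _, region, w1, w2, _, _ = self._shell_fields(0.0, 0.0)
        assert integrate_double_window(base, base, region, w1, w2) == 0.0

    def test_two_border_loss_matches_analytic_shell_volumes(self):
        # oracle: closed-form sphere-shell volumes lost at each border
        d = 0.3
        base, rep, region, w1, w2, r1, r2 = self._shell_fields(delta_out=d, delta_in=d)
        total = integrate_double_window(base, rep, region, w1, w2)
        v = lambda rr: 4 / 3 * np.pi * rr**3
        expected = (v(r2) - v(r2 - d)) + (v(r1 + d) - v(r1))
        assert total == pytest.approx(expected, rel=0.05)

    def test_equal_volume_loss_at_both_borders_doubles_single(self):
        # inner shift scaled by (r2/r1)^2 so both borders lose equal volume
        d_out = 0.3
        r1, r2 = 8.0, 15.0
        d_in = d_out * (r2 / r1) ** 2
        base, rep, region, w1, w2, _, _ = self._shell_fields(d_out, d_in)
        total = integrate_double_window(base, rep, region, w1, w2)
        single = integrate(base, rep, region, w1)
        assert total == pytest.approx(2 * single, rel=0.1)


class TestPbvc:
    def _mask(self, n_voxels):
        prob = np.zeros((10, 10, 10))
        prob.ravel()[:n_voxels] = 1.0
        return make_mask(prob)

    @pytest.mark.parametrize(
        "bsi,vol,years,expected",
        [(10.0, 1000, 1.0, 1.0), (10.0, 1000, 2.0, 0.5), (-5.0, 1000, 0.5, -1.0)],
    )
    def test_annualization_and_sign(self, bsi, vol, years, expected):
        assert pbvc(bsi, self._mask(vol), years, 1.0) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            pbvc(1.0, self._mask(0), 1.0, 1.0)


class TestRunBsi:
    def test_identical_pair_all_variants_zero(self, identical_pair):
        # the normalization fit introduces ~1 ulp of slope error, so the
        # integral is zero only to float accumulation precision
        for variant in ("pxor_gbsi", "binary_xor", "pbsi_1", "pbsi_gamma"):
            res = run_bsi(identical_pair, PipelineConfig(variant=variant))
            assert res.bsi_mm3 == pytest.approx(0.0, abs=1e-8)
            assert res.pbvc_percent_per_year == pytest.approx(0.0, abs=1e-10)

    def test_phantom_2pct_recovery_within_15pct(self, small_phantom_pair):
        pair, truth = small_phantom_pair
        res = run_bsi(pair, PipelineConfig())
        assert res.pbvc_percent_per_year == pytest.approx(
            truth.true_pbvc_percent_per_year, rel=0.15
        )
        assert 0 < res.kappa <= 1
        assert res.region_voxels > 0

    def test_pipeline_reversion_gbsi_to_kn(self, small_phantom_pair):
        pair, _ = small_phantom_pair
        from gbsi.volumes import binarize

        binary_pair = dataclasses.replace(
            pair,
            baseline_mask=binarize(pair.baseline_mask, 0.5),
            repeat_mask=binarize(pair.repeat_mask, 0.5),
        )
        gb = run_bsi(binary_pair, PipelineConfig(variant="pxor_gbsi", kappa_override=1.0))
        kn = run_bsi(
            binary_pair, PipelineConfig(variant="binary_xor", xor_dilate=0, xor_erode=0)
        )
        assert gb.bsi_mm3 == pytest.approx(kn.bsi_mm3, rel=1e-12)

    def test_phantom_monotone_in_true_loss(self):
        measured = []
        for f in (0.0, 0.01, 0.02, 0.04):
            spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_size=2.0, atrophy_fraction=f)
            pair, _ = make_phantom(spec)
            measured.append(run_bsi(pair, PipelineConfig()).bsi_mm3)
        assert measured == sorted(measured)
        assert len(set(measured)) == 4

    def test_double_window_shell_phantom_recovery(self):
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            voxel_size=1.0,
            outer_semiaxes=(14, 12, 10),
            inner_semiaxes=(9, 7, 6),
            atrophy_fraction=0.04,
            mask_structure="shell",
        )
        pair, truth = make_phantom(spec)
        res = run_bsi(pair, PipelineConfig(window_mode="double"))
        assert res.pbvc_percent_per_year == pytest.approx(
            truth.true_pbvc_percent_per_year, rel=0.15
        )
        assert len(res.windows) == 2

    def test_stage_errors_are_tagged(self, identical_pair):
        bad = dataclasses.replace(identical_pair, baseline=identical_pair.baseline.with_data(
            identical_pair.baseline.data - 100.0  # non-positive intensities
        ))
        with pytest.raises(StageError) as err:
            run_bsi(bad, PipelineConfig(dbc=True))
        assert err.value.stage == "dbc"

    def test_result_report_is_serializable(self, small_phantom_pair):
        import json

        pair, _ = small_phantom_pair
        res = run_bsi(pair, PipelineConfig())
        payload = json.loads(json.dumps(res.to_dict()))
        assert set(payload) >= {
            "bsi_mm3", "pbvc_percent_per_year", "variant", "windows",
            "kappa", "region_voxels", "baseline_volume_mm3",
        }
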