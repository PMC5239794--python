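"""Gabor rendering and contour-in-noise stimulus construction."""

import numpy as np
import pandas as pd
import pytest

from curvestats._angles import wrap90
from curvestats.gabor import GaborParams, render_gabor
from curvestats.stimulus import (
    CELL_DEG,
    ContourSpec,
    PlacementError,
    build_contour_path,
    enumerate_conditions,
    fill_noise_and_render,
    make_stimulus,
    place_contour_in_grid,
)


class TestRenderGabor:
    def test_center_pixel_is_envelope_peak(self):
        patch = render_gabor(GaborParams(), 0.0, 33)
        assert patch[16, 16] == pytest.approx(1.0)

    def test_rotation_by_90_transposes_patch(self):
        p = GaborParams()
        assert np.allclose(render_gabor(p, 90.0, 33), render_gabor(p, 0.0, 33).T,
                           atol=1e-12)

    def test_carrier_frequency_is_8_cpd(self):
        # sigma 4 px, lambda 8 px at 64 px/deg
        assert GaborParams().carrier_cpd == pytest.approx(8.0)

    def test_matches_independent_evaluation(self):
        # closed form written out separately from the renderer
        p = GaborParams(sigma_px=4, lambda_px=8, phase_psi=0.3)
        ori = 25.0
        patch = render_gabor(p, ori, 33)
        c = 16.0
        yy, xx = np.mgrid[0:33, 0:33].astype(float)
        x, y = xx - c, yy - c
        th = np.deg2rad(ori)
        xp = x * np.cos(th) + y * np.sin(th)
        yp = -x * np.sin(th) + y * np.cos(th)
        ref = np.exp(-(xp**2 + yp**2) / (2 * 16.0)) * np.cos(2 * np.pi * xp / 8.0 + 0.3)
        r = np.corrcoef(patch.ravel(), ref.ravel())[0, 1]
        assert r > 0.999
        assert np.allclose(patch, ref, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(sigma_px=0), dict(lambda_px=-1)])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            GaborParams(**bad)

    def test_too_small_patch_raises(self):
        with pytest.raises(ValueError):
            render_gabor(GaborParams(sigma_px=4), 0.0, 12)


class TestContourPath:
    def test_straight_path_is_collinear(self):
        path = build_contour_path(ContourSpec(curvature_angle_deg=0,
                                              end_direction_deg=0))
        assert len(path) == 6
        assert np.allclose(path["orientation_deg"], 0.0)
        assert np.allclose(path["y_deg"], 0.0)

    def test_curved_path_steps_and_end_direction(self):
        # 30 deg curvature with end elements at -10 deg
        path = build_contour_path(ContourSpec(curvature_angle_deg=30,
                                              end_direction_deg=-10))
        core = path[~path["is_end"]]["orientation_deg"].to_numpy()
        assert np.allclose(wrap90(np.diff(core)), 30.0)
        tail = path.iloc[-1]
        assert tail["orientation_deg"] == pytest.approx((core[-1] - 10) % 180)

    @pytest.mark.parametrize("spec", [
        ContourSpec(curvature_angle_deg=20, end_direction_deg=30),
        ContourSpec(curvature_angle_deg=40, end_direction_deg=-30, shape="C"),
        ContourSpec(curvature_angle_deg=30, shape="S"),
        ContourSpec(curvature_angle_deg=10, core_separation_deg=0.75,
                    end_separation_deg=2.0),
    ])
    def test_spacings_are_exact(self, spec):
        path = build_contour_path(spec)
        xy = path[["x_deg", "y_deg"]].to_numpy()
        d = np.hypot(*np.diff(xy, axis=0).T)
        expected = np.full(len(d), spec.core_separation_deg)
        expected[0] = expected[-1] = spec.end_separation_deg
        assert np.allclose(d, expected, atol=1e-9)

    def test_s_shape_flips_sign_once_and_reduces_net_turn(self):
        def net(shape):
            p = build_contour_path(ContourSpec(curvature_angle_deg=30, shape=shape))
            core = p[~p["is_end"]]["orientation_deg"].to_numpy()
            return wrap90(np.diff(core)).sum()

        steps_s = wrap90(np.diff(
            build_contour_path(ContourSpec(curvature_angle_deg=30, shape="S"))
            [lambda d: ~d["is_end"]]["orientation_deg"].to_numpy()))
        signs = np.sign(steps_s)
        assert (np.diff(signs) != 0).sum() == 1
        assert abs(net("S")) < abs(net("C"))

    def test_invalid_element_count_raises(self):
        with pytest.raises(ValueError):
            ContourSpec(n_elements=5)


class TestPlacement:
    def test_places_six_elements_in_distinct_cells(self):
        path = build_contour_path(ContourSpec(curvature_angle_deg=0,
                                              core_separation_deg=0.75,
                                              end_separation_deg=0.75))
        placed = place_contour_in_grid(path, rng_seed=5)
        cells = list(zip(placed["cell_row"], placed["cell_col"]))
        assert len(set(cells)) == 6

    def test_same_seed_is_identical(self):
        path = build_contour_path(ContourSpec(curvature_angle_deg=20))
        a = place_contour_in_grid(path, rng_seed=9)
        b = place_contour_in_grid(path, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_fit_raises(self):
        # a straight path longer than the field diagonal can never fit
        path = build_contour_path(ContourSpec(curvature_angle_deg=0,
                                              core_separation_deg=4.0,
                                              end_separation_deg=4.0))
        with pytest.raises(PlacementError):
            place_contour_in_grid(path, rng_seed=0)


class TestFieldAssembly:
    def test_complete_field_has_256_elements_one_per_cell(self):
        fld = make_stimulus(ContourSpec(curvature_angle_deg=20), seed=3)
        assert len(fld.elements) == 256
        per_cell = fld.elements.groupby(["cell_row", "cell_col"]).size()
        assert len(per_cell) == 256 and (per_cell == 1).all()
        assert fld.elements["is_contour"].sum() == 6
        assert fld.image.dtype == np.uint8 and fld.image.shape == (512, 512)

    def test_target_absent_field_is_noise_only(self):
        fld = make_stimulus(ContourSpec(), seed=3, target_present=False,
                            render=False)
        assert len(fld.elements) == 256
        assert fld.elements["is_contour"].sum() == 0

    def test_noise_orientations_cover_the_axial_range(self):
        fld = make_stimulus(ContourSpec(), seed=12, target_present=False,
                            render=False)
        o = fld.elements["orientation_deg"]
        assert o.min() >= 0 and o.max() < 180
        assert o.std() > 30  # spread out, not clustered

    def test_identical_seeds_give_bit_identical_images(self):
        spec = ContourSpec(curvature_angle_deg=10, end_direction_deg=20)
        a = make_stimulus(spec, seed=21)
        b = make_stimulus(spec, seed=21)
        assert np.array_equal(a.image, b.image)

    def test_noise_fill_respects_placed_elements(self):
        path = build_contour_path(ContourSpec(curvature_angle_deg=30))
        placed = place_contour_in_grid(path, rng_seed=2)
        fld = fill_noise_and_render(placed, rng_seed=2, render=False)
        contour_cells = set(zip(placed["cell_row"], placed["cell_col"]))
        noise = fld.elements[~fld.elements["is_contour"]]
        noise_cells = set(zip(noise["cell_row"], noise["cell_col"]))
        assert contour_cells.isdisjoint(noise_cells)


class TestConditions:
    def test_experiment1_grid(self):
        c = enumerate_conditions(1)
        assert len(c) == 50
        assert int((c["reps_per_block"]).sum()) == 1250
        assert set(c["contour_angle_deg"]) == {0, 10, 20, 30, 40}
        # the straight contour uses the longer 0.75 deg spacing
        assert (c.loc[c["contour_angle_deg"] == 0, "core_separation_deg"] == 0.75).all()
        assert (c.loc[c["contour_angle_deg"] != 0, "core_separation_deg"] == 0.5).all()

    def test_experiment2_grid(self):
        c = enumerate_conditions(2)
        assert len(c) == 22
        assert int(c["is_baseline"].sum()) == 2
        main = c[~c["is_baseline"]]
        assert len(main) == 20
        assert set(main["end_separation_deg"]) == {0.5, 0.75, 1.0, 1.5, 2.0}
        assert set(main["shape"]) == {"C", "S"}
        assert set(main["end_direction_deg"]) == {0, 30}

    def test_unknown_experiment_raises(self):
        with pytest.raises(ValueError):
            enumerate_conditions(3)

    def test_exp2_conditions_all_place(self):
        for _, row in enumerate_conditions(2).iterrows():
            spec = ContourSpec(
                n_elements=int(row["n_elements"]),
                curvature_angle_deg=row["contour_angle_deg"],
                end_direction_deg=0.0 if np.isnan(row["end_direction_deg"])
                else row["end_direction_deg"],
                end_separation_deg=CELL_DEG if np.isnan(row["end_separation_deg"])
                else row["end_separation_deg"],
                core_separation_deg=row["core_separation_deg"],
                shape=row["shape"])
            fld = make_stimulus(spec, seed=11, render=False)
            assert len(fld.elements) == 256
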