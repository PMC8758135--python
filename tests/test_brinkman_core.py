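import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brinkswim.brinkman_core import (
    FlowField,
    ForceElement,
    GridSpec,
    Medium,
    Pose,
    SpectralField,
    SwimmerModel,
    gaussian_spectral_green,
    liron_mochon_far_field,
    multi_swimmer_flow,
    point_stokeslet_closed_form,
    read_flowfield_csv,
    read_flowfield_hdf5,
    spectral_green,
    swimmer_preset,
    synthesize_flow,
    write_flowfield_csv,
    write_flowfield_hdf5,
)

# medium with eta_pn == 1 so spectral amplitudes can be checked against
# the bare formula
UNIT_MEDIUM = Medium(H=10.0, eta=1000.0)


class TestMedium:
    def test_kappa_is_pi_over_H(self):
        for H in (5.0, 10.0, 30.0):
            assert Medium(H=H).kappa == np.pi / H

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_height(self, bad):
        with pytest.raises(ValueError):
            Medium(H=bad)

    def test_invalid_viscosity(self):
        with pytest.raises(ValueError):
            Medium(H=10.0, eta=-1.0)


class TestSpectralGreen:
    def test_zero_force(self):
        k = np.array([1.3, -0.4])
        assert np.allclose(spectral_green(k, np.zeros(2), UNIT_MEDIUM), 0.0)

    def test_longitudinal_annihilated(self):
        # k parallel to F: the transverse projector kills everything
        k = np.array([2.5, 0.0])
        F = np.array([3.0, 0.0])
        assert np.allclose(spectral_green(k, F, UNIT_MEDIUM), 0.0)

    def test_transverse_amplitude(self):
        # k perp F with |k| = pi/H, |F| = 1, eta = 1: amplitude H^2/(2 pi^2)
        H = 10.0
        k = np.array([0.0, np.pi / H])
        F = np.array([1.0, 0.0])
        v = spectral_green(k, F, UNIT_MEDIUM)
        assert v[1] == 0.0
        assert np.isclose(v[0], H**2 / (2 * np.pi**2))

    def test_k_zero_mode(self):
        assert np.allclose(spectral_green(np.zeros(2), np.ones(2), UNIT_MEDIUM), 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            spectral_green(np.array([np.nan, 0.0]), np.ones(2), UNIT_MEDIUM)

    def test_transversality_property(self, rng):
        k = rng.normal(size=(200, 2))
        F = np.array([1.0, -2.0])
        vk = spectral_green(k, F, UNIT_MEDIUM)
        sf = SpectralField(k, vk.astype(complex))
        assert sf.max_transversality_residual() < 1e-12


class TestGaussianSpectralGreen:
    def test_sigma_zero_reduces_to_point(self, rng):
        k = rng.normal(size=(50, 2))
        F = np.array([0.7, 1.1])
        np.testing.assert_allclose(
            gaussian_spectral_green(k, F, 0.0, UNIT_MEDIUM),
            spectral_green(k, F, UNIT_MEDIUM),
        )

    def test_k_zero(self):
        assert np.allclose(
            gaussian_spectral_green(np.zeros(2), np.ones(2), 2.0, UNIT_MEDIUM), 0.0
        )

    def test_large_sigma_decay(self):
        k = np.array([0.0, 1.0])
        F = np.array([1.0, 0.0])
        v = gaussian_spectral_green(k, F, 50.0, UNIT_MEDIUM)
        assert np.linalg.norm(v) < 1e-10

    def test_negative_sigma(self):
        with pytest.raises(ValueError):
            gaussian_spectral_green(np.ones(2), np.ones(2), -1.0, UNIT_MEDIUM)


class TestPresets:
    def test_names_and_geometry(self):
        two = swimmer_preset("two_gaussian")
        assert len(two.elements) == 2
        assert two.elements[0].position == (6.0, 11.0)
        assert two.elements[1].position == (6.0, -11.0)
        assert all(el.spread == 5.0 for el in two.elements)
        three = swimmer_preset("three_stokeslet")
        assert len(three.elements) == 3
        assert three.elements[2].strength == (11.31, 0.0)
        assert all(el.spread == 0.0 for el in three.elements)

    def test_forces_sum(self):
        # two-force presets are net force monopoles, three-force are neutral
        two = swimmer_preset("two_stokeslet", F0=4.0)
        assert np.isclose(sum(el.strength[0] for el in two.elements), -4.0)
        three = swimmer_preset("three_gaussian", F0=4.0)
        assert np.isclose(sum(el.strength[0] for el in three.elements), 0.0)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            swimmer_preset("four_stokeslet")

    def test_presets_immutable(self):
        m = swimmer_preset("two_gaussian")
        with pytest.raises(AttributeError):
            m.elements = ()

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            SwimmerModel((), Medium(H=10.0))


class TestSynthesizeFlow:
    def test_linearity_duplicate_half_strength(self):
        med = Medium(H=10.0)
        grid = GridSpec.centered(30.0, 1.0)
        single = SwimmerModel(
            (ForceElement((3.0, 2.0), (1.0, 0.5), 4.0),), med
        )
        doubled = SwimmerModel(
            (
                ForceElement((3.0, 2.0), (0.5, 0.25), 4.0),
                ForceElement((3.0, 2.0), (0.5, 0.25), 4.0),
            ),
            med,
        )
        fa = synthesize_flow(single, grid)
        fb = synthesize_flow(doubled, grid)
        np.testing.assert_allclose(fa.vx, fb.vx, atol=1e-12)
        np.testing.assert_allclose(fa.vy, fb.vy, atol=1e-12)

    def test_strength_scaling(self):
        med = Medium(H=10.0)
        grid = GridSpec.centered(20.0, 1.0)
        m1 = SwimmerModel((ForceElement((0.0, 0.0), (1.0, 0.0), 3.0),), med)
        m2 = SwimmerModel((ForceElement((0.0, 0.0), (2.0, 0.0), 3.0),), med)
        f1 = synthesize_flow(m1, grid)
        f2 = synthesize_flow(m2, grid)
        np.testing.assert_allclose(2 * f1.vx, f2.vx, atol=1e-12)

    def test_mirror_symmetry(self, two_gaussian_field):
        # y-symmetric model with x-directed forces
        vx = two_gaussian_field.vx
        vy = two_gaussian_field.vy
        np.testing.assert_allclose(vx, vx[:, ::-1], atol=1e-9 * np.abs(vx).max())
        np.testing.assert_allclose(vy, -vy[:, ::-1], atol=1e-9 * np.abs(vx).max())

    def test_anterior_stagnation_distance(self, two_gaussian_field):
        from brinkswim.flow_features import find_stagnation_on_axis

        d = find_stagnation_on_axis(two_gaussian_field, x_min=6.0)
        assert d == pytest.approx(13.0, abs=1.0)

    def test_discrete_incompressibility(self, two_gaussian_field):
        ff = two_gaussian_field
        div = ff.divergence()
        gx = np.gradient(ff.vx, ff.spacing[0], axis=0)
        gy = np.gradient(ff.vy, ff.spacing[1], axis=1)
        gxy = np.gradient(ff.vx, ff.spacing[1], axis=1)
        gyx = np.gradient(ff.vy, ff.spacing[0], axis=0)
        scale = np.max(np.sqrt(gx**2 + gy**2 + gxy**2 + gyx**2))
        assert np.max(np.abs(div)) / scale < 1e-2

    def test_point_core_masked(self):
        field = synthesize_flow(
            swimmer_preset("two_stokeslet", H=10.0), GridSpec.centered(40.0, 1.0)
        )
        assert field.mask is not None
        xg, yg = field.meshgrid()
        at_core = np.hypot(xg - 6.0, yg - 11.0) < 0.25
        assert field.mask[at_core].all()

    def test_geometry_invariant_to_force_scale(self):
        from brinkswim.flow_features import find_stagnation_on_axis

        grid = GridSpec.centered(60.0, 1.0)
        d = [
            find_stagnation_on_axis(
                synthesize_flow(swimmer_preset("two_gaussian", F0=F0), grid), x_min=6.0
            )
            for F0 in (1.0, 11.31)
        ]
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_aliasing_warning(self):
        med = Medium(H=10.0)
        m = SwimmerModel((ForceElement((500.0, 0.0), (1.0, 0.0), 2.0),), med)
        with pytest.warns(UserWarning, match="aliasing"):
            synthesize_flow(m, GridSpec.centered(20.0, 1.0))


class TestClosedForm:
    def test_fft_agreement_random_points(self):
        # 50 random points in 2 um < r < 20 um, offset-corrected (the FFT
        # field carries the zero-mean k = 0 convention)
        med = Medium(H=10.0)
        model = SwimmerModel((ForceElement((0.0, 0.0), (1.0, 0.0), 0.0),), med)
        grid = GridSpec.centered(60.0, 0.5)
        ff = synthesize_flow(model, grid, internal_spacing=0.125, pad_factor=4.0)
        rng = np.random.default_rng(7)
        r = rng.uniform(2.0, 20.0, size=50)
        th = rng.uniform(0, 2 * np.pi, size=50)
        # snap to grid nodes
        ix = np.rint((r * np.cos(th) - ff.origin[0]) / ff.spacing[0]).astype(int)
        iy = np.rint((r * np.sin(th) - ff.origin[1]) / ff.spacing[1]).astype(int)
        pts = np.column_stack([ff.x[ix], ff.y[iy]])
        v_fft = np.column_stack([ff.vx[ix, iy], ff.vy[ix, iy]])
        v_cf = point_stokeslet_closed_form(pts, np.array([1.0, 0.0]), med)
        diff = v_fft - v_cf
        diff -= diff.mean(axis=0)
        rel = np.sqrt(np.sum(diff**2) / np.sum(v_cf**2))
        assert rel < 1e-3

    def test_linearity(self):
        med = Medium(H=10.0)
        pts = np.array([[3.0, 4.0], [-7.0, 2.0]])
        F = np.array([1.0, -0.5])
        v1 = point_stokeslet_closed_form(pts, F, med)
        v2 = point_stokeslet_closed_form(pts, 2 * F, med)
        np.testing.assert_allclose(v2, 2 * v1)

    def test_singularity(self):
        with pytest.raises(ValueError):
            point_stokeslet_closed_form(np.zeros(2), np.ones(2), Medium(H=10.0))

    def test_far_field_slope_minus_two(self):
        med = Medium(H=10.0)
        F = np.array([1.0, 0.0])
        rr = np.array([30.0, 40.0, 60.0, 80.0])
        th = 0.7
        pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        v = np.linalg.norm(point_stokeslet_closed_form(pts, F, med), axis=1)
        slope = np.polyfit(np.log(rr), np.log(v), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.02)

    def test_far_field_dipolar_pattern(self):
        # kappa r >> 1: v ~ (2 r_hat r_hat - I) . F / r^2
        med = Medium(H=10.0)
        F = np.array([1.0, 0.0])
        r = 60.0
        for th in (0.0, 0.9, 2.1):
            pt = np.array([r * np.cos(th), r * np.sin(th)])
            v = point_stokeslet_closed_form(pt, F, med)
            rhat = pt / r
            pattern = 2 * rhat * (rhat @ F) - F
            expected = pattern / (2 * np.pi * med.eta_pn * med.kappa**2 * r**2)
            np.testing.assert_allclose(v, expected, rtol=0.02)

    def test_screening_monotonicity(self):
        # fixed F and r: |v| decreases as H decreases (kappa increases)
        pt = np.array([8.0, 3.0])
        F = np.array([1.0, 0.0])
        mags = [
            np.linalg.norm(point_stokeslet_closed_form(pt, F, Medium(H=H)))
            for H in (30.0, 20.0, 10.0, 5.0)
        ]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_sigma_continuity(self):
        # Gaussian field converges monotonically to the point field at a
        # fixed probe as sigma -> 0 (both via the same FFT discretization
        # so the k = 0 offset cancels)
        med = Medium(H=10.0)
        grid = GridSpec.centered(20.0, 0.5)
        probe_idx = None
        vals = {}
        for sig in (0.0, 2.0, 1.0, 0.5, 0.25):
            m = SwimmerModel((ForceElement((0.0, 0.0), (1.0, 0.0), sig),), med)
            ff = synthesize_flow(m, grid, internal_spacing=0.0625, mask_point_cores=False)
            if probe_idx is None:
                ix = int(np.argmin(np.abs(ff.x - 4.0)))
                iy = int(np.argmin(np.abs(ff.y - 3.0)))
                probe_idx = (ix, iy)
            vals[sig] = np.array([ff.vx[probe_idx], ff.vy[probe_idx]])
        errs = [np.linalg.norm(vals[s] - vals[0.0]) for s in (2.0, 1.0, 0.5, 0.25)]
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 0.05 * np.linalg.norm(vals[0.0])


class TestLironMochon:
    def test_inverse_square_decay(self):
        med = Medium(H=10.0)
        F = np.array([1.0, 0.0])
        v1 = liron_mochon_far_field(np.array([20.0, 5.0]), F, med)
        v2 = liron_mochon_far_field(np.array([40.0, 10.0]), F, med)
        np.testing.assert_allclose(np.linalg.norm(v2), np.linalg.norm(v1) / 4, rtol=1e-12)

    def test_ratio_to_brinkman_constant(self):
        # along a fixed ray the ratio to the screened Stokeslet tends to a
        # constant (same dipolar far field)
        med = Medium(H=10.0)
        F = np.array([1.0, 0.0])
        th = 0.6
        ratios = []
        for r in (5 * med.H, 10 * med.H, 20 * med.H):
            pt = np.array([r * np.cos(th), r * np.sin(th)])
            lm = np.linalg.norm(liron_mochon_far_field(pt, F, med))
            bk = np.linalg.norm(point_stokeslet_closed_form(pt, F, med))
            ratios.append(lm / bk)
        assert max(ratios) / min(ratios) < 1.01

    def test_zero_force(self):
        v = liron_mochon_far_field(np.array([5.0, 5.0]), np.zeros(2), Medium(H=10.0))
        assert np.allclose(v, 0.0)

    def test_singularity(self):
        with pytest.raises(ValueError):
            liron_mochon_far_field(np.zeros(2), np.ones(2), Medium(H=10.0))


class TestMultiSwimmer:
    def test_single_identity_equals_synthesize(self):
        m = swimmer_preset("two_gaussian")
        grid = GridSpec.centered(30.0, 1.0)
        fa = synthesize_flow(m, grid)
        fb = multi_swimmer_flow([m], grid)
        np.testing.assert_allclose(fa.vx, fb.vx)
        np.testing.assert_allclose(fa.vy, fb.vy)

    def test_antisymmetry_under_180_rotation(self):
        m = swimmer_preset("two_gaussian")
        a = m.with_pose(-15.0, 0.0, 0.0)
        b = m.with_pose(15.0, 0.0, np.pi)
        grid = GridSpec.centered(60.0, 1.0)
        ff = multi_swimmer_flow([a, b], grid)
        # rotation by pi about the origin: v(-r) = -v(r)
        np.testing.assert_allclose(ff.vx, -ff.vx[::-1, ::-1], atol=1e-9 * np.abs(ff.vx).max())
        np.testing.assert_allclose(ff.vy, -ff.vy[::-1, ::-1], atol=1e-9 * np.abs(ff.vx).max())

    def test_probe_equals_sum_of_singles(self, rng):
        base = swimmer_preset("two_gaussian")
        models = [
            base.with_pose(*rng.uniform(-20, 20, size=2), rng.uniform(0, 2 * np.pi))
            for _ in range(4)
        ]
        grid = GridSpec.centered(50.0, 1.0)
        total = multi_swimmer_flow(models, grid)
        acc_x = np.zeros(total.shape)
        acc_y = np.zeros(total.shape)
        for m in models:
            f = synthesize_flow(m, grid)
            acc_x += f.vx
            acc_y += f.vy
        i, j = 12, 31
        assert abs(total.vx[i, j] - acc_x[i, j]) <= 1e-6 * abs(acc_x[i, j])
        assert abs(total.vy[i, j] - acc_y[i, j]) <= 1e-6 * max(abs(acc_y[i, j]), 1e-12)

    def test_overlap_warning(self):
        m = swimmer_preset("two_gaussian")
        with pytest.warns(UserWarning, match="overlap"):
            multi_swimmer_flow([m, m], GridSpec.centered(30.0, 1.0))

    def test_empty_list(self):
        with pytest.raises(ValueError):
            multi_swimmer_flow([], GridSpec.centered(30.0, 1.0))


class TestIO:
    def test_csv_roundtrip(self, tmp_path, two_gaussian_field):
        p = tmp_path / "field.csv"
        write_flowfield_csv(two_gaussian_field, p)
        back = read_flowfield_csv(p)
        np.testing.assert_allclose(back.vx, two_gaussian_field.vx, rtol=1e-12)
        np.testing.assert_allclose(back.vy, two_gaussian_field.vy, rtol=1e-12)
        assert back.spacing == two_gaussian_field.spacing

    def test_csv_mask_roundtrip(self, tmp_path):
        ff = synthesize_flow(
            swimmer_preset("two_stokeslet"), GridSpec.centered(30.0, 1.0)
        )
        p = tmp_path / "f.csv"
        write_flowfield_csv(ff, p)
        back = read_flowfield_csv(p)
        np.testing.assert_array_equal(back.mask, ff.mask)

    def test_hdf5_roundtrip(self, tmp_path, two_gaussian_field):
        p = tmp_path / "field.h5"
        write_flowfield_hdf5(two_gaussian_field, p)
        back = read_flowfield_hdf5(p)
        np.testing.assert_allclose(back.vx, two_gaussian_field.vx)
        assert back.frame == two_gaussian_field.frame

    def test_model_config_roundtrip(self, tmp_path):
        m = swimmer_preset("three_gaussian", H=30.0).with_pose(2.0, -1.0, 0.3)
        p = tmp_path / "model.json"
        p.write_text(json.dumps(m.to_config()))
        from brinkswim.brinkman_core import load_model_config

        back = load_model_config(p)
        assert back.medium.H == 30.0
        assert back.elements == m.elements
        assert back.pose == m.pose


@given(
    fx=st.floats(-5, 5, allow_nan=False),
    fy=st.floats(-5, 5, allow_nan=False),
    kx=st.floats(-3, 3, allow_nan=False),
    ky=st.floats(-3, 3, allow_nan=False),
)
@settings(max_examples=50, deadline=None)
def test_spectral_green_transverse_always(fx, fy, kx, ky):
    k = np.array([kx, ky])
    v = spectral_green(k, np.array([fx, fy]), UNIT_MEDIUM)
    assert abs(np.dot(k, v)) < 1e-9 * max(1.0, np.linalg.norm(v) * np.linalg.norm(k))
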