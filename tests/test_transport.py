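import math

import numpy as np
import pytest
from scipy import stats

import brainbeam as bb
from brainbeam.tissue_model import LabeledVolume, OpticalPropertyTable
from brainbeam.transport import (
    C_MM_PER_S,
    advance_time,
    fresnel_interface,
    fresnel_reflectance,
    hg_cos_theta,
    sample_free_path,
    scatter_hg,
)

RNG = 12345


def homogeneous(shape, voxel_mm, mua, mus, g, n):
    vol = LabeledVolume(labels=np.ones(shape, np.uint8), voxel_size_mm=voxel_mm)
    props = OpticalPropertyTable(rows={0: (0.0, 0.0, 1.0, 1.0), 1: (mua, mus, g, n)})
    return vol, props


class TestFreePath:
    def test_exponential_mean(self):
        draws = sample_free_path(1.0, RNG, size=1_000_000)
        assert abs(draws.mean() - 1.0) < 4.0 / math.sqrt(1e6)

    def test_scalp_interaction_length(self):
        """Scalp mu_t = mu_a + mu_s = 19.018/mm: mean free path 1/19.018 mm."""
        mut = 0.018 + 19.0
        draws = sample_free_path(mut, RNG, size=1_000_000)
        assert abs(draws.mean() - 1 / mut) < 4.0 / (mut * math.sqrt(1e6))

    def test_doubling_rate_halves_path(self):
        a = sample_free_path(1.0, 7, size=100_000)
        b = sample_free_path(2.0, 7, size=100_000)  # paired draws, same stream
        assert np.allclose(a, 2 * b)

    def test_nonpositive_rate_is_ballistic(self):
        assert np.isinf(sample_free_path(0.0, RNG, size=10)).all()


class TestHenyeyGreenstein:
    def test_isotropic_limit_is_uniform(self):
        cost = hg_cos_theta(0.0, RNG, size=1_000_000)
        assert stats.kstest(cost, stats.uniform(-1, 2).cdf).pvalue > 1e-4

    @pytest.mark.parametrize("g", [0.5, 0.9])
    def test_mean_cosine_equals_g(self, g):
        cost = hg_cos_theta(g, RNG, size=1_000_000)
        assert cost.min() >= -1 and cost.max() <= 1
        assert abs(cost.mean() - g) < 4.0 * cost.std() / math.sqrt(1e6)

    def test_scatter_preserves_norm_and_mean_deflection(self):
        rng = np.random.default_rng(RNG)
        d = np.array([0.48, -0.6, 0.64]) / np.linalg.norm([0.48, -0.6, 0.64])
        dots = []
        for _ in range(20_000):
            new = scatter_hg(d, 0.9, rng)
            assert abs(np.linalg.norm(new) - 1.0) < 1e-12
            dots.append(float(new @ d))
        assert abs(np.mean(dots) - 0.9) < 4.0 * np.std(dots) / math.sqrt(len(dots))


class TestFresnel:
    def test_normal_incidence_scalp_skull(self):
        """R = ((1.43-1.37)/(1.43+1.37))^2 at normal incidence."""
        expected = ((1.43 - 1.37) / (1.43 + 1.37)) ** 2
        assert fresnel_reflectance(1.0, 1.37, 1.43) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.59e-4, abs=1e-6)

    def test_matched_media_transmit(self):
        d = np.array([0.0, 0.6, 0.8])
        out, reflected = fresnel_interface(d, np.array([0.0, 0.0, 1.0]), 1.4, 1.4, RNG)
        assert not reflected
        assert np.allclose(out, d, atol=1e-12)

    def test_total_internal_reflection_skull_to_csf(self):
        """Critical angle arcsin(1.33/1.43) ~ 68.5 deg; 75 deg always reflects."""
        th = math.radians(75.0)
        assert th > math.asin(1.33 / 1.43)
        assert fresnel_reflectance(math.cos(th), 1.43, 1.33) == 1.0
        d = np.array([math.sin(th), 0.0, math.cos(th)])
        rng = np.random.default_rng(RNG)
        for _ in range(20):
            out, reflected = fresnel_interface(d, np.array([0, 0, 1.0]), 1.43, 1.33, rng)
            assert reflected
            assert np.allclose(out, [math.sin(th), 0.0, -math.cos(th)], atol=1e-12)

    def test_refraction_obeys_snell(self):
        th = math.radians(30.0)
        d = np.array([math.sin(th), 0.0, math.cos(th)])
        rng = np.random.default_rng(RNG)
        # at 30 deg 1.33 -> 1.43, R < 1e-2: nearly every draw refracts
        outs = [fresnel_interface(d, np.array([0, 0, 1.0]), 1.33, 1.43, rng) for _ in range(50)]
        refr = [o for o, refl in outs if not refl]
        assert refr
        sin_t = np.hypot(refr[0][0], refr[0][1])
        assert sin_t == pytest.approx(1.33 / 1.43 * math.sin(th), abs=1e-12)
        assert abs(np.linalg.norm(refr[0]) - 1.0) < 1e-12

    def test_non_unit_inputs_rejected(self):
        with pytest.raises(ValueError):
            fresnel_interface([0, 0, 2.0], [0, 0, 1.0], 1.0, 1.4, RNG)


class TestTime:
    def test_one_mm_in_scalp(self):
        assert advance_time(1.0, 1.37) == pytest.approx(1.37 / C_MM_PER_S)
        assert advance_time(1.0, 1.37) == pytest.approx(4.57e-12, rel=1e-2)

    def test_zero_path_keeps_clock(self):
        assert advance_time(0.0, 1.4, t_s=3.3e-9) == 3.3e-9

    def test_gate_inert_at_tissue_scale(self):
        # even 10 m of optical path stays inside the 5e-8 s gate
        assert advance_time(1e4, 1.4) < 5e-8

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            advance_time(-1.0, 1.4)


class TestTransportPhysics:
    def test_beer_lambert_in_pure_absorber(self):
        """Unscattered pencil beam: on-axis F(z) ~ exp(-mu_a z)."""
        vol, props = homogeneous((40, 40, 120), 0.1, mua=1.0, mus=0.0, g=0.0, n=1.0)
        src = bb.SourceSpec(type_tag="pencil", center_mm=(2.0, 2.0, 0.0))
        E = bb.run_simulation(vol, props, src, bb.SimConfig(n_photons=2_000, rng_seed=1))
        col = E.F[20, 20, :]
        z = (np.arange(120) + 0.5) * 0.1
        slope = np.polyfit(z[5:100], np.log(col[5:100]), 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.02)

    def test_no_absorption_means_no_absorbed_energy(self):
        vol, props = homogeneous((30, 30, 30), 0.1, mua=0.0, mus=5.0, g=0.5, n=1.0)
        src = bb.SourceSpec(type_tag="isotropic", center_mm=(1.5, 1.5, 1.5))
        E = bb.run_simulation(vol, props, src, bb.SimConfig(n_photons=20_000, rng_seed=2))
        assert E.A.sum() == 0.0
        assert E.escaped_energy + E.residual_energy == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("tag", ["pencil", "isotropic", "ring", "line", "spatial_freq_fourier"])
    def test_energy_conservation(self, head_volume, props, tag):
        E = bb.run_simulation(
            head_volume, props, bb.SourceSpec(type_tag=tag), bb.SimConfig(n_photons=50_000, rng_seed=3)
        )
        assert abs(E.energy_closure() - 1.0) < 1e-6

    def test_absorption_is_mua_times_fluence(self, small_pencil_run, head_volume, props):
        mua = props.as_arrays()[0]
        expected = mua[head_volume.labels] * small_pencil_run.F
        assert np.array_equal(small_pencil_run.A, expected)

    def test_voxel_traversal_recovers_chord_length(self):
        """With interactions off, summed segment lengths equal the chord."""
        vol, props = homogeneous((140, 140, 140), 0.1, mua=0.0, mus=0.0, g=0.0, n=1.0)
        th = math.radians(30.0)
        src = bb.SourceSpec(type_tag="pencil", direction=(math.sin(th), 0.0, math.cos(th)))
        E = bb.run_simulation(vol, props, src, bb.SimConfig(n_photons=10, rng_seed=4))
        # beam from (7,7,0) at 30 deg exits the x = 14 mm face after 14 mm
        chord = (14.0 - 7.0) / math.sin(th)
        total_track = E.F.sum() * E.voxel_volume_mm3
        assert total_track == pytest.approx(chord, rel=1e-9)
        assert E.escaped_energy == pytest.approx(1.0, abs=1e-12)

    def test_bit_identical_for_same_seed(self, head_volume, props):
        cfg = bb.SimConfig(n_photons=20_000, rng_seed=11)
        src = bb.SourceSpec(type_tag="disk")
        a = bb.run_simulation(head_volume, props, src, cfg)
        b = bb.run_simulation(head_volume, props, src, cfg)
        assert a.F.tobytes() == b.F.tobytes()
        assert a.escaped_energy == b.escaped_energy
        c = bb.run_simulation(head_volume, props, src, bb.SimConfig(n_photons=20_000, rng_seed=12))
        assert a.F.tobytes() != c.F.tobytes()

    def test_max_steps_guard_scores_residual(self, head_volume, props):
        E = bb.run_simulation(
            head_volume,
            props,
            bb.SourceSpec(type_tag="pencil"),
            bb.SimConfig(n_photons=2_000, rng_seed=5, max_steps=50),
        )
        assert E.residual_energy > 0.0
        assert abs(E.energy_closure() - 1.0) < 1e-6

    def test_time_gate_scores_residual(self, head_volume, props):
        E = bb.run_simulation(
            head_volume,
            props,
            bb.SourceSpec(type_tag="pencil"),
            bb.SimConfig(n_photons=2_000, rng_seed=5, t_end=1e-13),
        )
        assert E.residual_energy > 0.9

    def test_specular_launch_option(self, head_volume, props):
        src = bb.SourceSpec(type_tag="pencil")
        base = bb.run_simulation(head_volume, props, src, bb.SimConfig(n_photons=20_000, rng_seed=6))
        spec = bb.run_simulation(
            head_volume, props, src, bb.SimConfig(n_photons=20_000, rng_seed=6, specular_at_launch=True)
        )
        R = ((1.37 - 1.0) / (1.37 + 1.0)) ** 2
        expected = R + (1 - R) * base.escaped_energy
        assert spec.escaped_energy == pytest.approx(expected, abs=2e-3)

    def test_missing_property_label_rejected(self, head_volume):
        table = OpticalPropertyTable(rows={0: (0.0, 0.0, 1.0, 1.0), 1: (0.1, 1.0, 0.9, 1.4)})
        with pytest.raises(ValueError):
            bb.run_simulation(head_volume, table, bb.SourceSpec(type_tag="pencil"), bb.SimConfig(n_photons=10))

    def test_diffusion_theory_point_source(self):
        """Isotropic point source in an infinite homogeneous medium:
        F(r) = exp(-mu_eff r) / (4 pi D r) within 10% at 2-5 transport lengths."""
        mua, mus, g = 0.018, 19.0, 0.9
        nv, dxv = 120, 0.2
        vol, props = homogeneous((nv, nv, nv), dxv, mua=mua, mus=mus, g=g, n=1.37)
        ctr = nv * dxv / 2
        src = bb.SourceSpec(type_tag="isotropic", center_mm=(ctr, ctr, ctr))
        E = bb.run_simulation(
            vol, props, src, bb.SimConfig(n_photons=50_000, rng_seed=8, roulette_threshold=1e-2)
        )
        musp = mus * (1 - g)
        D = 1.0 / (3 * (mua + musp))
        mueff = math.sqrt(mua / D)
        ltr = 1.0 / (mua + musp)
        x = (np.arange(nv) + 0.5) * dxv - ctr
        R = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2)
        for r in np.arange(2.0, 5.01, 0.5) * ltr:
            shell = (R > r - dxv / 2) & (R <= r + dxv / 2)
            ratio = E.F[shell].mean() / (math.exp(-mueff * r) / (4 * math.pi * D * r))
            assert ratio == pytest.approx(1.0, abs=0.10)
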