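"""Virtual sectioning: transforms, grey/domain cuts, compositing, tiles."""

import numpy as np
import pytest

from emas.intervals import from_mask, to_mask
from emas.morphology import StructuringSpec, dilate
from emas.sectioning import (
    CompoundObject,
    GreyVolume,
    Layer,
    SectionSpec,
    composite,
    cut_domain_section,
    cut_section,
    get_tile,
    render_section,
    section_transform,
)
from emas.synthetic import make_phantom_volume

from conftest import random_domain


@pytest.fixture(scope="module")
def phantom():
    return make_phantom_volume(seed=8, shape=(32, 40, 36))


class TestSectionTransform:
    def test_zero_angles_is_axis_aligned(self):
        spec = SectionSpec(fixed_point=(0, 0, 0), distance=5, width=10, height=10)
        tf = section_transform(spec)
        xyz = tf.forward(np.array([[3.0, 7.0]]))[0]
        assert np.allclose(xyz, [3.0, 7.0, 5.0])

    def test_composed_rotations_match_matrix_oracle(self, rng):
        def rz(a):
            a = np.deg2rad(a)
            return np.array(
                [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
            )

        def rx(a):
            a = np.deg2rad(a)
            return np.array(
                [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
            )

        for _ in range(20):
            yaw, pitch, roll = rng.uniform(-180, 180, 3)
            spec = SectionSpec(pitch=pitch, yaw=yaw, roll=roll, width=4, height=4)
            tf = section_transform(spec)
            r = rz(yaw) @ rx(pitch) @ rz(roll)
            assert np.allclose(tf.e_u, r @ [1, 0, 0])
            assert np.allclose(tf.e_v, r @ [0, 1, 0])
            assert np.allclose(tf.normal, r @ [0, 0, 1])

    def test_forward_inverse_roundtrip(self, rng):
        spec = SectionSpec(
            fixed_point=(10, 20, 5),
            pitch=31.0,
            yaw=-47.0,
            roll=112.0,
            distance=6.5,
            scale=1.7,
            width=8,
            height=8,
            origin=(-3.0, 2.0),
        )
        tf = section_transform(spec, spacing=(1.0, 1.5, 2.0))
        uv = rng.uniform(-200, 200, size=(1000, 2))
        back = tf.inverse(tf.forward(uv))
        assert np.abs(back[:, :2] - uv).max() < 1e-9
        assert np.abs(back[:, 2]).max() < 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(scale=0)
        with pytest.raises(ValueError):
            SectionSpec(width=0)


class TestCutSection:
    def test_zero_angles_reproduce_stored_slices(self, phantom):
        vol, _ = phantom
        nz, ny, nx = vol.data.shape
        for k in range(nz):
            spec = SectionSpec(distance=k, width=nx, height=ny)
            assert np.array_equal(cut_section(vol, spec, "nearest"), vol.data[k])

    def test_section_outside_volume_is_background(self, phantom):
        vol, _ = phantom
        spec = SectionSpec(distance=-500, width=8, height=8)
        sec = cut_section(vol, spec, "trilinear", background=7.5)
        assert (sec == 7.5).all()

    def test_roll_180_rotates_image(self, phantom):
        vol, _ = phantom
        nz, ny, nx = vol.data.shape
        c = ((nx - 1) / 2, (ny - 1) / 2, nz / 2)
        base = SectionSpec(
            fixed_point=c, width=nx, height=ny, origin=(-(nx - 1) / 2, -(ny - 1) / 2)
        )
        rolled = SectionSpec(
            fixed_point=c,
            roll=180.0,
            width=nx,
            height=ny,
            origin=(-(nx - 1) / 2, -(ny - 1) / 2),
        )
        a = cut_section(vol, base, "nearest")
        b = cut_section(vol, rolled, "nearest")
        assert np.allclose(b, a[::-1, ::-1])

    def test_spherical_phantom_rotation_invariance(self):
        vol, _ = make_phantom_volume(seed=5, shape=(48, 48, 48), spherical=True)
        c = ((48 - 1) / 2,) * 3
        rng = np.random.default_rng(0)
        means = []
        for _ in range(8):
            p, y, r = rng.uniform(0, 360, 3)
            spec = SectionSpec(
                fixed_point=c, pitch=p, yaw=y, roll=r,
                width=48, height=48, origin=(-23.5, -23.5),
            )
            means.append(cut_section(vol, spec, "trilinear").mean())
        means = np.array(means)
        assert (means.max() - means.min()) / means.mean() < 0.01


class TestCutDomainSection:
    def test_whole_volume_domain_fills_viewport(self, phantom):
        vol, _ = phantom
        nz, ny, nx = vol.data.shape
        dom = from_mask(np.ones(vol.data.shape, bool), vol.frame)
        spec = SectionSpec(distance=nz // 2, width=nx, height=ny)
        assert cut_domain_section(dom, spec).size == nx * ny

    def test_empty_domain_cuts_empty(self, phantom):
        vol, _ = phantom
        from emas.intervals import IntervalDomain

        spec = SectionSpec(distance=3, width=10, height=10)
        assert cut_domain_section(IntervalDomain.empty(3, vol.frame), spec).is_empty

    def test_matches_dense_cut_oracle(self, rng, phantom):
        vol, _ = phantom
        nz, ny, nx = vol.data.shape
        for _ in range(10):
            dom = random_domain(rng, vol.data.shape, 0.3, vol.frame)
            p, y, r = rng.uniform(-60, 60, 3)
            spec = SectionSpec(
                fixed_point=(nx / 2, ny / 2, nz / 2),
                pitch=p, yaw=y, roll=r,
                distance=rng.uniform(-5, 5),
                width=40, height=40, origin=(-20, -20),
            )
            got = to_mask(cut_domain_section(dom, spec), (40, 40))
            tf = section_transform(spec)
            uu, vv = np.meshgrid(np.arange(40), np.arange(40))
            xyz = np.rint(tf.forward(np.stack([uu.ravel(), vv.ravel()], 1))).astype(int)
            ok = ((xyz >= 0) & (xyz < [nx, ny, nz])).all(1)
            mask = to_mask(dom, vol.data.shape)
            want = np.zeros(1600, bool)
            want[ok] = mask[xyz[ok, 2], xyz[ok, 1], xyz[ok, 0]]
            assert np.array_equal(got, want.reshape(40, 40))

    def test_consistent_under_dilation(self, rng, phantom):
        vol, _ = phantom
        nz, ny, nx = vol.data.shape
        dom = random_domain(rng, vol.data.shape, 0.2, vol.frame)
        spec = SectionSpec(
            fixed_point=(nx / 2, ny / 2, nz / 2), pitch=20, yaw=30,
            width=30, height=30, origin=(-15, -15),
        )
        a = cut_domain_section(dom, spec)
        b = cut_domain_section(dilate(dom, StructuringSpec(1, 26)), spec)
        from emas.intervals import is_subset

        assert is_subset(a, b)


class TestComposite:
    def test_alpha_zero_leaves_grey(self, rng):
        grey = rng.integers(0, 256, size=(10, 10), dtype=np.uint8)
        layer = Layer("l", random_domain(rng, (10, 10), 0.5), colour="#ff0000", alpha=0.0)
        out = composite(grey, [layer])
        assert np.array_equal(out, np.repeat(grey[:, :, None], 3, 2))

    def test_alpha_one_paints_pure_colour(self, rng):
        grey = rng.integers(0, 256, size=(10, 10), dtype=np.uint8)
        dom = random_domain(rng, (10, 10), 0.5)
        out = composite(grey, [Layer("l", dom, colour="#00ff00", alpha=1.0)])
        mask = to_mask(dom, (10, 10))
        assert (out[mask] == [0, 255, 0]).all()
        assert (out[~mask] == np.repeat(grey[:, :, None], 3, 2)[~mask]).all()

    def test_two_overlapping_layers_blend_in_order(self):
        grey = np.zeros((4, 4), dtype=np.uint8)
        full = from_mask(np.ones((4, 4), bool))
        l1 = Layer("a", full, colour=(1.0, 0.0, 0.0), alpha=0.5)
        l2 = Layer("b", full, colour=(0.0, 0.0, 1.0), alpha=0.5)
        out = composite(grey, [l1, l2])
        # 0 -> 0.5 red -> blend half blue over: (0.25, 0, 0.5)
        want = np.rint(np.array([0.25, 0.0, 0.5]) * 255).astype(np.uint8)
        assert (out == want).all(axis=(0, 1)).all()

    def test_overlapping_layers_are_allowed(self, phantom):
        """Compound objects must accept freely overlapping domains; only
        index-image export restricts them."""
        vol, compound = phantom
        # nested anatomy layers all overlap; rendering must not raise
        spec = SectionSpec(distance=vol.data.shape[0] // 2,
                           width=vol.data.shape[2], height=vol.data.shape[1])
        rgb = render_section(vol, compound, spec)
        assert rgb.shape == (vol.data.shape[1], vol.data.shape[2], 3)


class TestTiles:
    def test_single_tile_covers_full_section(self, phantom):
        vol, compound = phantom
        nz, ny, nx = vol.data.shape
        spec = SectionSpec(distance=nz // 2, width=nx, height=ny)
        full = render_section(vol, compound, spec)
        tile = get_tile(vol, compound, spec, (0, 0), tile_size=max(nx, ny))
        assert np.array_equal(tile[:ny, :nx], full)

    def test_mosaic_reassembles_section(self, phantom):
        vol, compound = phantom
        nz, ny, nx = vol.data.shape
        spec = SectionSpec(
            fixed_point=(nx / 2, ny / 2, nz / 2), pitch=15, yaw=25,
            width=nx, height=ny, origin=(-nx / 2, -ny / 2),
        )
        full = render_section(vol, compound, spec)
        ts = 16
        n_i, n_j = -(-nx // ts), -(-ny // ts)
        mosaic = np.zeros((n_j * ts, n_i * ts, 3), np.uint8)
        for j in range(n_j):
            for i in range(n_i):
                mosaic[j * ts : (j + 1) * ts, i * ts : (i + 1) * ts] = get_tile(
                    vol, compound, spec, (i, j), ts
                )
        assert np.array_equal(mosaic[:ny, :nx], full)

    def test_out_of_viewport_tile_rejected(self, phantom):
        vol, compound = phantom
        spec = SectionSpec(distance=3, width=20, height=20)
        with pytest.raises(ValueError):
            get_tile(vol, compound, spec, (5, 0), tile_size=16)
        with pytest.raises(ValueError):
            get_tile(vol, compound, spec, (-1, 0), tile_size=16)


class TestGreyVolume:
    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            GreyVolume(np.zeros((2, 2, 2)), spacing=(1, 0, 1))

    def test_compound_frame_consistency(self, rng, phantom):
        vol, _ = phantom
        other = random_domain(rng, (4, 4, 4))
        with pytest.raises(ValueError, match="frames"):
            CompoundObject(
                [
                    Layer("a", from_mask(np.ones((2, 2, 2), bool), vol.frame)),
                    Layer("b", other),
                ]
            )
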