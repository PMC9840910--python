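"""Renderer and input-encoding tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antsim import vision
from antsim.vision import (BACKGROUND, FOOD_COLOR, Frame, dump_frame, flatten,
                           read_ppm, render_frame, unflatten)
from antsim.world import init_world

from .conftest import tiny_config
from .oracles import random_scene, render_frame_bruteforce


def _scene_arrays(objects):
    centers = np.array([[o["x"], o["y"]] for o in objects]).reshape(-1, 2)
    radii = np.array([o["radius"] for o in objects])
    heights = np.array([o["height"] for o in objects])
    colors = np.array([o["color"] for o in objects]).reshape(-1, 3)
    return centers, radii, heights, colors


class TestRenderer:
    def test_empty_arena_is_uniform_background(self):
        frame = vision.render_scene(5.0, 5.0, 0.3, np.empty((0, 2)),
                                    np.empty(0), np.empty(0), np.empty((0, 3)),
                                    8, 6, math.pi / 2, 10.0)
        assert np.all(frame == np.array(BACKGROUND))

    def test_food_straight_ahead_centered_and_symmetric(self):
        cfg = tiny_config(vision_width=7, vision_height=5,
                          layer_sizes=(105, 5, 3))
        vr = cfg.resolved_view_range
        frame = vision.render_scene(
            10.0, 10.0, 0.0, np.array([[10.0 + vr / 2, 10.0]]),
            np.array([cfg.food_radius]), np.array([cfg.food_height]),
            np.array([FOOD_COLOR]), cfg.vision_width, cfg.vision_height,
            cfg.fov, vr)
        green = np.all(frame == np.array(FOOD_COLOR), axis=2)
        assert green.any()
        # centered on the middle column, mirror-symmetric left/right
        cols = np.flatnonzero(green.any(axis=0))
        assert np.array_equal(cols, (cfg.vision_width - 1) - cols[::-1])
        assert green[:, cfg.vision_width // 2].any()
        # and symmetric about the middle row
        assert np.array_equal(green, green[::-1, :])

    @pytest.mark.parametrize("scene_seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_pixel_oracle(self, scene_seed):
        """The vectorised renderer equals an independent per-pixel oracle."""
        rng = np.random.default_rng(1000 + scene_seed)
        objects = random_scene(rng, n_food=(1, 6), n_org=(1, 4))
        ox, oy = rng.uniform(0, 20, size=2)
        heading = rng.uniform(0, 2 * math.pi)
        W, H, fov, vr = 9, 7, math.pi / 2, 18.0
        expected = render_frame_bruteforce(ox, oy, heading, objects, W, H, fov, vr)
        got = vision.render_scene(ox, oy, heading, *_scene_arrays(objects),
                                  W, H, fov, vr)
        assert np.array_equal(got, expected)

    @pytest.mark.parametrize("scene_seed", [10, 11, 12])
    def test_mirror_symmetry(self, scene_seed):
        """Mirroring the scene about the heading axis mirrors the columns."""
        rng = np.random.default_rng(scene_seed)
        objects = random_scene(rng, n_food=(1, 5), n_org=(0, 3))
        ox, oy, heading = 10.0, 10.0, rng.uniform(0, 2 * math.pi)
        mirrored = []
        for o in objects:     # reflect each object about the heading axis
            dx, dy = o["x"] - ox, o["y"] - oy
            along = dx * math.cos(heading) + dy * math.sin(heading)
            across = -dx * math.sin(heading) + dy * math.cos(heading)
            mx = ox + along * math.cos(heading) - (-across) * math.sin(heading)
            my = oy + along * math.sin(heading) + (-across) * math.cos(heading)
            mirrored.append({**o, "x": mx, "y": my})
        W, H, fov, vr = 8, 6, math.pi / 2, 25.0
        frame = vision.render_scene(ox, oy, heading, *_scene_arrays(objects),
                                    W, H, fov, vr)
        mframe = vision.render_scene(ox, oy, heading, *_scene_arrays(mirrored),
                                     W, H, fov, vr)
        assert np.allclose(mframe, frame[:, ::-1, :], atol=1e-12)

    def test_objects_beyond_view_range_invisible(self):
        frame = vision.render_scene(
            0.0, 0.0, 0.0, np.array([[12.0, 0.0]]), np.array([0.5]),
            np.array([1.0]), np.array([[1.0, 0.0, 0.0]]), 8, 6,
            math.pi / 2, 10.0)
        assert np.all(frame == np.array(BACKGROUND))

    def test_nearer_object_occludes(self):
        frame = vision.render_scene(
            0.0, 0.0, 0.0,
            np.array([[4.0, 0.0], [8.0, 0.0]]), np.array([0.5, 0.5]),
            np.array([5.0, 5.0]),
            np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
            9, 9, math.pi / 2, 20.0)
        center = frame[4, 4]
        assert np.array_equal(center, [1.0, 0.0, 0.0])

    def test_render_frame_excludes_observer(self, config):
        state = init_world(config)
        observer = state.organisms[0]
        frame = render_frame(state, observer, config)
        assert frame.pixels.shape == (config.vision_height, config.vision_width, 3)
        # observer's own colour never appears when no other organism shares it
        own = np.array(observer.color)
        others = [np.array(o.color) for o in state.organisms.values() if o.id != 0]
        if not any(np.allclose(own, c) for c in others):
            assert not np.all(frame.pixels == own, axis=2).any()


class TestFlatten:
    def test_default_resolution_gives_2700_values(self):
        frame = Frame(np.zeros((30, 30, 3)))
        assert flatten(frame).shape == (2700,)

    def test_single_pixel_channel_order(self):
        frame = Frame(np.array([[[0.2, 0.5, 0.9]]]))
        assert np.array_equal(flatten(frame), [0.2, 0.5, 0.9])

    def test_channel_major_layout(self):
        # 2x2 frame: R block row-major first, then G, then B
        px = np.arange(12, dtype=float).reshape(2, 2, 3) / 12
        vec = flatten(Frame(px))
        assert np.array_equal(vec[:4], px[:, :, 0].reshape(-1))
        assert np.array_equal(vec[4:8], px[:, :, 1].reshape(-1))
        assert np.array_equal(vec[8:], px[:, :, 2].reshape(-1))

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**32 - 1))
    def test_roundtrip_identity(self, w, h, seed):
        px = np.random.default_rng(seed).uniform(size=(h, w, 3))
        back = unflatten(flatten(Frame(px)), w, h)
        assert np.array_equal(back.pixels, px)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            unflatten(np.zeros(10), 2, 2)


class TestPPM:
    def test_uniform_frame_scale1(self, tmp_path):
        frame = Frame(np.full((4, 6, 3), 0.5))
        path = tmp_path / "f.ppm"
        dump_frame(frame, path, scale=1)
        header = path.read_text().splitlines()[:3]
        assert header == ["P3", "6 4", "255"]
        back = read_ppm(path)
        assert back.pixels.shape == (4, 6, 3)
        assert np.all(back.pixels == round(0.5 * 255) / 255)

    def test_scale5_expands_each_pixel_to_block(self, tmp_path, rng):
        px = rng.uniform(size=(3, 4, 3))
        path = tmp_path / "f.ppm"
        dump_frame(Frame(px), path, scale=5)
        back = read_ppm(path)
        assert back.pixels.shape == (15, 20, 3)
        for r in range(3):
            for c in range(4):
                block = back.pixels[5 * r:5 * r + 5, 5 * c:5 * c + 5]
                assert np.all(block == block[0, 0])

    def test_roundtrip_reproduces_quantized_intensities(self, tmp_path, rng):
        px = rng.uniform(size=(5, 5, 3))
        path = tmp_path / "f.ppm"
        dump_frame(Frame(px), path, scale=1)
        back = read_ppm(path)
        assert np.array_equal(np.rint(back.pixels * 255), np.rint(px * 255))
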