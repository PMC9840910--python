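"""Independent reference implementations used only as test oracles.

Both deliberately avoid the library's vectorised/JIT code paths: the
renderer oracle decides every pixel on its own with scalar geometry, and
the forward-pass oracle is a plain nested-loop perceptron.
"""

import math

import numpy as np


def render_frame_bruteforce(ox, oy, heading, objects, width, height,
                            fov, view_range,
                            background=(0.5, 0.5, 0.5)):
    """Per-pixel brute-force renderer.

    ``objects`` is a list of dicts with keys x, y, radius, height, color.
    For every pixel independently: cast the column's ray, find the nearest
    intersected disc within view_range by scanning all objects, and colour
    the pixel if its row lies within the billboard's vertical span
    (angular half-height atan(h / (2 d)) against a vertical fov of
    fov * H / W, with a half-row visibility floor).
    """
    frame = np.empty((height, width, 3))
    vfov = fov * height / width
    row_center = (height - 1) / 2.0
    for row in range(height):
        for col in range(width):
            ang = heading + fov / 2 - (col + 0.5) * fov / width
            ux, uy = math.cos(ang), math.sin(ang)
            best_t, best_obj = math.inf, None
            for obj in objects:
                dx, dy = obj["x"] - ox, obj["y"] - oy
                r2 = obj["radius"] ** 2
                proj = ux * dx + uy * dy
                perp = ux * dy - uy * dx
                disc = r2 - perp * perp
                if disc < 0:
                    continue
                if proj <= 0 and dx * dx + dy * dy > r2:
                    continue
                t = max(proj - math.sqrt(disc), 0.0)
                if t > view_range or t >= best_t:
                    continue
                best_t, best_obj = t, obj
            color = background
            if best_obj is not None:
                d = max(best_t, 1e-9)
                alpha = math.atan2(best_obj["height"] / 2.0, d)
                half_rows = max(alpha * height / vfov, 0.5)
                if abs(row - row_center) <= half_rows:
                    color = best_obj["color"]
            frame[row, col] = color
    return frame


def forward_naive(layer_sizes, weights, biases, input_vector,
                  activation="logistic"):
    """Nested-loop perceptron forward pass (no numpy linear algebra)."""
    x = [float(v) for v in input_vector]
    for k in range(len(layer_sizes) - 1):
        out = []
        for i in range(layer_sizes[k + 1]):
            z = float(biases[k][i])
            for j in range(layer_sizes[k]):
                z += float(weights[k][i][j]) * x[j]
            if activation == "logistic":
                if z >= 0:
                    out.append(1.0 / (1.0 + math.exp(-z)))
                else:
                    ez = math.exp(z)
                    out.append(ez / (1.0 + ez))
            elif activation == "tanh":
                out.append(math.tanh(z))
            else:
                out.append(1.0 if z > 0 else 0.0)
        x = out
    return np.array(x)


def random_scene(rng, n_food=(0, 6), n_org=(0, 4), arena=20.0):
    """A random list of billboard objects in oracle form."""
    objects = []
    for _ in range(rng.integers(*n_food, endpoint=True)):
        objects.append({
            "x": rng.uniform(0, arena), "y": rng.uniform(0, arena),
            "radius": 0.4, "height": 0.8, "color": (0.0, 1.0, 0.0)})
    for _ in range(rng.integers(*n_org, endpoint=True)):
        objects.append({
            "x": rng.uniform(0, arena), "y": rng.uniform(0, arena),
            "radius": 0.5, "height": 1.0,
            "color": tuple(rng.uniform(0.1, 0.9, size=3))})
    return objects
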