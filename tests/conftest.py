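import json

import numpy as np
import pandas as pd
import pytest

from mycostats.annotation_geometry import AnnotatedImage, PolygonShape


@pytest.fixture
def via_json(tmp_path):
    """A small VIA JSON export exercising every shape dialect."""
    payload = {
        "img1.jpg12345": {
            "filename": "img1.jpg",
            "size": 12345,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [10, 60, 60, 10],
                        "all_points_y": [10, 10, 60, 60],
                    },
                    "region_attributes": {"class": "root"},
                },
                {
                    "shape_attributes": {"name": "rect", "x": 5, "y": 5, "width": 20, "height": 20},
                    "region_attributes": {"class": "arbuscule"},
                },
                {
                    "shape_attributes": {"name": "point", "cx": 30, "cy": 30},
                    "region_attributes": {"class": "spore"},
                },
                {
                    "shape_attributes": {"name": "circle", "cx": 100, "cy": 100, "r": 20},
                    "region_attributes": {"class": "vesicle"},
                },
                {
                    "shape_attributes": {
                        "name": "polyline",
                        "all_points_x": [0, 30, 30],
                        "all_points_y": [0, 0, 30],
                    },
                    "region_attributes": {"class": "external hypha"},
                },
            ],
        }
    }
    path = tmp_path / "annotations.json"
    path.write_text(json.dumps(payload))
    return path


@pytest.fixture
def toy_slide_records():
    """One slide: a 1000-px root plus two 100-px arbuscules."""
    return pd.DataFrame(
        {
            "image_id": ["s1_im1"] * 3,
            "slide_id": ["s1"] * 3,
            "class_label": ["root", "arb", "arb"],
            "pixel_area": [1000, 100, 100],
            "confidence": [0.99, 0.9, 0.8],
        }
    )


def random_annotated_image(rng: np.random.Generator, width=1200, height=900, n_shapes=6) -> AnnotatedImage:
    """A random image of simple convex polygons for conservation checks."""
    shapes = []
    for _ in range(n_shapes):
        cx, cy = rng.uniform(0, width), rng.uniform(0, height)
        r = rng.uniform(20, 200)
        k = rng.integers(3, 9)
        theta = np.sort(rng.uniform(0, 2 * np.pi, k))
        verts = tuple(zip(cx + r * np.cos(theta), cy + r * np.sin(theta)))
        cls = rng.choice(["root", "arb", "exH", "ves", "sp"])
        shapes.append(PolygonShape(verts, str(cls)))
    return AnnotatedImage("rand", width, height, shapes).clamped()


def brute_force_pixel_count(vertices: np.ndarray, width: int, height: int) -> int:
    """O(W*H) even-odd pixel-center oracle, independent of shapely."""
    count = 0
    x, y = vertices[:, 0], vertices[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    for i in range(width):
        px = i + 0.5
        for j in range(height):
            py = j + 0.5
            cond = (y > py) != (y2 > py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x + (py - y) * (x2 - x) / (y2 - y)
            if np.sum(cond & (px < xint)) % 2:
                count += 1
    return count
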