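import numpy as np
import pytest

from hippomorph.contours import Contour, ContourStack


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def make_stack(rings, thickness=1.0, subject_id="test", side="left") -> ContourStack:
    """Stack from a list of (n, 2) vertex rings at z = k * thickness."""
    contours = [
        Contour(points=np.asarray(r, float), slice_index=k, z=k * thickness)
        for k, r in enumerate(rings)
    ]
    return ContourStack(subject_id, contours, thickness, side)


@pytest.fixture
def unit_square() -> Contour:
    return Contour(
        points=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        slice_index=0,
        z=0.0,
    )


@pytest.fixture
def cylinder_stack() -> ContourStack:
    """40 slices of a regular 100-gon of circumradius 5 mm, 1 mm apart."""
    ring = regular_polygon(100, radius=5.0)
    return make_stack([ring] * 40)
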