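import numpy as np
import pytest

from madct.geometry import AnnulusLandmarkSet


def saddle_markers(a: float, b: float, h: float, n: int = 16, offset: float = 0.0) -> np.ndarray:
    """Markers on the analytic saddle ellipse x=a·cosθ, y=b·sinθ, z=h·cos2θ."""
    theta = offset + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(theta), b * np.sin(theta), h * np.cos(2.0 * theta)])


@pytest.fixture
def make_saddle_landmarks():
    def _make(a=6.0, b=6.5, h=1.0, offset=0.0, trigones=(1, 15), phase="ES", **kwargs):
        return AnnulusLandmarkSet(
            subject_id=kwargs.pop("subject_id", "t01"),
            visit=kwargs.pop("visit", "pre"),
            phase=phase,
            markers=saddle_markers(a, b, h, offset=offset),
            trigone_indices=trigones,
            **kwargs,
        )

    return _make


def random_rigid(rng: np.random.Generator):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-30.0, 30.0, size=3)
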