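import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def tube_cloud(curve_fn, t_range, tube_radius, n, rng,
               noise_sd=0.0) -> np.ndarray:
    """Points filling a solid tube around a parametric curve."""
    t = rng.uniform(*t_range, n)
    centers = np.array([curve_fn(ti) for ti in t])
    eps = 1e-5
    tangents = np.array([curve_fn(ti + eps) for ti in t]) - centers
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 1.0, 0.0])
    normals = ref - tangents * (tangents @ ref)[:, None]
    bad = np.linalg.norm(normals, axis=1) < 1e-6
    normals[bad] = np.array([1.0, 0.0, 0.0]) - tangents[bad] * tangents[bad, 0][:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    binormals = np.cross(tangents, normals)
    rho = tube_radius * np.sqrt(rng.uniform(0, 1, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    pts = centers + rho[:, None] * (np.cos(theta)[:, None] * normals
                                    + np.sin(theta)[:, None] * binormals)
    if noise_sd > 0:
        pts = pts + rng.normal(0, noise_sd, pts.shape)
    return pts
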