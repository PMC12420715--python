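"""Shared field constructions for the test suite.

All synthetic fields are built from fixed continuum expressions sampled on
the voxel grid, so tests can refine the grid (halve the spacing) while
keeping the underlying function identical.
"""

import numpy as np
import pytest


def band_limited_u(n, seed, *, amplitude=0.3, wavenumber=np.pi, modes=4):
    """Smooth band-limited scalar field on the unit cube sampled at n^3.

    A sum of separable cosine modes with a single spatial wavenumber per
    axis, random amplitudes and phases; peak absolute value scaled to
    ``amplitude``.  Returns ``(u, h)`` with the grid spacing ``h``.
    """
    rng = np.random.default_rng(seed)
    coefs = [(rng.normal(), rng.uniform(0, 2 * np.pi, 3)) for _ in range(modes)]
    h = 1.0 / (n - 1)
    x = np.linspace(0.0, 1.0, n)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    u = np.zeros((n, n, n))
    for a, ph in coefs:
        u += (
            a
            * np.cos(wavenumber * X + ph[0])
            * np.cos(wavenumber * Y + ph[1])
            * np.cos(wavenumber * Z + ph[2])
        )
    u *= amplitude / np.abs(u).max()
    return u, h


def band_limited_gradient(n, seed, **kw):
    """Gradient field of :func:`band_limited_u` (central differences)."""
    u, h = band_limited_u(n, seed, **kw)
    v = np.stack(np.gradient(u, h, h, h, edge_order=2))
    return v, h


def sphere_cap_gradient(r, n=48, h=1.0, cap_fraction=0.95):
    """Analytic gradient field of the hemisphere cap u = sqrt(r^2 - |x|^2).

    The graph of the cap is a sphere of radius ``r``, so its scalar
    curvature is exactly 6/r^2.  ``v = -x / u`` inside ``|x| <= cap_fraction*r``
    (zero outside, far from the evaluated interior).  Returns
    ``(v, rho2, center)`` with the squared radius field for region masks.
    """
    c = (n - 1) / 2.0 * h
    x = np.arange(n) * h
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    dx, dy, dz = X - c, Y - c, Z - c
    rho2 = dx * dx + dy * dy + dz * dz
    valid = rho2 <= (cap_fraction * r) ** 2
    u = np.sqrt(np.maximum(r * r - rho2, 1e-12))
    v = np.zeros((3, n, n, n))
    for i, d in enumerate((dx, dy, dz)):
        v[i] = np.where(valid, -d / u, 0.0)
    return v, rho2, c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
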