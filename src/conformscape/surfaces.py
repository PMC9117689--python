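"""Analytic potential surfaces with exact gradients.

These serve both the nudged-elastic-band path finder and the Brownian
simulator: each surface is an energy/gradient oracle over d-dimensional
points. Built-ins: the Müller-Brown surface (the standard 2-D test bed for
saddle-finding methods), a 1-D double well, and the three-well
collective-variable surface mimicking the receptor's free-energy basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ValidationError

__all__ = ["PotentialSurface", "muller_brown", "double_well_1d", "get_surface"]


@dataclass
class PotentialSurface:
    """Energy/gradient oracle. Both callables accept (d,) or (n, d) arrays."""

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"
    metadata: dict = field(default_factory=dict)

    def check_gradient(self, points: np.ndarray, h: float = 1e-6,
                       atol: float = 1e-4) -> float:
        """Max |analytic - central difference| over points (consistency check)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        worst = 0.0
        for p in points:
            g = np.asarray(self.gradient(p), dtype=float)
            for k in range(self.dim):
                e = np.zeros(self.dim)
                e[k] = h
                fd = (self.energy(p + e) - self.energy(p - e)) / (2 * h)
                worst = max(worst, abs(float(fd) - g[k]))
        return worst


# Müller-Brown parameters (standard literature values)
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown() -> PotentialSurface:
    """The four-Gaussian Müller-Brown surface (minima near (-0.558, 1.442),
    (0.623, 0.028) and (-0.050, 0.467); two saddles between them)."""

    def energy(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        dx = x[..., None] - _MB_x0
        dy = y[..., None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx ** 2 + _MB_b * dx * dy + _MB_c * dy ** 2)
        return terms.sum(axis=-1)

    def gradient(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        dx = x[..., None] - _MB_x0
        dy = y[..., None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx ** 2 + _MB_b * dx * dy + _MB_c * dy ** 2)
        gx = (terms * (2 * _MB_a * dx + _MB_b * dy)).sum(axis=-1)
        gy = (terms * (_MB_b * dx + 2 * _MB_c * dy)).sum(axis=-1)
        return np.stack([gx, gy], axis=-1)

    return PotentialSurface(dim=2, energy=energy, gradient=gradient,
                            name="muller-brown")


def double_well_1d() -> PotentialSurface:
    """V(x) = x^4 - 2x^2: minima at x = ±1, saddle (barrier top) at x = 0."""

    def energy(p):
        x = np.asarray(p, dtype=float)[..., 0]
        return x ** 4 - 2 * x ** 2

    def gradient(p):
        x = np.asarray(p, dtype=float)[..., 0]
        return (4 * x ** 3 - 4 * x)[..., None]

    return PotentialSurface(dim=1, energy=energy, gradient=gradient,
                            name="double-well-1d")


def get_surface(name: str) -> PotentialSurface:
    """Look up a built-in surface by name."""
    if name == "muller-brown":
        return muller_brown()
    if name == "double-well-1d":
        return double_well_1d()
    if name == "cv-three-well":
        from .synth import default_wells, make_cv_surface
        return make_cv_surface(default_wells())
    raise ValidationError(f"unknown surface {name!r}")
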