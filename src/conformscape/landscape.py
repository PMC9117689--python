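"""2-D free-energy landscape over the (distance_sum, dihedral) plane.

The landscape is a Boltzmann inversion of the sampled density:
F(bin) = -kT ln(n_bin / n_max), so the modal bin sits at F = 0 and empty bins
carry an explicit marker (+inf) rather than a fake zero. Default units are
kcal/mol at the simulation temperature of 300 K; a kT-units switch is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

__all__ = ["KB_KCAL", "LandscapeGrid", "estimate_landscape", "locate"]


@dataclass
class LandscapeGrid:
    """Binned free-energy surface over the two collective variables."""

    distance_edges: np.ndarray
    dihedral_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray  # +inf marks unvisited bins
    temperature: float
    units: str = "kcal/mol"

    @property
    def kT(self) -> float:
        return 1.0 if self.units == "kT" else KB_KCAL * self.temperature

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per bin (bin_d, bin_chi, count, F)."""
        nd, nx = self.counts.shape
        di, xi = np.meshgrid(np.arange(nd), np.arange(nx), indexing="ij")
        dc = 0.5 * (self.distance_edges[:-1] + self.distance_edges[1:])
        xc = 0.5 * (self.dihedral_edges[:-1] + self.dihedral_edges[1:])
        return pd.DataFrame({
            "bin_d": di.ravel(),
            "bin_chi": xi.ravel(),
            "distance_center": dc[di.ravel()],
            "dihedral_center": xc[xi.ravel()],
            "count": self.counts.ravel(),
            "free_energy": self.free_energy.ravel(),
        })


def _stack_samples(features) -> np.ndarray:
    """Accept a DataFrame, an (n,2) array, or a sequence of either."""
    if isinstance(features, pd.DataFrame):
        return features[["distance_sum", "dihedral"]].to_numpy(dtype=float)
    arr = np.asarray(features, dtype=object)
    if isinstance(features, np.ndarray) and features.ndim == 2:
        return features.astype(float)
    parts = [_stack_samples(f) for f in features]
    return np.vstack(parts)


def estimate_landscape(features, n_bins: tuple[int, int] = (100, 100),
                       temperature: float = 300.0, units: str = "kcal/mol",
                       ranges=None) -> LandscapeGrid:
    """Histogram CV samples and Boltzmann-invert to a free-energy surface.

    ``features`` may be a single FeatureSeries table or a collection; pooling
    a collection is identical to concatenating the samples. Data-driven bin
    ranges are padded by 2% on each side unless ``ranges`` is given.
    """
    samples = _stack_samples(features)
    if samples.shape[0] < 1:
        raise DegenerateInputError("need at least one CV sample")
    if min(n_bins) < 2:
        raise ValidationError("need at least 2 bins per axis")
    if ranges is None:
        lo = samples.min(axis=0)
        hi = samples.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        lo = lo - 0.02 * span
        hi = hi + 0.02 * span
        ranges = ((lo[0], hi[0]), (lo[1], hi[1]))
    counts, d_edges, x_edges = np.histogram2d(
        samples[:, 0], samples[:, 1], bins=n_bins, range=ranges
    )
    if np.count_nonzero(counts) == 1:
        warnings.warn("all samples fall in a single bin; landscape is degenerate",
                      stacklevel=2)
    kT = 1.0 if units == "kT" else KB_KCAL * temperature
    free = np.full_like(counts, np.inf)
    occ = counts > 0
    free[occ] = -kT * np.log(counts[occ] / counts.max())
    return LandscapeGrid(distance_edges=d_edges, dihedral_edges=x_edges,
                         counts=counts, free_energy=free,
                         temperature=temperature, units=units)


def locate(point: tuple[float, float], grid: LandscapeGrid):
    """Bin indices and free energy at a CV point.

    Bins follow the half-open convention [lo, hi): a point exactly on an
    interior edge belongs to the higher bin. Returns ((i, j), F) where F is
    +inf for an unvisited bin.
    """
    d, chi = point
    for value, edges, name in ((d, grid.distance_edges, "distance"),
                               (chi, grid.dihedral_edges, "dihedral")):
        if not (edges[0] <= value <= edges[-1]):
            raise ValidationError(
                f"{name}={value} outside grid range [{edges[0]}, {edges[-1]}]"
            )
    i = int(np.searchsorted(grid.distance_edges, d, side="right") - 1)
    j = int(np.searchsorted(grid.dihedral_edges, chi, side="right") - 1)
    i = min(i, grid.counts.shape[0] - 1)  # top edge closes the last bin
    j = min(j, grid.counts.shape[1] - 1)
    return (i, j), float(grid.free_energy[i, j])
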