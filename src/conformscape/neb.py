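"""Nudged-elastic-band (NEB) minimum-energy paths on analytic surfaces.

A band is a chain of replicas [R_0 ... R_n] with fixed endpoints. Each
interior replica feels the true force only perpendicular to the local tangent
and the spring force only parallel to it, which prevents the band from
sliding into the energy basins while keeping replicas spread along the path:

    F_perp  = -∇V + (∇V·τ)τ
    F_par   = k(|R_{i+1}-R_i| - |R_{i-1}-R_i|) τ
    F_total = F_perp + F_par

The tangent τ_i is energy-weighted with four cases: the uphill difference on
monotonic segments, and a ΔV^max/ΔV^min-weighted mix of both differences at
local extrema (the higher-energy neighbor carries the ΔV^max weight). Bands
are relaxed through a simulated-annealing schedule (noisy overdamped steps at
phase temperatures) followed by a zero-temperature FIRE descent until the
perpendicular force converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .structure import kabsch_rotation
from .surfaces import PotentialSurface

__all__ = [
    "NEBBand", "AnnealPhase", "AnnealSchedule", "default_schedule",
    "init_band", "tangent", "band_tangents", "band_forces", "relax_band",
    "align_replicas", "select_diverse_replicas", "pairwise_rmsd",
]

DEFAULT_N_REPLICAS = 52  # interior replicas in the default band


@dataclass
class NEBBand:
    """Ordered replicas with energies; endpoints are always held fixed."""

    replicas: np.ndarray            # (n, d)
    spring_k: float = 50.0
    energies: np.ndarray | None = None
    converged: bool | None = None
    residual: float | None = None

    @property
    def n_replicas(self) -> int:
        return self.replicas.shape[0]

    @property
    def dim(self) -> int:
        return self.replicas.shape[1]


@dataclass
class AnnealPhase:
    temperature: float   # in surface energy units (kT)
    steps: int
    spring_k: float
    step_size: float


@dataclass
class AnnealSchedule:
    phases: list[AnnealPhase] = field(default_factory=list)

    def validate(self) -> None:
        if not self.phases:
            raise ValidationError("schedule has no phases")
        for p in self.phases:
            if p.steps <= 0:
                raise ValidationError("phase step counts must be positive")
        if self.phases[-1].temperature != 0.0:
            raise ValidationError("final phase must be at zero temperature")


def default_schedule(energy_scale: float, step_size: float) -> AnnealSchedule:
    """Heat at soft springs, equilibrate at stiff springs, anneal hot-to-cold,
    then hold at zero temperature (phase proportions mirror the usual
    heat 300 K @ k=10 → equilibrate @ k=50 → heat 500 K/cool → 0 K recipe,
    expressed in optimizer steps and surface energy units)."""
    es = energy_scale
    phases = [AnnealPhase(0.3 * es, 500, 10.0, step_size),
              AnnealPhase(0.3 * es, 600, 50.0, step_size)]
    for frac in (0.5, 0.3, 0.15, 0.05):
        phases.append(AnnealPhase(frac * es, 300, 50.0, step_size))
    phases.append(AnnealPhase(0.0, 2000, 50.0, step_size))
    return AnnealSchedule(phases=phases)


def init_band(start, end, n_replicas: int = DEFAULT_N_REPLICAS,
              spring_k: float = 50.0) -> NEBBand:
    """Linear interpolation between endpoints, inclusive.

    ``n_replicas`` counts the interior replicas; the band therefore has
    n_replicas + 2 points.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    end = np.atleast_1d(np.asarray(end, dtype=float))
    if np.allclose(start, end):
        raise DegenerateInputError("band endpoints coincide")
    if n_replicas < 2:
        raise ValidationError("need at least 2 interior replicas")
    ts = np.linspace(0.0, 1.0, n_replicas + 2)
    replicas = start[None, :] + ts[:, None] * (end - start)[None, :]
    return NEBBand(replicas=replicas, spring_k=spring_k)


def _tangents_vectorized(R: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Unit tangents for all interior replicas (energy-weighted case split)."""
    seg = R[1:] - R[:-1]
    fwd, bwd = seg[1:], seg[:-1]
    Vm, Vc, Vp = V[:-2], V[1:-1], V[2:]
    dp = np.abs(Vp - Vc)
    dm = np.abs(Vm - Vc)
    dmax = np.maximum(dp, dm)
    dmin = np.minimum(dp, dm)
    up = (Vp > Vc) & (Vc > Vm)
    down = (Vp < Vc) & (Vc < Vm)
    hi_fwd = Vp >= Vm  # higher-energy neighbor ahead → forward diff gets dmax
    wf = np.where(up, 1.0, np.where(down, 0.0, np.where(hi_fwd, dmax, dmin)))
    wb = np.where(up, 0.0, np.where(down, 1.0, np.where(hi_fwd, dmin, dmax)))
    raw = wf[:, None] * fwd + wb[:, None] * bwd
    norms = np.linalg.norm(raw, axis=1)
    flat = norms < 1e-12  # flat-energy extremum: fall back to central difference
    if flat.any():
        raw[flat] = fwd[flat] + bwd[flat]
        norms = np.linalg.norm(raw, axis=1)
    if (norms < 1e-12).any():
        raise DegenerateInputError(
            "zero-length tangent: duplicate neighboring replicas"
        )
    return raw / norms[:, None]


def tangent(band: NEBBand, i: int, surface: PotentialSurface | None = None) -> np.ndarray:
    """Unit tangent at interior replica i."""
    if not 0 < i < band.n_replicas - 1:
        raise ValidationError(f"replica {i} is not interior")
    V = band.energies
    if V is None:
        if surface is None:
            raise ValidationError("band has no energies; pass a surface")
        V = surface.energy(band.replicas)
    return _tangents_vectorized(band.replicas, np.asarray(V, dtype=float))[i - 1]


def band_tangents(band: NEBBand, surface: PotentialSurface) -> np.ndarray:
    """Unit tangents for all interior replicas, shape (n-2, d)."""
    V = np.asarray(surface.energy(band.replicas), dtype=float)
    return _tangents_vectorized(band.replicas, V)


def _forces(R: np.ndarray, surface: PotentialSurface,
            spring_k: float) -> tuple[np.ndarray, np.ndarray]:
    """(total force, perpendicular force) per replica; endpoints zero."""
    V = np.asarray(surface.energy(R), dtype=float)
    G = np.asarray(surface.gradient(R), dtype=float)
    if not np.all(np.isfinite(G)):
        bad = int(np.flatnonzero(~np.isfinite(G).all(axis=1))[0])
        raise ValidationError(f"non-finite gradient at replica {bad}")
    tau = _tangents_vectorized(R, V)
    g_int = G[1:-1]
    g_par = np.einsum("id,id->i", g_int, tau)
    f_perp = -g_int + g_par[:, None] * tau
    seg = R[1:] - R[:-1]
    spring = spring_k * (np.linalg.norm(seg[1:], axis=1)
                         - np.linalg.norm(seg[:-1], axis=1))
    total = np.zeros_like(R)
    perp = np.zeros_like(R)
    total[1:-1] = f_perp + spring[:, None] * tau
    perp[1:-1] = f_perp
    return total, perp


def band_forces(band: NEBBand, surface: PotentialSurface) -> np.ndarray:
    """Total NEB force per replica (projection scheme above); endpoints zero."""
    total, _ = _forces(band.replicas, surface, band.spring_k)
    return total


def _fire_descend(R, surface, spring_k, step0, tol, max_steps, max_disp):
    """Zero-temperature FIRE minimization of the NEB force."""
    v = np.zeros_like(R)
    dt, alpha, n_pos = step0, 0.1, 0
    dt_max = 50 * step0
    residual = np.inf
    for _ in range(max_steps):
        F, perp = _forces(R, surface, spring_k)
        residual = float(np.abs(perp[1:-1]).max()) if len(R) > 2 else 0.0
        if residual < tol:
            return R, True, residual
        p = float((F * v).sum())
        if p > 0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha, n_pos = 0.1, 0
        v += dt * F
        vn = np.linalg.norm(v)
        fn = np.linalg.norm(F)
        if fn > 0:
            v = (1 - alpha) * v + alpha * vn * F / fn
        step = dt * v
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_disp / np.maximum(norm, 1e-30))
        R = R + step * scale
        R[0], R[-1] = R[0], R[-1]  # endpoints carry zero force anyway
    return R, False, residual


def relax_band(band: NEBBand, surface: PotentialSurface,
               schedule: AnnealSchedule | None = None, seed: int = 0,
               tol: float = 1e-3, max_descent_steps: int = 200_000) -> NEBBand:
    """Anneal then converge a band to the minimum-energy path.

    Each schedule phase takes noisy overdamped steps on the total NEB force
    (noise amplitude √(2 T δ), interior replicas only); after the schedule a
    zero-temperature FIRE descent runs until max interior |F_perp| < ``tol``.
    A non-converged band is returned flagged with its residual force rather
    than raising.
    """
    rng = np.random.default_rng(seed)
    R = band.replicas.copy()
    V0 = np.asarray(surface.energy(R), dtype=float)
    G0 = np.asarray(surface.gradient(R), dtype=float)
    gscale = float(np.abs(G0).max()) + 1e-12
    spacing = float(np.linalg.norm(R[1] - R[0]))
    step0 = min(1e-2, 0.1 * spacing / gscale)
    if schedule is None:
        schedule = default_schedule(energy_scale=0.02 * (V0.max() - V0.min() + 1e-12),
                                    step_size=step0)
    schedule.validate()
    spring_k = band.spring_k
    for phase in schedule.phases:
        spring_k = phase.spring_k
        dt = phase.step_size
        for _ in range(phase.steps):
            F, _ = _forces(R, surface, spring_k)
            kick = np.zeros_like(R)
            if phase.temperature > 0:
                kick[1:-1] = (np.sqrt(2.0 * phase.temperature * dt)
                              * rng.standard_normal(R[1:-1].shape))
            step = dt * F + kick
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            cap = np.minimum(1.0, (0.5 * spacing) / np.maximum(norm, 1e-30))
            R = R + step * cap
            if not np.all(np.isfinite(R)):
                raise ValidationError("band diverged during annealing; "
                                      "reduce the step size")
    R, ok, residual = _fire_descend(R, surface, spring_k, step0, tol,
                                    max_descent_steps, 0.5 * spacing)
    assert np.array_equal(R[0], band.replicas[0])
    assert np.array_equal(R[-1], band.replicas[-1])
    return replace(band, replicas=R, spring_k=spring_k,
                   energies=np.asarray(surface.energy(R), dtype=float),
                   converged=bool(ok), residual=residual)


# ---------------------------------------------------------------------------
# Structure-band utilities


def align_replicas(band_structures: np.ndarray) -> np.ndarray:
    """Remove rigid-body drift along a band of Cα replicas.

    Every replica is translated to a common centroid and rotated onto its
    predecessor by the optimal proper (det=+1) least-squares rotation.
    Input shape (n_replicas, n_atoms, 3).
    """
    X = np.asarray(band_structures, dtype=float).copy()
    if X.ndim != 3:
        raise ValidationError("expected (replicas, atoms, 3) array")
    X -= X.mean(axis=1, keepdims=True)
    for i in range(1, X.shape[0]):
        R = kabsch_rotation(X[i], X[i - 1])
        X[i] = X[i] @ R
    return X


def pairwise_rmsd(band_structures: np.ndarray) -> np.ndarray:
    """All-pairs best-fit Cα RMSD matrix for a band of structures."""
    X = np.asarray(band_structures, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R = kabsch_rotation(X[j], X[i])
            diff = X[j] @ R - X[i]
            out[i, j] = out[j, i] = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return out


def select_diverse_replicas(band, n: int, metric: str = "auto") -> np.ndarray:
    """Greedy max-min diverse subset of replicas, endpoints forced.

    Distances are best-fit RMSD for structure bands ((r, atoms, 3) input) and
    Euclidean for point bands; ties break toward the lower index. Returns
    sorted replica indices.
    """
    if isinstance(band, NEBBand):
        pts = band.replicas
    else:
        pts = np.asarray(band, dtype=float)
    if pts.ndim == 3 or metric == "rmsd":
        D = pairwise_rmsd(pts)
    else:
        diff = pts[:, None, :] - pts[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
    total = D.shape[0]
    if n > total:
        raise ValidationError(f"cannot select {n} replicas from {total}")
    if n < 2:
        raise ValidationError("need at least the two endpoints")
    selected = [0, total - 1]
    while len(selected) < n:
        remaining = np.setdiff1d(np.arange(total), selected)
        min_d = D[np.ix_(remaining, selected)].min(axis=1)
        best = remaining[int(np.argmax(min_d))]  # argmax → lowest index on ties
        selected.append(int(best))
    return np.array(sorted(selected))
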