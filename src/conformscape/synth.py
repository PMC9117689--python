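"""Synthetic inputs with known ground truth for every pipeline stage.

* Gaussian multi-well surfaces over the (distance_sum, dihedral) CV plane and
  an overdamped (Brownian) integrator producing trajectories with per-frame
  well labels — the statistical stand-in for long MD trajectory ensembles;
* discrete Markov-chain label sequences from a known transition matrix;
* multiple sequence alignments with conserved positions and planted
  co-evolving sector groups driven by a shared hidden binary state;
* an idealized Cα helix-bundle PDB fixture with a centered pseudo-ligand and
  a matching Ballesteros-Weinstein map.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .sca import AMINO_ACIDS, GAP, MSA
from .structure import BWMap, build_bw_map
from .surfaces import PotentialSurface

__all__ = [
    "WellSpec", "default_wells", "make_cv_surface",
    "BrownianConfig", "BrownianResult", "default_brownian_config",
    "simulate_brownian", "boltzmann_well_weights",
    "simulate_chain",
    "MSASpec", "SectorGroup", "SyntheticMSA", "generate_msa",
    "ToyBundle", "make_toy_bundle",
]


# ---------------------------------------------------------------------------
# CV surfaces and Brownian dynamics


@dataclass(frozen=True)
class WellSpec:
    """A Gaussian well: V contribution -depth * exp(-sum ((x-c)/w)^2)."""

    center: tuple[float, ...]
    depth: float
    width: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError("well depth must be positive")
        if any(w <= 0 for w in self.width):
            raise ValidationError("well widths must be positive")
        if len(self.center) != len(self.width):
            raise ValidationError("center and width dimensions differ")


def default_wells() -> list[WellSpec]:
    """Three wells at the receptor's free-energy basins.

    Centers sit inside the observed basin ranges (active-like ≈ 52-56 Å /
    100-110°, intermediate ≈ 51-56 Å / 180-197°, inactive-like ≈ 53-58 Å /
    203-230°). Depths of ~6 kT against the default confinement make the
    basins genuinely metastable and leave them holding the large majority of
    the equilibrium population (the plateau between basins is an entropic
    sink otherwise), while inter-basin hopping stays regular within the
    canonical study length; depth differences order the Boltzmann weights
    intermediate > active-like > inactive-like.
    """
    return [
        WellSpec(center=(54.0, 105.0), depth=5.98, width=(1.5, 9.0)),   # active-like
        WellSpec(center=(53.5, 188.0), depth=5.72, width=(1.5, 8.0)),   # intermediate
        WellSpec(center=(55.5, 216.0), depth=5.85, width=(1.5, 10.0)),  # inactive-like
    ]


#: default harmonic container for the CV plane: center, per-axis scale, kT stiffness
DEFAULT_CONFINEMENT = ((54.5, 160.0), (3.0, 55.0), 1.3)


def make_cv_surface(wells: list[WellSpec],
                    confinement: tuple | None = DEFAULT_CONFINEMENT) -> PotentialSurface:
    """Analytic sum-of-Gaussian-wells surface with exact gradient.

    V(x) = -Σ depth exp(-Σ_axis ((x-c)/w)²) [+ kc Σ_axis ((x-c0)/s)²]

    The optional harmonic confinement term (center c0, per-axis scale s,
    stiffness kc) keeps the flat plateau between wells from acting as an
    entropic sink, the analogue of the finite conformational range a real
    receptor explores; pass ``confinement=None`` for the bare wells.
    """
    if not wells:
        raise ValidationError("need at least one well")
    dim = len(wells[0].center)
    centers = np.array([w.center for w in wells])          # (m, d)
    depths = np.array([w.depth for w in wells])
    widths = np.array([w.width for w in wells])
    if confinement is not None:
        c0 = np.asarray(confinement[0], dtype=float)
        cs = np.asarray(confinement[1], dtype=float)
        kc = float(confinement[2])
        if c0.shape != (dim,) or cs.shape != (dim,):
            raise ValidationError("confinement center/scale must match dimension")

    def energy(p):
        p = np.asarray(p, dtype=float)
        z = (p[..., None, :] - centers) / widths           # (..., m, d)
        v = -(depths * np.exp(-(z ** 2).sum(axis=-1))).sum(axis=-1)
        if confinement is not None:
            v = v + kc * (((p - c0) / cs) ** 2).sum(axis=-1)
        return v

    def gradient(p):
        p = np.asarray(p, dtype=float)
        z = (p[..., None, :] - centers) / widths
        e = depths * np.exp(-(z ** 2).sum(axis=-1))        # (..., m)
        g = (e[..., None] * 2.0 * z / widths).sum(axis=-2)
        if confinement is not None:
            g = g + kc * 2.0 * (p - c0) / cs ** 2
        return g

    return PotentialSurface(dim=dim, energy=energy, gradient=gradient,
                            name="cv-wells",
                            metadata={"wells": list(wells),
                                      "confinement": confinement})


@dataclass
class BrownianConfig:
    steps: int
    kT: float = 1.0
    dt: float = 0.05
    n_traj: int = 1
    initial: np.ndarray | None = None   # (n_traj, d); default cycles well centers
    mobility: tuple[float, ...] | None = None  # per-axis; isotropic 1 if None
    stride: int = 1                     # integration sub-steps per saved frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kT < 0:
            raise ValidationError("kT must be non-negative")
        if self.dt <= 0:
            raise ValidationError("time step must be positive")
        if self.steps < 1 or self.n_traj < 1:
            raise ValidationError("steps and n_traj must be positive")
        if self.mobility is not None and any(m <= 0 for m in self.mobility):
            raise ValidationError("mobilities must be positive")
        if self.stride < 1:
            raise ValidationError("stride must be at least 1")


def default_brownian_config(steps: int = 50_000, n_traj: int = 10,
                            seed: int = 0) -> BrownianConfig:
    """Canonical study conditions for the three-well CV surface.

    kT=1 against well depths of ~6 kT gives metastable basins with regular
    inter-basin hopping; the dihedral mobility is scaled by the squared
    basin-width ratio (9/1.5)² so relaxation is isotropic in the
    width-scaled coordinates the microstate clustering itself uses —
    mirroring that the dihedral coordinate explores a numerically far larger
    range than the distance coordinate on the same wall-clock timescale.
    A diagonal positive mobility leaves the Boltzmann law unchanged. Frames
    are saved every 40 integration sub-steps (as MD saves frames every many
    integrator steps), so intra-basin relaxation (a few sub-steps) is
    sub-frame and the saved-frame process is Markovian from lag 1.
    """
    return BrownianConfig(steps=steps, n_traj=n_traj, kT=1.0, dt=0.1,
                          mobility=(1.0, 36.0), stride=40, seed=seed)


@dataclass
class BrownianResult:
    samples: np.ndarray          # (n_traj, steps, d)
    labels: np.ndarray | None    # (n_traj, steps) nearest-well index
    config: BrownianConfig

    @property
    def features(self) -> list[pd.DataFrame]:
        """FeatureSeries view (requires a 2-D CV surface)."""
        if self.samples.shape[2] != 2:
            raise ValidationError("features view needs 2-D samples")
        out = []
        for t in range(self.samples.shape[0]):
            df = pd.DataFrame(self.samples[t],
                              columns=["distance_sum", "dihedral"])
            df.insert(0, "frame", np.arange(len(df)))
            out.append(df)
        return out


def boltzmann_well_weights(surface: PotentialSurface, kT: float = 1.0,
                           padding: float = 4.0, n_grid: int = 400) -> np.ndarray:
    """Equilibrium weight of each well's basin by direct quadrature.

    Integrates exp(-V/kT) on a dense grid covering all wells (padded by
    ``padding`` well widths per axis) and assigns each grid cell to its
    nearest well — the ground truth against which sampled or MSM-derived
    state proportions are compared.
    """
    wells = surface.metadata.get("wells")
    if not wells:
        raise ValidationError("surface carries no well metadata")
    centers = np.array([w.center for w in wells])
    widths = np.array([w.width for w in wells])
    lo = (centers - padding * widths).min(axis=0)
    hi = (centers + padding * widths).max(axis=0)
    axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(surface.dim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(mesh, axis=-1)
    w = np.exp(-np.asarray(surface.energy(pts)) / kT)
    lab = _nearest_well(pts, wells)
    weights = np.array([w[lab == i].sum() for i in range(len(wells))])
    return weights / weights.sum()


def _nearest_well(points: np.ndarray, wells: list[WellSpec]) -> np.ndarray:
    centers = np.array([w.center for w in wells])
    widths = np.array([w.width for w in wells])
    z = (points[..., None, :] - centers) / widths
    return np.argmin((z ** 2).sum(axis=-1), axis=-1)


def simulate_brownian(surface: PotentialSurface,
                      config: BrownianConfig) -> BrownianResult:
    """Overdamped Langevin sampling: x ← x - μ ∇V dt + √(2 kT μ dt) ξ.

    μ is the (diagonal, per-axis) mobility, 1 by default. When the surface
    carries well metadata each frame is labelled with its nearest well
    (per-axis width-scaled distance), giving the ground truth for
    metastable-state recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    mob = (np.ones(surface.dim) if config.mobility is None
           else np.asarray(config.mobility, dtype=float))
    if mob.shape != (surface.dim,):
        raise ValidationError("mobility must have one entry per axis")
    wells = surface.metadata.get("wells")
    if config.initial is not None:
        x = np.atleast_2d(np.asarray(config.initial, dtype=float)).copy()
        if x.shape != (config.n_traj, surface.dim):
            raise ValidationError("initial points must have shape (n_traj, dim)")
    elif wells:
        centers = np.array([w.center for w in wells])
        x = centers[np.arange(config.n_traj) % len(centers)].astype(float)
    else:
        x = np.zeros((config.n_traj, surface.dim))
    sigma = np.sqrt(2.0 * config.kT * config.dt * mob)
    out = np.empty((config.n_traj, config.steps, surface.dim))
    bound = 1e6 + 1e3 * np.abs(x).max()
    for s in range(config.steps):
        for _ in range(config.stride):
            g = np.asarray(surface.gradient(x), dtype=float)
            x = x - g * (config.dt * mob)
            if config.kT > 0:
                x = x + sigma * rng.standard_normal(x.shape)
        if np.abs(x).max() > bound:
            raise DegenerateInputError(
                "Brownian trajectory diverged; reduce the time step"
            )
        out[:, s, :] = x
    labels = _nearest_well(out, wells) if wells else None
    return BrownianResult(samples=out, labels=labels, config=config)


# ---------------------------------------------------------------------------
# Discrete Markov chains


def simulate_chain(tpm: np.ndarray, steps: int, seed: int = 0,
                   initial: int = 0) -> np.ndarray:
    """Sample a label sequence from a row-stochastic transition matrix."""
    T = np.asarray(tpm, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValidationError("transition matrix must be square")
    if (T < 0).any():
        raise ValidationError("transition matrix has negative entries")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("transition matrix rows must sum to 1")
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(steps)
    seq = np.empty(steps, dtype=int)
    state = int(initial)
    for t in range(steps):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, T.shape[0] - 1)  # guard float round-off at u≈1
        seq[t] = state
    return seq


# ---------------------------------------------------------------------------
# Synthetic MSAs with planted sectors


@dataclass(frozen=True)
class SectorGroup:
    """Positions sharing a hidden binary state; coupling = copy probability."""

    positions: tuple[int, ...]
    coupling: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValidationError("coupling must lie in [0, 1]")


@dataclass
class MSASpec:
    n_sequences: int = 500
    n_positions: int = 100
    conserved: dict[int, tuple[str, float]] = field(default_factory=dict)
    groups: list[SectorGroup] = field(default_factory=list)
    #: weak residue preference shared by every background position within a
    #: sequence clade — the phylogenetic signal that makes the leading SCA
    #: eigenvector a global mode, as in real alignments; 0 disables it
    clade_coupling: float = 0.0
    background: np.ndarray | None = None     # length-20 simplex; uniform default
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1 or self.n_positions < 1:
            raise ValidationError("alignment dimensions must be positive")
        if not 0.0 <= self.clade_coupling <= 1.0:
            raise ValidationError("clade_coupling must lie in [0, 1]")
        claimed: set[int] = set()
        for g in self.groups:
            pos = set(g.positions)
            if pos & claimed:
                raise ValidationError("sector groups must be disjoint")
            if pos & set(self.conserved):
                raise ValidationError(
                    "sector groups must not overlap conserved positions")
            if max(pos) >= self.n_positions or min(pos) < 0:
                raise ValidationError("group position outside alignment")
            claimed |= pos
        for p, (res, f) in self.conserved.items():
            if not 0 <= p < self.n_positions:
                raise ValidationError(f"conserved position {p} out of range")
            if res not in AMINO_ACIDS or not 0.0 <= f <= 1.0:
                raise ValidationError(f"bad conserved spec at position {p}")


def default_sector_msa_spec(seed: int = 0) -> MSASpec:
    """Canonical study conditions for sector recovery.

    A 500-sequence, 100-position alignment with a few conserved motif
    positions, a clade signal (coupling 0.65) across the background — the
    phylogenetic structure that makes the first eigenvector the global mode
    the sector rules drop — and one planted 10-position sector at coupling
    0.9, which then carries the second eigenvector and should be recovered
    by the red-sector rule.
    """
    return MSASpec(
        n_sequences=500, n_positions=100,
        conserved={5: ("W", 0.92), 15: ("P", 0.88), 95: ("Y", 0.9)},
        groups=[SectorGroup(positions=tuple(range(45, 55)), coupling=0.9)],
        clade_coupling=0.65, seed=seed,
    )


@dataclass
class SyntheticMSA:
    msa: MSA
    sector_positions: list[np.ndarray]   # per group
    hidden_states: np.ndarray            # (n_groups, n_sequences)
    state_residues: dict[int, tuple[str, str]]
    clades: np.ndarray | None = None     # per-sequence clade label

    def to_fasta(self) -> str:
        lines = []
        for i in range(self.msa.n_sequences):
            lines.append(f">seq{i}")
            lines.append("".join(self.msa.chars[i]))
        return "\n".join(lines) + "\n"


def generate_msa(spec: MSASpec) -> SyntheticMSA:
    """Draw an alignment with planted conservation and co-evolving groups.

    Independent positions draw from the background; conserved positions emit
    their designated residue with the target frequency; each group shares a
    per-sequence hidden binary state and each member copies its
    state-designated residue with probability ``coupling`` (else draws from
    the background). The gap guard row is appended as in :func:`sca.load_msa`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    bg = (np.full(20, 0.05) if spec.background is None
          else np.asarray(spec.background, dtype=float))
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValidationError("background must be a length-20 simplex")
    n, L = spec.n_sequences, spec.n_positions
    chars = aa[rng.choice(20, size=(n, L), p=bg)]
    for p, (res, f) in spec.conserved.items():
        hit = rng.random(n) < f
        chars[hit, p] = res
    clades = None
    if spec.clade_coupling > 0:
        clades = rng.integers(0, 2, size=n)
        claimed = set(spec.conserved)
        for g in spec.groups:
            claimed |= set(g.positions)
        for p in range(L):
            if p in claimed:
                continue
            pair = aa[rng.choice(20, size=2, replace=False)]
            copies = rng.random(n) < spec.clade_coupling
            chars[copies, p] = pair[clades][copies]
    hidden = np.zeros((len(spec.groups), n), dtype=int)
    state_residues: dict[int, tuple[str, str]] = {}
    for gi, group in enumerate(spec.groups):
        hidden[gi] = rng.integers(0, 2, size=n)
        for p in group.positions:
            pair = tuple(aa[rng.choice(20, size=2, replace=False)])
            state_residues[p] = pair
            copies = rng.random(n) < group.coupling
            chosen = np.array(pair)[hidden[gi]]
            chars[copies, p] = chosen[copies]
    rows = np.vstack([chars, np.full((1, L), GAP, dtype="U1")])
    msa = MSA(chars=rows, ids=[f"seq{i}" for i in range(n)],
              gap_row_appended=True)
    return SyntheticMSA(
        msa=msa,
        sector_positions=[np.asarray(g.positions) for g in spec.groups],
        hidden_states=hidden,
        state_residues=state_residues,
        clades=clades,
    )


# ---------------------------------------------------------------------------
# Toy structure fixture


@dataclass
class ToyBundle:
    pdb_text: str
    bw_map: BWMap
    n_atoms: int
    n_residues: int


def make_toy_bundle(seed: int = 0, n_helices: int = 4,
                    n_res: int = 15, bundle_radius: float = 5.5) -> ToyBundle:
    """Idealized Cα helix bundle with a centered pseudo-ligand.

    Each helix is ideal (3.6 residues/turn, 1.5 Å rise, 2.3 Å helical
    radius), helix axes stand on a circle of ``bundle_radius``; a single
    HETATM pseudo-ligand sits 3 Å inside the first helix's middle Cα (toward
    the bundle axis), within 4 Å of at least one residue by construction.
    The matching BW map anchors x.50 at each helix's middle residue. A small
    seeded jitter (0.01 Å) keeps fixtures distinct across seeds without
    breaking the ideal geometry.
    """
    if n_helices < 4:
        raise ValidationError("bundle needs at least 4 helices")
    rng = np.random.default_rng(seed)
    lines = ["HEADER    SYNTHETIC HELIX BUNDLE (TOY FIXTURE)"]
    serial = 0
    resid = 0
    anchors: dict[str, int] = {}
    ranges: dict[str, tuple[int, int]] = {}
    helix_r, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    anchor_ca = None
    for h in range(n_helices):
        ang = 2 * np.pi * h / n_helices
        ax, ay = bundle_radius * np.cos(ang), bundle_radius * np.sin(ang)
        first = resid + 1
        for k in range(n_res):
            resid += 1
            serial += 1
            phi = k * twist + ang  # phase offset per helix
            x = ax + helix_r * np.cos(phi) + 0.01 * rng.standard_normal()
            y = ay + helix_r * np.sin(phi) + 0.01 * rng.standard_normal()
            z = k * rise + 0.01 * rng.standard_normal()
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            if h == 0 and k == n_res // 2:
                anchor_ca = np.array([x, y, z])
        anchors[str(h + 1)] = first + n_res // 2
        ranges[str(h + 1)] = (first, resid)
    serial += 1
    inward = np.array([-anchor_ca[0], -anchor_ca[1], 0.0])
    inward /= np.linalg.norm(inward)
    lig = anchor_ca + 3.0 * inward
    lines.append(
        f"HETATM{serial:5d}  C1  LIG L{resid + 1:4d}    "
        f"{lig[0]:8.3f}{lig[1]:8.3f}{lig[2]:8.3f}  1.00  0.00           C"
    )
    lines.append("END")
    return ToyBundle(
        pdb_text="\n".join(lines) + "\n",
        bw_map=build_bw_map(anchors, ranges),
        n_atoms=serial,
        n_residues=resid,
    )
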