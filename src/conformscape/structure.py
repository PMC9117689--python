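"""Structures, trajectories, Ballesteros-Weinstein numbering and per-frame observables.

The conformational coordinates used throughout the package are two internal
coordinates of the receptor's intracellular face:

* ``distance_sum`` — |r(2.40) - r(5.63)| + |r(2.40) - r(6.25)| over Cα atoms,
  tracking the opening of intracellular TM5/TM6 relative to the stable TM2;
* ``dihedral`` — the torsion over the Cα atoms of positions 8.54, 7.56, 7.54
  and 7.47, tracking the orientation of helix 8 relative to the TM7 stalk,
  reported in degrees wrapped to [0, 360).

Superscripts are Ballesteros-Weinstein (BW) positions: ``helix.index`` with
``x.50`` anchored at the helix's most conserved residue and every other index
an arithmetic offset from it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .errors import (
    BWResolutionError,
    DegenerateInputError,
    EmptySelectionError,
    FeaturizationError,
    ParseError,
)

__all__ = [
    "Structure",
    "Trajectory",
    "BWMap",
    "DEFAULT_BW_MAP",
    "CV_DISTANCE_CODES",
    "CV_DIHEDRAL_CODES",
    "read_structure",
    "read_trajectory",
    "read_trajectory_csv",
    "build_bw_map",
    "compute_cv",
    "featurize_trajectory",
    "dihedral_angle",
    "kabsch_rotation",
    "superpose_trajectory",
    "rmsf",
    "pca_modes",
    "dccm",
    "DCCMMatrix",
    "ContactProfile",
    "contact_fraction",
]

# BW codes entering the two collective variables
CV_DISTANCE_CODES = ("2.40", "5.63", "6.25")
CV_DIHEDRAL_CODES = ("8.54", "7.56", "7.54", "7.47")

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}


@dataclass
class Structure:
    """Atom table parsed from a PDB file.

    Arrays are parallel, one entry per atom. ``hetero`` marks HETATM records
    (ligands, waters); residue numbering is 1-based PDB numbering.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    hetero: np.ndarray
    title: str = ""

    def __len__(self) -> int:
        return len(self.res_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def longest_protein_chain(self) -> str:
        """Chain id with the most Cα atoms (receptor vs antibody/ligand)."""
        mask = (self.atom_names == "CA") & ~self.hetero
        if not mask.any():
            raise EmptySelectionError("structure contains no Calpha atoms")
        chains, counts = np.unique(self.chain_ids[mask], return_counts=True)
        return str(chains[np.argmax(counts)])

    def ca_table(self, chain: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(residue ids, coordinates) of Cα atoms, optionally for one chain."""
        mask = (self.atom_names == "CA") & ~self.hetero
        if chain is not None:
            mask &= self.chain_ids == chain
        if not mask.any():
            raise EmptySelectionError(
                f"no Calpha atoms in selection (chain={chain!r})"
            )
        return self.res_ids[mask].copy(), self.coords[mask].copy()

    def ligand_coords(self, exclude_water: bool = True) -> np.ndarray:
        """Coordinates of HETATM atoms (waters dropped by default)."""
        mask = self.hetero.copy()
        if exclude_water:
            mask &= ~np.isin(self.res_names, list(_WATER_NAMES))
        return self.coords[mask].copy()


@dataclass
class Trajectory:
    """Ordered Cα frames with a consistent atom ordering.

    coords has shape (n_frames, n_atoms, 3); ``frame_interval`` is the saved
    time per frame in nanoseconds.
    """

    coords: np.ndarray
    res_ids: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.res_ids):
            raise ValueError("res_ids length must match atom count")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _prescan_pdb_text(text: str) -> None:
    """Validate coordinate columns of ATOM/HETATM records, naming bad lines."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field {fld!r} on line {lineno}"
                    ) from None


def read_structure(pdb_text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only ATOM/HETATM records are used. Raises :class:`ParseError` naming the
    offending line for malformed coordinate fields.
    """
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise ParseError("text contains no ATOM/HETATM records")
    _prescan_pdb_text(pdb_text)
    pdb = bpdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1)
    title = ""
    for line in pdb_text.splitlines():
        if line.startswith(("TITLE", "HEADER")):
            title = line[10:].strip()
            break
    return Structure(
        chain_ids=np.asarray(atoms.chain_id, dtype="U4"),
        res_ids=np.asarray(atoms.res_id, dtype=int),
        res_names=np.asarray(atoms.res_name, dtype="U4"),
        atom_names=np.asarray(atoms.atom_name, dtype="U5"),
        coords=np.asarray(atoms.coord, dtype=float),
        hetero=np.asarray(atoms.hetero, dtype=bool),
        title=title,
    )


def read_trajectory(pdb_text: str, frame_interval: float = 1.0,
                    chain: str | None = None) -> Trajectory:
    """Read a multi-model PDB as a Cα trajectory."""
    _prescan_pdb_text(pdb_text)
    pdb = bpdb.PDBFile.read(io.StringIO(pdb_text))
    stack = pdb.get_structure()  # AtomArrayStack over models
    mask = (stack.atom_name == "CA") & ~stack.hetero
    if chain is not None:
        mask &= stack.chain_id == chain
    if not mask.any():
        raise EmptySelectionError("no Calpha atoms in trajectory")
    return Trajectory(
        coords=np.asarray(stack.coord[:, mask, :], dtype=float),
        res_ids=np.asarray(stack.res_id[mask], dtype=int),
        frame_interval=frame_interval,
    )


def read_trajectory_csv(path_or_buf, frame_interval: float = 1.0) -> Trajectory:
    """Read a trajectory from a long-format table (frame, residue, x, y, z)."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    required = {"frame", "residue", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"trajectory table missing columns: {sorted(missing)}")
    res_ids = np.sort(df["residue"].unique())
    frames = np.sort(df["frame"].unique())
    wide = df.set_index(["frame", "residue"]).sort_index()
    coords = np.empty((len(frames), len(res_ids), 3))
    for fi, f in enumerate(frames):
        sub = wide.loc[f].reindex(res_ids)
        if sub[["x", "y", "z"]].isna().any().any():
            raise ParseError(f"frame {f} is missing residues")
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(coords=coords, res_ids=res_ids, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein numbering


@dataclass(frozen=True)
class BWMap:
    """Arithmetic BW-code resolver.

    ``anchors[h]`` is the residue number of position h.50; ``helix_ranges[h]``
    bounds valid resolutions so codes are never extrapolated beyond the helix.
    """

    anchors: dict[str, int]
    helix_ranges: dict[str, tuple[int, int]]

    def resolve(self, code: str) -> int:
        helix, _, idx = str(code).partition(".")
        if not idx:
            raise BWResolutionError(f"not a BW code: {code!r}")
        if helix not in self.anchors:
            raise BWResolutionError(f"no anchor defined for helix {helix}")
        residue = self.anchors[helix] + (int(idx) - 50)
        lo, hi = self.helix_ranges[helix]
        if not lo <= residue <= hi:
            raise BWResolutionError(
                f"BW code {code} resolves to residue {residue}, outside "
                f"helix {helix} range {lo}-{hi}"
            )
        return residue


def build_bw_map(anchors: dict[str, int],
                 helix_ranges: dict[str, tuple[int, int]]) -> BWMap:
    """Validate and build a :class:`BWMap` (anchors must lie inside ranges)."""
    for helix, anchor in anchors.items():
        if helix not in helix_ranges:
            raise BWResolutionError(f"helix {helix} has an anchor but no range")
        lo, hi = helix_ranges[helix]
        if not lo <= anchor <= hi:
            raise BWResolutionError(
                f"anchor {anchor} for helix {helix} outside range {lo}-{hi}"
            )
    return BWMap(anchors=dict(anchors), helix_ranges=dict(helix_ranges))


# AT2R numbering: x.50 anchors from conserved class-A motifs
# (D1.33=45 => 1.50=62; W2.60=100 => 2.50=90; R3.50=142; N4.38=156 => 4.50=168;
#  P5.50=223; P6.50=271; P7.50=315; R8.49=324 => 8.50=325), helix ranges from
# the receptor's domain table.
DEFAULT_BW_MAP = build_bw_map(
    anchors={"1": 62, "2": 90, "3": 142, "4": 168,
             "5": 223, "6": 271, "7": 315, "8": 325},
    helix_ranges={"1": (45, 72), "2": (78, 107), "3": (112, 148),
                  "4": (156, 182), "5": (203, 241), "6": (245, 285),
                  "7": (289, 321), "8": (322, 335)},
)


# ---------------------------------------------------------------------------
# Collective variables


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion of four points, in degrees wrapped to [0, 360).

    Standard atan2 construction; raises for collinear inner triples where the
    torsion is undefined.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or b1n < 1e-12:
        raise DegenerateInputError("collinear points: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / b1n)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def _ca_lookup(frame) -> dict[int, np.ndarray]:
    if isinstance(frame, dict):
        return {int(k): np.asarray(v, dtype=float) for k, v in frame.items()}
    res_ids, coords = frame
    return {int(r): np.asarray(c, dtype=float) for r, c in zip(res_ids, coords)}


def compute_cv(frame, bw: BWMap = DEFAULT_BW_MAP) -> tuple[float, float]:
    """Compute (distance_sum [Å], dihedral [deg]) from one Cα frame.

    ``frame`` is either a mapping residue→xyz or a (res_ids, coords) pair.
    Both observables are internal coordinates, invariant under rigid motion.
    """
    ca = _ca_lookup(frame)

    def pos(code: str) -> np.ndarray:
        residue = bw.resolve(code)
        if residue not in ca:
            raise FeaturizationError(
                f"no Calpha for BW position {code} (residue {residue})"
            )
        return ca[residue]

    a, b, c = (pos(code) for code in CV_DISTANCE_CODES)
    distance_sum = float(np.linalg.norm(a - b) + np.linalg.norm(a - c))
    dihedral = dihedral_angle(*(pos(code) for code in CV_DIHEDRAL_CODES))
    return distance_sum, dihedral


def featurize_trajectory(traj: Trajectory, bw: BWMap = DEFAULT_BW_MAP) -> pd.DataFrame:
    """Per-frame collective variables as a DataFrame (frame, distance_sum, dihedral)."""
    rows = []
    for fi in range(traj.n_frames):
        d, chi = compute_cv((traj.res_ids, traj.coords[fi]), bw)
        rows.append((fi, d, chi))
    return pd.DataFrame(rows, columns=["frame", "distance_sum", "dihedral"])


# ---------------------------------------------------------------------------
# Superposition and fluctuation analyses


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimizing ||P @ R - Q|| for centered P, Q."""
    C = P.T @ Q
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superpose_trajectory(traj: Trajectory, n_iter: int = 2) -> np.ndarray:
    """Superpose every frame onto the mean structure.

    Iterates mean → fit → mean ``n_iter`` times (the mean structure is itself
    orientation-dependent). Returns superposed coordinates, original untouched.
    """
    X = traj.coords.copy()
    X -= X.mean(axis=1, keepdims=True)  # remove per-frame centroid
    for _ in range(max(1, n_iter)):
        ref = X.mean(axis=0)
        ref = ref - ref.mean(axis=0)
        for fi in range(X.shape[0]):
            R = kabsch_rotation(X[fi], ref)
            X[fi] = X[fi] @ R
    return X


def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         superpose: bool = True) -> pd.Series:
    """Per-residue root-mean-square fluctuation about the mean structure (Å)."""
    if traj.n_frames < 2:
        raise DegenerateInputError("RMSF requires at least 2 frames")
    X = superpose_trajectory(traj) if superpose else traj.coords
    disp = X - X.mean(axis=0)
    vals = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    out = pd.Series(vals, index=pd.Index(traj.res_ids, name="residue"), name="rmsf")
    if selection is not None:
        out = out.loc[list(selection)]
    return out


def pca_modes(traj: Trajectory, n_modes: int, superpose: bool = True):
    """Principal components of Cα coordinate fluctuations.

    Returns (modes, eigenvalues, per_residue) where ``modes`` has shape
    (n_modes, n_atoms, 3), eigenvalues are non-increasing (ddof=1 covariance),
    and ``per_residue[m, i]`` is the displacement magnitude of residue i within
    mode m.
    """
    X = superpose_trajectory(traj) if superpose else traj.coords
    F, N, _ = X.shape
    rank = min(F - 1, 3 * N)
    if n_modes > rank:
        raise DegenerateInputError(
            f"n_modes={n_modes} exceeds covariance rank {rank}"
        )
    flat = X.reshape(F, 3 * N)
    flat = flat - flat.mean(axis=0)
    # SVD of the centered data matrix avoids forming the 3N x 3N covariance
    _, s, Vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = (s ** 2) / (F - 1)
    modes = Vt[:n_modes].reshape(n_modes, N, 3)
    per_residue = np.linalg.norm(modes, axis=2)
    return modes, eigvals[:n_modes], per_residue


@dataclass
class DCCMMatrix:
    """Dynamic cross-correlation matrix of Cα displacement vectors."""

    values: np.ndarray
    res_ids: np.ndarray
    mask_threshold: float | None = None

    def masked(self) -> np.ndarray:
        """Display copy with |c| below the mask threshold blanked to NaN."""
        if self.mask_threshold is None:
            return self.values.copy()
        out = self.values.copy()
        out[np.abs(out) < self.mask_threshold] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.res_ids, columns=self.res_ids)


def dccm(traj: Trajectory, mask_threshold: float | None = 0.3,
         superpose: bool = True) -> DCCMMatrix:
    """Normalized covariance of residue displacement vectors.

    entry(i,j) = <Δri·Δrj> / sqrt(<|Δri|²><|Δrj|²>); +1 correlated, -1
    anti-correlated. Residues with zero variance yield NaN (undefined), never
    a silent 0. The mask threshold affects only display export.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("DCCM requires at least 2 frames")
    X = superpose_trajectory(traj) if superpose else traj.coords
    disp = X - X.mean(axis=0)
    num = np.einsum("fid,fjd->ij", disp, disp) / traj.n_frames
    var = np.einsum("fid,fid->i", disp, disp) / traj.n_frames
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = num / denom
    corr[denom == 0] = np.nan
    return DCCMMatrix(values=corr, res_ids=np.asarray(traj.res_ids),
                      mask_threshold=mask_threshold)


@dataclass
class ContactProfile:
    """Per-residue fraction of frames within a distance threshold of the ligand."""

    fractions: pd.Series
    threshold: float
    min_fraction: float
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def contact_fraction(traj: Trajectory, ligand: np.ndarray,
                     threshold: float = 4.0,
                     min_fraction: float = 0.6) -> ContactProfile:
    """Residues in frequent contact with the ligand.

    A residue is in contact in a frame if any of its atoms (Cα in reduced
    mode) is within ``threshold`` Å of any ligand atom; ``selected`` collects
    residues whose contact fraction is at least ``min_fraction``.
    """
    ligand = np.asarray(ligand, dtype=float)
    if ligand.ndim == 2:  # static ligand replicated over frames
        ligand = np.broadcast_to(ligand, (traj.n_frames,) + ligand.shape)
    if ligand.shape[0] != traj.n_frames:
        raise DegenerateInputError(
            f"ligand frames ({ligand.shape[0]}) do not align with "
            f"trajectory frames ({traj.n_frames})"
        )
    hits = np.zeros(traj.n_atoms, dtype=int)
    for fi in range(traj.n_frames):
        diff = traj.coords[fi][:, None, :] - ligand[fi][None, :, :]
        dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
        hits += dmin <= threshold
    frac = pd.Series(hits / traj.n_frames,
                     index=pd.Index(traj.res_ids, name="residue"),
                     name="contact_fraction")
    selected = np.asarray(frac.index[frac >= min_fraction])
    return ContactProfile(fractions=frac, threshold=threshold,
                          min_fraction=min_fraction, selected=selected)
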