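"""Statistical coupling analysis (SCA) of a multiple sequence alignment.

Positional conservation is the relative entropy (cross-entropy loss) of the
dominant residue's observed frequency f against a background q:

    D(f, q) = f ln(f/q) + (1-f) ln((1-f)/(1-q))

Pairwise co-evolution couples the conservation gradients with the deviation
of the joint frequency from independence:

    C_ij = dD_i/df_i * dD_j/df_j * |f_ij - f_i f_j|

with dD/df = ln[f(1-q) / (q(1-f))]. Sectors (groups of co-evolving positions)
are read off the signed loadings of the 2nd-4th eigenvectors of the C matrix:
the first mode carries global conservation/phylogenetic signal and is dropped.
An all-gap row is appended to the alignment once before any frequency is
computed, guarding against zero frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DegenerateInputError, ParseError, ValidationError

__all__ = [
    "AMINO_ACIDS", "GAP", "MSA", "ConservationProfile", "SCAMatrix",
    "SectorDefinition", "load_msa", "conservation_score",
    "conservation_gradient", "conservation_profile", "sca_matrix",
    "define_sectors", "domain_conservation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_VALID = set(AMINO_ACIDS)


@dataclass
class MSA:
    """Aligned sequences as a (rows x positions) character matrix.

    The final row is the appended all-gap guard row; ``n_sequences`` counts
    only the real sequences.
    """

    chars: np.ndarray
    ids: list[str]
    position_labels: np.ndarray | None = None
    gap_row_appended: bool = True

    @property
    def n_rows(self) -> int:
        return self.chars.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.n_rows - int(self.gap_row_appended)

    @property
    def n_positions(self) -> int:
        return self.chars.shape[1]


def load_msa(fasta_text: str, position_labels=None) -> MSA:
    """Read a FASTA alignment, normalize residues, append the gap row.

    Sequences are uppercased; any character outside the 20 standard amino
    acids is mapped to the gap symbol. Ragged alignments are rejected naming
    the offending sequence.
    """
    records = list(SeqIO.parse(StringIO(fasta_text), "fasta"))
    if not records:
        raise ParseError("no sequences found in FASTA input")
    length = len(records[0].seq)
    rows, ids = [], []
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise ParseError(
                f"sequence {rec.id!r} has length {len(seq)}, expected {length}"
            )
        rows.append([c if c in _VALID else GAP for c in seq])
        ids.append(rec.id)
    rows.append([GAP] * length)  # zero-frequency guard
    chars = np.asarray(rows, dtype="U1")
    labels = None if position_labels is None else np.asarray(position_labels)
    if labels is not None and len(labels) != length:
        raise ValidationError("position_labels length must match alignment width")
    return MSA(chars=chars, ids=ids, position_labels=labels)


def conservation_score(f: float, q: float) -> float:
    """Relative-entropy conservation D(f, q), with 0 ln 0 = 0 at f in {0, 1}."""
    if not 0.0 < q < 1.0:
        raise ValidationError(f"background frequency must be in (0,1), got {q}")
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"frequency must be in [0,1], got {f}")
    term1 = 0.0 if f == 0.0 else f * np.log(f / q)
    term2 = 0.0 if f == 1.0 else (1.0 - f) * np.log((1.0 - f) / (1.0 - q))
    return float(term1 + term2)


def conservation_gradient(f: float, q: float) -> float:
    """dD/df = ln[f(1-q) / (q(1-f))]; diverges at f in {0, 1}."""
    if not 0.0 < f < 1.0:
        raise DegenerateInputError(
            f"conservation gradient undefined at f={f} (needs 0<f<1)"
        )
    return float(np.log(f * (1.0 - q) / (q * (1.0 - f))))


@dataclass
class ConservationProfile:
    dominant: np.ndarray       # dominant residue per position ('' if all-gap)
    frequency: np.ndarray      # f of the dominant residue (over all rows)
    score: np.ndarray          # D per position
    position_labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.position_labels,
            "dominant": self.dominant,
            "frequency": self.frequency,
            "conservation": self.score,
        })


def _dominant_residues(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    """Modal residue per column (gaps never dominate; ties alphabetical)."""
    n_rows = msa.n_rows
    dominant = np.empty(msa.n_positions, dtype="U1")
    freq = np.zeros(msa.n_positions)
    for j in range(msa.n_positions):
        col = msa.chars[:, j]
        residues, counts = np.unique(col[col != GAP], return_counts=True)
        if residues.size == 0:
            dominant[j] = ""
            continue
        best = np.argmax(counts)  # np.unique sorts, so ties fall alphabetical
        dominant[j] = residues[best]
        freq[j] = counts[best] / n_rows  # gap row inflates the denominator
    return dominant, freq


def conservation_profile(msa: MSA, q: float = 0.05) -> ConservationProfile:
    """Per-position dominant residue, frequency, and conservation score."""
    dominant, freq = _dominant_residues(msa)
    score = np.array([
        conservation_score(f, q) if a else 0.0
        for a, f in zip(dominant, freq)
    ])
    labels = (msa.position_labels if msa.position_labels is not None
              else np.arange(1, msa.n_positions + 1))
    return ConservationProfile(dominant=dominant, frequency=freq, score=score,
                               position_labels=np.asarray(labels))


@dataclass
class SCAMatrix:
    values: np.ndarray
    dominant: np.ndarray
    position_labels: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]


def sca_matrix(msa: MSA, q: float = 0.05, zero_diagonal: bool = True) -> SCAMatrix:
    """Pairwise co-evolution matrix over the dominant residues.

    Joint frequencies count rows carrying the dominant residue at both
    positions; the gap guard row enters every denominator, keeping all
    frequencies strictly inside (0, 1). All-gap columns yield zero rows with
    a warning. The diagonal (pure self-conservation) is zeroed by default so
    the eigenvector sectors are driven by coupling.
    """
    if msa.n_positions < 2:
        raise ValidationError("SCA needs at least 2 aligned positions")
    dominant, freq = _dominant_residues(msa)
    dead = dominant == ""
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-gap position(s) produce zero SCA rows",
            stacklevel=2)
    n_rows = msa.n_rows
    indic = np.zeros((n_rows, msa.n_positions))
    grad = np.zeros(msa.n_positions)
    for j in range(msa.n_positions):
        if dead[j]:
            continue
        indic[:, j] = msa.chars[:, j] == dominant[j]
        grad[j] = conservation_gradient(freq[j], q)
    joint = indic.T @ indic / n_rows              # f_ij
    coupling = np.abs(joint - np.outer(freq, freq))
    C = np.outer(grad, grad) * coupling
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    if zero_diagonal:
        np.fill_diagonal(C, 0.0)
    labels = (msa.position_labels if msa.position_labels is not None
              else np.arange(1, msa.n_positions + 1))
    return SCAMatrix(values=C, dominant=dominant,
                     position_labels=np.asarray(labels))


@dataclass
class SectorDefinition:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray    # columns, sorted by eigenvalue descending
    epsilon: float
    red: np.ndarray             # indices into positions
    blue: np.ndarray

    def red_labels(self, labels) -> np.ndarray:
        return np.asarray(labels)[self.red]


def define_sectors(C: SCAMatrix | np.ndarray, epsilon: float = 0.05) -> SectorDefinition:
    """Eigenvector sectors of the SCA matrix.

    The first mode (global conservation) is dropped; with v2 and v4 the signed
    loadings of the 2nd and 4th eigenvectors (each sign-fixed so its largest-
    magnitude component is positive):

      red  = { i : v2_i > v4_i  and v2_i >  eps }
      blue = { i : (v2_i < v4_i and v2_i < -eps) or (v4_i > v2_i and v4_i > eps) }

    The two sets are disjoint by construction.
    """
    values = C.values if isinstance(C, SCAMatrix) else np.asarray(C, dtype=float)
    n = values.shape[0]
    if n < 4:
        raise ValidationError("sector definition needs at least 4 positions")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValidationError("SCA matrix must be symmetric")
    w, V = np.linalg.eigh(values)
    order = np.argsort(-w)
    w, V = w[order], V[:, order]
    for k in range(V.shape[1]):  # reproducible sign convention
        pivot = np.argmax(np.abs(V[:, k]))
        if V[pivot, k] < 0:
            V[:, k] = -V[:, k]
    v2, v4 = V[:, 1], V[:, 3]
    red = np.flatnonzero((v2 > v4) & (v2 > epsilon))
    blue = np.flatnonzero(((v2 < v4) & (v2 < -epsilon))
                          | ((v4 > v2) & (v4 > epsilon)))
    return SectorDefinition(eigenvalues=w, eigenvectors=V, epsilon=epsilon,
                            red=red, blue=blue)


def domain_conservation(profile: ConservationProfile,
                        domains: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Mean +/- sample sd of conservation over named residue ranges.

    ``domains`` maps a domain name to a list of inclusive (first, last) label
    ranges; composite rows simply list several ranges and pool their
    positions. Ranges matching no aligned position are omitted with a warning.
    """
    labels = np.asarray(profile.position_labels)
    rows = []
    for name, ranges in domains.items():
        mask = np.zeros(len(labels), dtype=bool)
        for lo, hi in ranges:
            mask |= (labels >= lo) & (labels <= hi)
        if not mask.any():
            warnings.warn(f"domain {name!r} matches no aligned positions; omitted",
                          stacklevel=2)
            continue
        vals = profile.score[mask]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append((name, int(mask.sum()), float(vals.mean()), sd))
    return pd.DataFrame(rows, columns=["domain", "n_positions", "mean", "sd"])
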