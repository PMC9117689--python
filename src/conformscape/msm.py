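"""Markov state model over microstates in collective-variable space.

Pipeline: z-score the two CVs, k-means into microstates, count lagged
transitions within (never across) trajectories, row-normalize into a
transition probability matrix, check Markovianity through the implied
timescale test t_i = -tau / ln(lambda_i), lump microstates into metastable
macrostates with PCCA+, and compute committors / mean first passage times
between macrostates with transition path theory. Representative conformations
are picked by the similarity score S_ij = exp(-d_ij / d_scale) with d_scale
the standard deviation of the pairwise distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "MicrostateModel", "TransitionModel", "ImpliedTimescaleScan", "LagChoice",
    "MacrostateModel", "TPTResult",
    "cluster_microstates", "estimate_tpm", "implied_timescales", "choose_lag",
    "pcca_macrostates", "macro_label_frames", "mfpt", "representative_frame",
]


# ---------------------------------------------------------------------------
# Microstate clustering


@dataclass
class MicrostateModel:
    k: int
    centers: np.ndarray          # (k, n_cv) in standardized space
    assignments: list[np.ndarray]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    seed: int


def _as_cv_arrays(features) -> list[np.ndarray]:
    if isinstance(features, pd.DataFrame):
        features = [features]
    elif isinstance(features, np.ndarray) and features.ndim == 2:
        features = [features]
    out = []
    for f in features:
        if isinstance(f, pd.DataFrame):
            arr = f[["distance_sum", "dihedral"]].to_numpy(dtype=float)
        else:
            arr = np.asarray(f, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("each feature series must be 2-D (frames x CVs)")
        out.append(arr)
    return out


def cluster_microstates(features, k: int = 500, seed: int = 0,
                        auto_scale: bool = True) -> MicrostateModel:
    """K-means microstates on z-scored CVs.

    Z-scoring first puts the two CVs (Å vs degrees) on a common scale so the
    clustering is not dihedral-dominated. With ``auto_scale`` the requested k
    is capped at one tenth of the available frames so small synthetic inputs
    do not fragment into singleton clusters.
    """
    series = _as_cv_arrays(features)
    X = np.vstack(series)
    total = X.shape[0]
    if total < k and not auto_scale:
        raise ValidationError(
            f"{total} frames cannot support k={k} microstates; reduce k "
            f"(at most ~{max(1, total // 10)} is reasonable)"
        )
    k_eff = min(k, max(1, total // 10)) if auto_scale else k
    if total < k_eff:
        raise ValidationError(f"{total} frames < k={k_eff}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=1)
    labels = km.fit_predict(Z)
    # prune empty clusters (possible after Lloyd convergence) and relabel
    occupied = np.unique(labels)
    remap = -np.ones(k_eff, dtype=int)
    remap[occupied] = np.arange(len(occupied))
    labels = remap[labels]
    centers = km.cluster_centers_[occupied]
    lengths = [len(s) for s in series]
    splits = np.cumsum(lengths)[:-1]
    return MicrostateModel(
        k=len(occupied), centers=centers,
        assignments=[np.asarray(a) for a in np.split(labels, splits)],
        scale_mean=mean, scale_sd=sd, seed=seed,
    )


def assign(model: MicrostateModel, features) -> list[np.ndarray]:
    """Map new CV frames to the nearest microstate center."""
    out = []
    for arr in _as_cv_arrays(features):
        Z = (arr - model.scale_mean) / model.scale_sd
        d2 = ((Z[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
        out.append(np.argmin(d2, axis=1))
    return out


# ---------------------------------------------------------------------------
# Transition matrix estimation


@dataclass
class TransitionModel:
    lag_frames: int
    lag_time: float                 # physical lag, ns
    counts: np.ndarray              # raw (un-symmetrized) counts, active set
    transition_matrix: np.ndarray   # row-stochastic
    eigenvalues: np.ndarray         # sorted by |lambda| descending
    stationary: np.ndarray
    states: np.ndarray              # active-set microstate labels
    mode: str = "symmetrized"

    @property
    def n_states(self) -> int:
        return len(self.states)


def _count_transitions(assignments, lag: int, n_states: int) -> np.ndarray:
    C = np.zeros((n_states, n_states))
    for seq in assignments:
        seq = np.asarray(seq)
        if len(seq) < lag + 1:
            raise ValidationError(
                f"trajectory of {len(seq)} frames shorter than lag+1={lag + 1}"
            )
        np.add.at(C, (seq[:-lag], seq[lag:]), 1.0)
    return C


def estimate_tpm(assignments, lag: int, mode: str = "symmetrized",
                 frame_interval: float = 1.0) -> TransitionModel:
    """Estimate a transition probability matrix at one lag.

    Sliding-window counts within each trajectory; ``symmetrized`` (default)
    row-normalizes (C + C^T)/2 giving a reversible chain, ``naive``
    row-normalizes C as counted. Estimation is restricted to the largest
    strongly connected set of the count graph.
    """
    if mode not in ("symmetrized", "naive"):
        raise ValidationError(f"unknown estimation mode {mode!r}")
    seqs = [np.asarray(s, dtype=int) for s in assignments]
    n_states = int(max(s.max() for s in seqs)) + 1
    C = _count_transitions(seqs, lag, n_states)
    n_comp, comp = connected_components(csr_matrix(C > 0), directed=True,
                                        connection="strong")
    sizes = np.bincount(comp, weights=C.sum(axis=1) + C.sum(axis=0))
    keep = np.flatnonzero(comp == np.argmax(sizes))
    if len(keep) < n_states:
        warnings.warn(
            f"count graph not strongly connected; restricting to largest "
            f"component ({len(keep)}/{n_states} states)", stacklevel=2)
    Ck = C[np.ix_(keep, keep)]
    Cest = 0.5 * (Ck + Ck.T) if mode == "symmetrized" else Ck
    rows = Cest.sum(axis=1)
    nonzero = rows > 0
    Ck, Cest, keep, rows = Ck[np.ix_(nonzero, nonzero)], \
        Cest[np.ix_(nonzero, nonzero)], keep[nonzero], rows[nonzero]
    T = Cest / Cest.sum(axis=1, keepdims=True)
    evals, levecs = np.linalg.eig(T.T)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    pi = np.real(levecs[:, order[0]])
    pi = np.abs(pi) / np.abs(pi).sum()
    if mode == "symmetrized":
        # exact stationary law of the symmetrized estimator
        pi = Cest.sum(axis=1) / Cest.sum()
    return TransitionModel(
        lag_frames=lag, lag_time=lag * frame_interval, counts=Ck,
        transition_matrix=T, eigenvalues=np.real_if_close(evals, tol=1e6),
        stationary=pi, states=keep, mode=mode,
    )


# ---------------------------------------------------------------------------
# Implied timescales and lag choice


@dataclass
class ImpliedTimescaleScan:
    lags: np.ndarray            # frames
    lag_times: np.ndarray       # ns
    timescales: np.ndarray      # (n_lags, m) ns; NaN undefined, inf for lambda->1

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{i + 2}" for i in range(self.timescales.shape[1])]
        df = pd.DataFrame(self.timescales, columns=cols)
        df.insert(0, "lag_time", self.lag_times)
        df.insert(0, "lag_frames", self.lags)
        return df


def timescale_from_eigenvalue(lam: complex, lag_time: float) -> float:
    """Eq of the implied timescale test: t = -tau / ln(lambda).

    Non-real or non-positive eigenvalues have no relaxation interpretation and
    map to NaN; lambda >= 1 maps to infinity.
    """
    if np.iscomplexobj(lam) and abs(np.imag(lam)) > 1e-10:
        return float("nan")
    lam = float(np.real(lam))
    if lam <= 0.0:
        return float("nan")
    if lam >= 1.0:
        return float("inf")
    return -lag_time / np.log(lam)


def implied_timescales(assignments, lags, mode: str = "symmetrized",
                       frame_interval: float = 1.0,
                       n_timescales: int = 4) -> ImpliedTimescaleScan:
    """Implied timescale scan over lag times (physical units)."""
    lags = np.asarray(sorted(lags), dtype=int)
    if (lags <= 0).any():
        raise ValidationError("lags must be positive")
    rows = []
    for lag in lags:
        model = estimate_tpm(assignments, int(lag), mode=mode,
                             frame_interval=frame_interval)
        ev = model.eigenvalues[1:n_timescales + 1]
        ts = [timescale_from_eigenvalue(l, model.lag_time) for l in ev]
        ts += [float("nan")] * (n_timescales - len(ts))
        rows.append(ts)
    return ImpliedTimescaleScan(
        lags=lags, lag_times=lags * frame_interval,
        timescales=np.asarray(rows, dtype=float),
    )


@dataclass
class LagChoice:
    lag_frames: int
    lag_time: float
    markovian: bool
    max_variation: float


def choose_lag(scan: ImpliedTimescaleScan, flatness_tol: float = 0.10) -> LagChoice:
    """Smallest lag past which the slowest implied timescale is flat.

    Chooses the first lag whose slowest timescale differs by less than
    ``flatness_tol`` (relative) from its value at every larger scanned lag.
    When no lag qualifies the largest lag is returned flagged non-Markovian.
    """
    if len(scan.lags) < 3:
        raise ValidationError("lag scan needs at least 3 lags")
    slowest = scan.timescales[:, 0]
    for i in range(len(scan.lags) - 1):
        ref = slowest[i]
        if not np.isfinite(ref) or ref <= 0:
            continue
        var = np.max(np.abs(slowest[i + 1:] - ref)) / ref
        if var < flatness_tol:
            return LagChoice(int(scan.lags[i]), float(scan.lag_times[i]),
                             True, float(var))
    ref = slowest[-1]
    var = float("nan") if not np.isfinite(ref) else 0.0
    return LagChoice(int(scan.lags[-1]), float(scan.lag_times[-1]), False,
                     float(var))


# ---------------------------------------------------------------------------
# PCCA+ macrostates


@dataclass
class MacrostateModel:
    n_macro: int
    micro_to_macro: np.ndarray       # crisp assignment per active microstate
    memberships: np.ndarray          # fuzzy chi, (n_states, n_macro)
    proportions: np.ndarray          # stationary-weighted
    states: np.ndarray               # active-set microstate labels
    representative_frames: dict = field(default_factory=dict)


def _right_eigenvectors(model: TransitionModel, m: int) -> np.ndarray:
    """pi-orthonormal right eigenvectors of a reversible T, dominant first."""
    pi = model.stationary
    dh = np.sqrt(pi)
    M = dh[:, None] * model.transition_matrix / dh[None, :]
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    order = np.argsort(-w)
    psi = V[:, order[:m]] / dh[:, None]
    # fix the trivial eigenvector to the constant +1
    psi[:, 0] = psi[:, 0] * np.sign(psi[0, 0]) if psi[0, 0] != 0 else 1.0
    return psi


def _inner_simplex(X: np.ndarray) -> np.ndarray:
    """PCCA+ inner simplex algorithm: memberships from extreme vertices."""
    n, m = X.shape
    index = np.zeros(m, dtype=int)
    index[0] = int(np.argmax(np.linalg.norm(X, axis=1)))
    ortho = X - X[index[0]]
    for j in range(1, m):
        dist = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(dist))
        v = ortho[index[j]]
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            v = v / nv
            ortho = ortho - np.outer(ortho @ v, v)
    A = np.linalg.inv(X[index])
    return X @ A


def pcca_macrostates(model: TransitionModel, n_macro: int = 3,
                     assignments=None) -> MacrostateModel:
    """Lump microstates into metastable macrostates (PCCA+, crisp by argmax).

    Macrostate proportions are stationary-probability sums over member
    microstates; pass ``assignments`` to also weight by raw frame counts via
    :func:`macro_label_frames`.
    """
    n = model.n_states
    if n_macro > n:
        raise ValidationError(f"n_macro={n_macro} exceeds {n} microstates")
    ev = np.real(model.eigenvalues)
    if n_macro < n and abs(ev[n_macro - 1] - ev[n_macro]) < 1e-6:
        warnings.warn(
            f"no spectral gap after eigenvalue {n_macro} "
            f"({ev[n_macro - 1]:.8f} vs {ev[n_macro]:.8f}); lumping ambiguous",
            stacklevel=2)
    if n_macro == n:
        chi = np.eye(n)
    else:
        psi = _right_eigenvectors(model, n_macro)
        chi = _inner_simplex(psi)
    crisp = np.argmax(chi, axis=1)
    # guarantee non-empty macrostates: each simplex vertex claims its own state
    for m in range(n_macro):
        if not (crisp == m).any():
            crisp[int(np.argmax(chi[:, m]))] = m
    proportions = np.array([model.stationary[crisp == m].sum()
                            for m in range(n_macro)])
    return MacrostateModel(n_macro=n_macro, micro_to_macro=crisp,
                           memberships=chi, proportions=proportions,
                           states=model.states)


def macro_label_frames(assignments, model: TransitionModel,
                       macro: MacrostateModel) -> list[np.ndarray]:
    """Per-frame macrostate labels (-1 for frames outside the active set)."""
    n_total = int(max(np.max(s) for s in assignments)) + 1
    lookup = -np.ones(max(n_total, model.states.max() + 1), dtype=int)
    lookup[model.states] = macro.micro_to_macro
    return [lookup[np.asarray(s, dtype=int)] for s in assignments]


def count_proportions(labels: list[np.ndarray], n_macro: int) -> np.ndarray:
    """Macrostate proportions by raw frame counts (active-set frames only)."""
    pooled = np.concatenate(labels)
    pooled = pooled[pooled >= 0]
    return np.bincount(pooled, minlength=n_macro) / len(pooled)


# ---------------------------------------------------------------------------
# Transition path theory


@dataclass
class TPTResult:
    source: np.ndarray
    sink: np.ndarray
    committor: np.ndarray
    mfpt: float            # physical units (frame_interval x lag frames per step)
    lag_time: float


def mfpt(model: TransitionModel, source, sink) -> TPTResult:
    """Forward committor and mean first passage time from source to sink.

    The committor solves the standard linear system with q=0 on the source
    and q=1 on the sink; the MFPT makes the sink absorbing, solves the
    first-passage system with step length equal to the model's physical lag,
    and averages over source states weighted by the stationary law restricted
    to the source. An unreachable sink yields an infinite MFPT.
    """
    source = np.asarray(sorted(set(int(s) for s in source)), dtype=int)
    sink = np.asarray(sorted(set(int(s) for s in sink)), dtype=int)
    if len(source) == 0 or len(sink) == 0:
        raise ValidationError("source and sink must be non-empty")
    if np.intersect1d(source, sink).size:
        raise ValidationError("source and sink must be disjoint")
    n = model.n_states
    T = model.transition_matrix
    q = np.zeros(n)
    q[sink] = 1.0
    inner = np.setdiff1d(np.arange(n), np.concatenate([source, sink]))
    if inner.size:
        A = np.eye(inner.size) - T[np.ix_(inner, inner)]
        b = T[np.ix_(inner, sink)].sum(axis=1)
        try:
            q[inner] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            q[inner] = np.linalg.lstsq(A, b, rcond=None)[0]
    # first-passage times with sink absorbing
    notsink = np.setdiff1d(np.arange(n), sink)
    A = np.eye(notsink.size) - T[np.ix_(notsink, notsink)]
    dt = model.lag_time
    try:
        t_part = np.linalg.solve(A, np.full(notsink.size, dt))
        t = np.zeros(n)
        t[notsink] = t_part
        if (t_part < 0).any() or not np.all(np.isfinite(t_part)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        t = np.full(n, np.inf)
        t[sink] = 0.0
    w = model.stationary[source]
    w = w / w.sum() if w.sum() > 0 else np.full(len(source), 1 / len(source))
    value = float(np.dot(w, t[source]))
    return TPTResult(source=source, sink=sink, committor=q, mfpt=value,
                     lag_time=model.lag_time)


# ---------------------------------------------------------------------------
# Representative conformation


def representative_frame(pairwise_d: np.ndarray) -> int:
    """Most central frame by the similarity score S_ij = exp(-d_ij / d_scale).

    d_scale is the standard deviation of the upper-triangle distances; the
    frame maximizing the summed similarity to all others wins, ties broken by
    lowest index. A fully degenerate (all-zero) distance matrix returns 0.
    """
    d = np.asarray(pairwise_d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("pairwise distance matrix must be square")
    if d.shape[0] == 1:
        return 0
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    iu = np.triu_indices(d.shape[0], k=1)
    d_scale = float(np.std(d[iu]))
    if d_scale == 0.0:
        return 0
    S = np.exp(-d / d_scale)
    scores = S.sum(axis=1)
    return int(np.argmax(scores))
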