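"""Group spatial ICA with GICA1 back-projection.

The group decomposition follows the temporal-concatenation recipe:
per-run variance normalization, row-stacking along time, a single-stage
group PCA down to the model order, fastICA on the reduced data for
maximally independent spatial sources, and GICA1 back-projection — the
concatenated mixing matrix is estimated by regressing the concatenated
data on the group maps and each run's block is pseudo-inverted against
that run's data to give subject-level maps and time courses.

Component identity is canonicalised (variance ordering, non-negative
skewness, unit-variance maps) so a decomposition is bit-reproducible
given (data, seed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .errors import ConvergenceError
from .preprocess import PreprocessedRun

#: expected value of log cosh for a standard normal variable
_GAUSS_LOGCOSH = 0.3745672


def variance_normalize(run_matrix: np.ndarray):
    """Zero-mean, unit-variance scaling of every voxel column of a
    (t, voxels) matrix.

    Zero-variance voxels are set to all-zero and their indices returned
    alongside the normalized matrix.
    """
    X = np.asarray(run_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xn = (X - mean) / sd_safe
    if zero.size:
        Xn[:, zero] = 0.0
    return Xn, zero


def concat_temporal(run_matrices: list[np.ndarray],
                    run_ids: list | None = None):
    """Row-stack (t_i, voxels) matrices along time.

    Returns the stacked matrix and a provenance table with one row per
    stacked time point (run identifier, volume index within run).
    """
    if not run_matrices:
        raise ValueError("no runs to concatenate")
    v = run_matrices[0].shape[1]
    for m in run_matrices:
        if m.shape[1] != v:
            raise ValueError(
                f"voxel dimension mismatch: {m.shape[1]} != {v}"
            )
    if run_ids is None:
        run_ids = list(range(len(run_matrices)))
    rows = []
    for rid, m in zip(run_ids, run_matrices):
        rows.append(pd.DataFrame({"run": [rid] * m.shape[0],
                                  "volume": np.arange(m.shape[0])}))
    provenance = pd.concat(rows, ignore_index=True)
    return np.vstack(run_matrices), provenance


def group_pca_reduce(X: np.ndarray, k: int, seed: int = 0):
    """Top-k principal subspace of the temporal covariance of ``X``
    (T_total, voxels).

    Returns ``(reduced, projection, explained)`` with ``reduced`` the
    (k, voxels) projected data, ``projection`` the (T_total, k) orthonormal
    temporal basis, and ``explained`` the top-k eigenvalues of the
    temporal covariance (sum-of-squares scale).  Exact SVD is used when
    the smaller matrix dimension is modest; a seeded randomized SVD
    otherwise.
    """
    X = np.asarray(X, dtype=float)
    T, V = X.shape
    if not (1 <= k <= min(T, V)):
        raise ValueError(f"k={k} must be in [1, min(T,V)={min(T, V)}]")
    if min(T, V) <= 1024:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    else:
        U, s, Vt = randomized_svd(
            X, n_components=k, n_iter=7, random_state=seed
        )
    # canonical sign: largest-magnitude loading of each temporal basis
    # vector is positive
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    U = U * flip
    reduced = U.T @ X          # == diag(s) @ Vt up to the sign convention
    return reduced, U, s**2


def fastica_spatial(reduced: np.ndarray, seed: int = 0, n_restarts: int = 5,
                    tol: float = 1e-6, max_iter: int = 1000,
                    allow_unconverged: bool = False):
    """FastICA on reduced (k, voxels) data, treating voxels as samples.

    Logcosh contrast with symmetric decorrelation; up to ``n_restarts``
    seeded restarts, keeping the converged run with the largest total
    negentropy proxy.  If no restart converges, raises
    :class:`ConvergenceError` with per-restart diagnostics — or, with
    ``allow_unconverged=True``, warns and keeps the best-contrast restart
    (symmetric FastICA commonly stalls just above a strict tolerance when
    one subspace direction is close to Gaussian).
    """
    X = np.asarray(reduced, dtype=float)
    k = X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 components")
    best = None
    best_any = None
    diagnostics = []
    for r in range(n_restarts):
        ica = FastICA(
            n_components=k, algorithm="parallel", fun="logcosh",
            whiten="unit-variance", tol=tol, max_iter=max_iter,
            random_state=seed + r,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X.T).T   # (k, voxels)
        converged = ica.n_iter_ < max_iter
        sd = sources.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        s_unit = sources / sd
        contrast = float(
            ((np.log(np.cosh(s_unit)).mean(axis=1) - _GAUSS_LOGCOSH) ** 2).sum()
        )
        diagnostics.append(
            {"restart": r, "seed": seed + r, "n_iter": int(ica.n_iter_),
             "converged": converged, "contrast": contrast}
        )
        if converged and (best is None or contrast > best[0]):
            best = (contrast, s_unit, ica)
        if best_any is None or contrast > best_any[0]:
            best_any = (contrast, s_unit, ica)
    if best is None:
        if not allow_unconverged:
            raise ConvergenceError(
                f"no FastICA restart converged in {max_iter} iterations",
                diagnostics=diagnostics,
            )
        warnings.warn(
            f"no FastICA restart converged in {max_iter} iterations; "
            "keeping the best-contrast restart", RuntimeWarning,
        )
        best = best_any
    _, sources, ica = best
    # unmixing from reduced data to unit-variance sources
    unmixing = np.linalg.lstsq(X.T, sources.T, rcond=None)[0].T  # (k, k)
    return unmixing, sources


@dataclass
class GroupDecomposition:
    """Group spatial ICA result at one model order."""

    model_order: int
    group_maps: np.ndarray            # (k, voxels), unit variance, skew >= 0
    mixing: np.ndarray                # (T_total, k) concatenated mixing
    provenance: pd.DataFrame          # run/volume per concatenated row
    subject_timecourses: dict         # run id -> (t, k)
    run_maps: dict                    # run id -> (k, voxels)
    subject_maps: dict                # subject id -> (k, voxels), run-averaged
    explained_variance: np.ndarray    # (k,) data variance fraction
    seed: int
    zero_variance_voxels: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.group_maps.shape[1]


def _canonicalize(sources: np.ndarray, Y: np.ndarray):
    """Order components by explained variance, fix sign by skewness >= 0,
    scale maps to unit variance.  Returns (maps, mixing, explained)."""
    k = sources.shape[0]
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = sources / sd
    # mixing by least squares of concatenated data on the maps
    A = np.linalg.lstsq(S.T, Y.T, rcond=None)[0].T      # (T, k)
    total = float((Y**2).sum())
    # ||a s^T||_F^2 = ||a||^2 ||s||^2
    ev = (A**2).sum(axis=0) * (S**2).sum(axis=1) / total
    order = np.argsort(-ev)
    S, A, ev = S[order], A[:, order], ev[order]
    signs = np.where(skew(S, axis=1) < 0, -1.0, 1.0)
    S = S * signs[:, None]
    A = A * signs[None, :]
    return S, A, ev


def backproject_gica1(group_maps: np.ndarray, mixing: np.ndarray,
                      provenance: pd.DataFrame, run_matrices: dict):
    """GICA1 back-projection to per-run maps and time courses.

    Each run's block of the concatenated mixing matrix gives its time
    courses; the run map is ``pinv(A_run) @ Y_run`` on that run's
    variance-normalized data.
    """
    timecourses, run_maps = {}, {}
    for rid, Y_run in run_matrices.items():
        block = provenance["run"] == rid
        A_run = mixing[np.asarray(block)]
        if A_run.shape[0] != Y_run.shape[0]:
            raise ValueError(f"provenance/run mismatch for {rid}")
        if np.linalg.matrix_rank(A_run) < A_run.shape[1]:
            warnings.warn(f"rank-deficient mixing block for run {rid}; "
                          "using pseudo-inverse", RuntimeWarning)
        timecourses[rid] = A_run
        run_maps[rid] = np.linalg.pinv(A_run) @ Y_run
    return timecourses, run_maps


def run_gica(runs: list[PreprocessedRun], k: int, seed: int = 0,
             n_restarts: int = 5) -> GroupDecomposition:
    """Full group decomposition of a list of preprocessed runs."""
    run_ids = [(r.subject_id, r.run_index) for r in runs]
    normalized, zero_vox = {}, {}
    for r in runs:
        Xn, zeros = variance_normalize(r.data)
        normalized[(r.subject_id, r.run_index)] = Xn
        if zeros.size:
            zero_vox[(r.subject_id, r.run_index)] = zeros
    Y, provenance = concat_temporal(
        [normalized[rid] for rid in run_ids], run_ids=run_ids
    )
    reduced, _, _ = group_pca_reduce(Y, k, seed=seed)
    _, sources = fastica_spatial(reduced, seed=seed, n_restarts=n_restarts,
                                 allow_unconverged=True)
    maps, mixing, ev = _canonicalize(sources, Y)
    timecourses, run_maps = backproject_gica1(maps, mixing, provenance, normalized)

    subject_maps: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for (sid, ridx), m in run_maps.items():
        subject_maps[sid] = subject_maps.get(sid, 0) + m
        counts[sid] = counts.get(sid, 0) + 1
    subject_maps = {sid: m / counts[sid] for sid, m in subject_maps.items()}

    return GroupDecomposition(
        model_order=k, group_maps=maps, mixing=mixing, provenance=provenance,
        subject_timecourses=timecourses, run_maps=run_maps,
        subject_maps=subject_maps, explained_variance=ev, seed=seed,
        zero_variance_voxels=zero_vox,
    )
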