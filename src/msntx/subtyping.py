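"""Semi-supervised polytope subtyping (HYDRA), ARI and model selection.

Patients are separated from controls by K linear max-margin hyperplanes
forming a convex polytope; each patient is clustered by the face that
assigns it the largest margin.  The joint objective minimized by
alternation is

    sum_j [ 1/2 ||w_j||^2
            + C * sum_{controls} (1/K) * hinge(1 + w_j.x + b_j)
            + C * sum_{patients} s_ij * hinge(1 - w_j.x - b_j) ]

with hard assignments s_ij in {0,1}, sum_j s_ij = 1.  Control hinge losses
are shared across faces at weight 1/K.  Final assignments come from
average-linkage clustering of a co-assignment consensus matrix built over
several seeded restarts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import AgglomerativeClustering, kmeans_plusplus
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ConfigError


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    Returns 1.0 for identical partitions up to relabelling; 1.0 is also
    returned in the degenerate all-singletons / single-block case where
    M == E.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D label vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_cells = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    mx = 0.5 * (sum_a + sum_b)
    if mx == expected:
        return 1.0
    return float((sum_cells - expected) / (mx - expected))


# ---------------------------------------------------------------------------
# covariate residualization (inputs to HYDRA)
# ---------------------------------------------------------------------------


def residualize_strengths(
    strengths: np.ndarray, meta: pd.DataFrame, fit_on: str = "control"
) -> np.ndarray:
    """Residualize subject x region strengths on age, sex (M=0/F=1) and TIV.

    The linear model is fit on the ``fit_on`` group only (controls by
    default) and applied to every subject, so patient-specific effects are
    not absorbed into the nuisance fit.
    """
    strengths = np.asarray(strengths, dtype=float)
    sex01 = (meta["sex"].to_numpy() == "F").astype(float)
    design = np.column_stack(
        [np.ones(len(meta)), meta["age"].to_numpy(float), sex01, meta["tiv"].to_numpy(float)]
    )
    fit_mask = (meta["group"].to_numpy() == fit_on) if fit_on else np.ones(len(meta), bool)
    beta, *_ = np.linalg.lstsq(design[fit_mask], strengths[fit_mask], rcond=None)
    return strengths - design @ beta


# ---------------------------------------------------------------------------
# HYDRA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubtypeSolution:
    """Fitted polytope: hyperplanes, patient assignments, consensus matrix."""

    k: int
    hyperplanes: list[tuple[np.ndarray, float]]
    assignments: np.ndarray  # patient -> cluster 1..K, over patient rows of X
    consensus_matrix: np.ndarray
    objective_trace: np.ndarray
    patient_index: np.ndarray  # row indices of patients in the input X


@dataclasses.dataclass
class ModelSelection:
    k_range: list[int]
    cv_ari: dict[int, float]
    chosen_k: int


def _fit_faces(X, is_patient, assignments, K, C, tol):
    """One hyperplane-estimation step: K weighted soft-margin linear fits.

    A face with no assigned patients gets its exact block optimum
    (w = 0, b = -1): zero margin cost on every control and zero norm.
    """
    labels = np.where(is_patient, 1.0, -1.0)
    faces = []
    pat_rows = np.flatnonzero(is_patient)
    for j in range(1, K + 1):
        members = pat_rows[assignments == j]
        if members.size == 0:
            faces.append((np.zeros(X.shape[1]), -1.0))
            continue
        keep = ~is_patient.copy()
        keep[members] = True
        sw = np.where(is_patient[keep], C, C / K)
        clf = SVC(kernel="linear", C=1.0, tol=tol)
        clf.fit(X[keep], labels[keep], sample_weight=sw)
        faces.append((clf.coef_.ravel().copy(), float(clf.intercept_[0])))
    return faces


def _margins(X_pat, faces):
    return np.column_stack([X_pat @ w + b for w, b in faces])


def _objective(X, is_patient, faces, assignments, C):
    K = len(faces)
    X_ctrl = X[~is_patient]
    X_pat = X[is_patient]
    total = 0.0
    for j, (w, b) in enumerate(faces, start=1):
        total += 0.5 * float(w @ w)
        total += (C / K) * np.maximum(0.0, 1.0 + (X_ctrl @ w + b)).sum()
        members = X_pat[assignments == j]
        if len(members):
            total += C * np.maximum(0.0, 1.0 - (members @ w + b)).sum()
    return total


def _repair_empty_faces(assignments, margins, K):
    """Reseed empty faces with worst-margin patients.

    Donors are only taken from faces with more than one member so repairing
    one face never empties another; a moved patient is not moved again.
    """
    margins = margins.copy()
    while True:
        counts = np.bincount(assignments, minlength=K + 1)
        empty = np.flatnonzero(counts[1:] == 0) + 1
        if empty.size == 0:
            return assignments
        best = margins.max(axis=1)
        best[counts[assignments] <= 1] = np.inf
        worst = int(np.argmin(best))
        assignments[worst] = empty[0]
        margins[worst, :] = np.inf
    return assignments


def hydra_single_run(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    C: float = 0.25,
    n_iter: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
):
    """One alternating optimization from a k-means++ seeded start.

    Returns ``(assignments, faces, objective_trace)``; the trace records the
    objective after each complete (hyperplane fit + reassignment) alternation
    and is non-increasing up to solver tolerance.
    """
    is_patient = np.asarray(y).astype(bool)
    X_pat = X[is_patient]
    n_pat = int(is_patient.sum())
    if K > n_pat:
        raise ConfigError(f"K={K} exceeds the number of patients ({n_pat})")
    if K == 1:
        assignments = np.ones(n_pat, dtype=int)
        faces = _fit_faces(X, is_patient, assignments, 1, C, tol)
        return assignments, faces, np.array([_objective(X, is_patient, faces, assignments, C)])

    centers, _ = kmeans_plusplus(X_pat, n_clusters=K, random_state=int(seed))
    d2 = ((X_pat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignments = d2.argmin(axis=1) + 1
    assignments = _repair_empty_faces(assignments, -d2, K)

    trace = []
    for _ in range(n_iter):
        faces = _fit_faces(X, is_patient, assignments, K, C, tol)
        margins = _margins(X_pat, faces)
        new_assign = margins.argmax(axis=1) + 1
        trace.append(_objective(X, is_patient, faces, new_assign, C))
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
    return assignments, faces, np.asarray(trace)


def hydra_fit(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    C: float = 0.25,
    n_iter: int = 50,
    n_consensus: int = 20,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-6,
) -> SubtypeSolution:
    """Fit the K-face polytope with consensus over seeded restarts.

    ``X`` holds one row per subject (patients and controls); ``y`` is 1 for
    patients and 0 for controls.  ``n_consensus`` independent alternating
    runs are combined into a patient co-assignment frequency matrix, which
    is clustered into K groups by average-linkage agglomeration on
    (1 - frequency); hyperplanes are refit once on those final assignments.
    The objective trace reported is that of the restart with the lowest
    final objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if y.min() == y.max():
        raise ConfigError("both patients (y=1) and controls (y=0) are required")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    is_patient = y.astype(bool)
    patient_index = np.flatnonzero(is_patient)
    n_pat = len(patient_index)

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_consensus)
    coassign = np.zeros((n_pat, n_pat))
    best_trace = None
    for rs in run_seeds:
        assign, _, trace = hydra_single_run(X, y, K, C=C, n_iter=n_iter, seed=int(rs), tol=tol)
        coassign += assign[:, None] == assign[None, :]
        if best_trace is None or trace[-1] < best_trace[-1]:
            best_trace = trace
    coassign /= n_consensus

    if K == 1 or n_pat == K:
        final = np.arange(1, n_pat + 1) if n_pat == K and K > 1 else np.ones(n_pat, int)
    else:
        agg = AgglomerativeClustering(n_clusters=K, metric="precomputed", linkage="average")
        labels = agg.fit_predict(1.0 - coassign)
        # relabel deterministically: cluster 1 = cluster of the lowest index
        final = np.empty(n_pat, dtype=int)
        next_id = 1
        mapping: dict[int, int] = {}
        for lab in labels:
            if lab not in mapping:
                mapping[lab] = next_id
                next_id += 1
        for i, lab in enumerate(labels):
            final[i] = mapping[lab]
    faces = _fit_faces(X, is_patient, final, K, C, tol)
    return SubtypeSolution(
        k=K,
        hyperplanes=faces,
        assignments=final,
        consensus_matrix=coassign,
        objective_trace=best_trace,
        patient_index=patient_index,
    )


# ---------------------------------------------------------------------------
# cross-validated model selection
# ---------------------------------------------------------------------------


def cv_ari(
    X: np.ndarray,
    y: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    folds: int = 10,
    C: float = 0.25,
    n_iter: int = 50,
    n_consensus: int = 20,
    seed: int = 0,
    standardize: bool = True,
) -> ModelSelection:
    """Clustering-stability model selection over the number of clusters.

    For each K, HYDRA is fit on each of the ``folds`` leave-one-fold-out
    training sets (folds stratified by diagnosis); stability is the mean
    pairwise ARI between fold solutions, computed on the patients common to
    both training sets.  ``chosen_k`` is the argmax (ties -> smaller K).
    """
    k_range = list(k_range)
    if not k_range:
        raise ConfigError("k_range must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ConfigError(f"need at least {folds} subjects per class")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    train_sets = [train for train, _ in skf.split(X, y)]
    rng = np.random.default_rng(seed)

    scores: dict[int, float] = {}
    for K in k_range:
        # full-length assignment vectors, 0 where the subject was held out
        assign_full = np.zeros((folds, n), dtype=int)
        for f, train in enumerate(train_sets):
            sol = hydra_fit(
                X[train],
                y[train],
                K,
                C=C,
                n_iter=n_iter,
                n_consensus=n_consensus,
                seed=int(rng.integers(0, 2**31 - 1)),
                standardize=standardize,
            )
            assign_full[f, train[sol.patient_index]] = sol.assignments
        pair_aris = []
        for f in range(folds):
            for g in range(f + 1, folds):
                common = (assign_full[f] > 0) & (assign_full[g] > 0)
                pair_aris.append(
                    adjusted_rand_index(assign_full[f, common], assign_full[g, common])
                )
        scores[K] = float(np.mean(pair_aris))

    best = max(sorted(scores), key=lambda k: scores[k])  # ties -> smaller K
    return ModelSelection(k_range=k_range, cv_ari=scores, chosen_k=int(best))
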