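"""Structural validation of collections: PCA and DAPC.

PCA summarizes total variance of the molecular (mean-imputed dosage) or
phenotypic (standardized BLUP) matrix. DAPC reduces the matrix to the
leading principal components covering a stated fraction of variance
(default 80%) and fits a linear discriminant with the collections as
a-priori groups; per-group reassignment accuracy measures how
distinguishable the collections are. A permutation test against shuffled
labels gives the null for that accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass
class OrdinationResult:
    scores: np.ndarray  # samples x components
    explained: np.ndarray  # variance fraction per component
    loadings: np.ndarray  # features x components
    sample_ids: list | None = None
    # DAPC-only fields
    retained_pcs: int | None = None
    discriminant_scores: np.ndarray | None = None
    groups: np.ndarray | None = None
    assigned: np.ndarray | None = None
    posterior: np.ndarray | None = None
    accuracy: float | None = None
    accuracy_by_group: dict | None = None


def pca(matrix, center: bool = True, scale: bool = False,
        sample_ids=None) -> OrdinationResult:
    """Principal components via SVD of the (centered, optionally scaled) data.

    Explained-variance fractions are eigenvalues over their total across
    all min(n-1, p) components, so they sum to 1. Zero-variance features
    are dropped when scaling. Eigenvector signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete (impute first)")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance features before scaling",
                stacklevel=2,
            )
        X = X[:, keep] / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    eig = s**2
    explained = eig / eig.sum() if eig.sum() > 0 else eig
    scores = u * s
    return OrdinationResult(
        scores=scores,
        explained=explained,
        loadings=vt.T,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def dapc(matrix, groups, variance_fraction: float = 0.80,
         sample_ids=None) -> OrdinationResult:
    """Discriminant analysis of principal components.

    Retains the minimal leading PCs whose cumulative explained variance
    reaches ``variance_fraction`` (capped below n_samples - n_groups as an
    overfitting guard), then fits a linear discriminant on the retained PC
    scores with the given a-priori groups. Reports discriminant scores,
    posterior group assignment and reassignment accuracy overall and per
    group. Discriminant axes number min(n_groups - 1, retained PCs).
    """
    groups = np.asarray(groups)
    X = np.asarray(matrix, dtype=float)
    if len(groups) != X.shape[0]:
        raise ValueError("group labels must match the number of samples")
    names, counts = np.unique(groups, return_counts=True)
    if len(names) < 2:
        raise ValueError("DAPC needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    base = pca(X, center=True, scale=False, sample_ids=sample_ids)
    cum = np.cumsum(base.explained)
    retained = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    retained = min(retained, base.scores.shape[1])
    cap = X.shape[0] - len(names) - 1
    if retained > cap:
        warnings.warn(
            f"retained PCs ({retained}) near sample count; capping at {cap} "
            "to avoid overfitting",
            stacklevel=2,
        )
        retained = max(cap, 1)
    pcs = base.scores[:, :retained]
    n_axes = min(len(names) - 1, retained)
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    lda.fit(pcs, groups)
    assigned = lda.predict(pcs)
    posterior = lda.predict_proba(pcs)
    acc = float((assigned == groups).mean())
    by_group = {
        str(g): float((assigned[groups == g] == g).mean()) for g in names
    }
    return OrdinationResult(
        scores=base.scores,
        explained=base.explained,
        loadings=base.loadings,
        sample_ids=base.sample_ids,
        retained_pcs=retained,
        discriminant_scores=lda.transform(pcs),
        groups=groups,
        assigned=assigned,
        posterior=posterior,
        accuracy=acc,
        accuracy_by_group=by_group,
    )


def permutation_null_accuracy(matrix, groups, variance_fraction: float = 0.80,
                              n_permutations: int = 199, seed: int = 0):
    """Label-permutation null for DAPC reassignment accuracy.

    Returns ``(observed, null_accuracies, p_value)`` with the standard
    add-one permutation p-value (1 + #null >= observed) / (1 + B).
    """
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    obs = dapc(matrix, groups, variance_fraction).accuracy
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = dapc(matrix, rng.permutation(groups), variance_fraction).accuracy
    p = (1 + int((null >= obs).sum())) / (1 + n_permutations)
    return obs, null, p
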