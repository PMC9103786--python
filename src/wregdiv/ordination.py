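"""Sample ordination: PCA of expression profiles and PERMANOVA group tests."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from wregdiv.expression_io import ExpressionMatrix

__all__ = ["PcaResult", "PermanovaResult", "run_pca", "permanova", "euclidean_distances"]


@dataclass(frozen=True)
class PcaResult:
    """Sample coordinates, variance-explained fractions and gene loadings."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x components
    variance_fractions: np.ndarray
    loadings: np.ndarray  # genes x components

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None


def run_pca(
    matrix: ExpressionMatrix,
    log_transform: bool = True,
    center: bool = True,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of samples in gene space via SVD on the (log2(TPM+1)) centered data.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so results are deterministic and invariant to gene
    order up to that fixed choice.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.values.T.astype(float)  # samples x genes
    if log_transform:
        x = np.log2(x + 1.0)
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0.0):
        raise ValueError("no variance in expression matrix")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape) if n_components is None else min(n_components, min(x.shape))
    u, s, vt = u[:, :k], s[:k], vt[:k, :]

    # fix signs: largest-|loading| entry positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    coords = u * s
    total_var = np.sum(x**2)
    var_frac = (s**2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        sample_ids=matrix.sample_ids,
        coordinates=coords,
        variance_fractions=var_frac,
        loadings=vt.T,
    )


def euclidean_distances(
    matrix: ExpressionMatrix, log_transform: bool = True
) -> np.ndarray:
    """Pairwise Euclidean sample distances on the (log-transformed) matrix."""
    x = matrix.values.T.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    return squareform(pdist(x, metric="euclidean"))


def _pseudo_f(dist_sq: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer-coded labels."""
    n = dist_sq.shape[0]
    ss_total = dist_sq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size < 1:
            continue
        block = dist_sq[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(idx.size, k=1)].sum() / idx.size
    k = groups.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    distances: np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    pairwise: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1). With
    ``pairwise=True`` every label pair is additionally tested on its
    sub-matrix and p-values are Benjamini-Hochberg adjusted.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if labels.shape[0] != d.shape[0]:
        raise ValueError(
            f"labels length {labels.shape[0]} does not match matrix size {d.shape[0]}"
        )
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every label needs at least 2 members")

    rng = np.random.default_rng(seed)
    d2 = d**2
    f_obs = _pseudo_f(d2, codes)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)

    pairwise_frame = None
    if pairwise:
        rows = []
        for a, b in combinations(range(uniq.size), 2):
            idx = np.flatnonzero((codes == a) | (codes == b))
            sub = permanova(
                d[np.ix_(idx, idx)],
                codes[idx],
                n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(
                {
                    "label_a": uniq[a],
                    "label_b": uniq[b],
                    "pseudo_F": sub.pseudo_f,
                    "p_value": sub.p_value,
                }
            )
        pairwise_frame = pd.DataFrame(rows)
        from wregdiv.diffexpr import estimate_qvalues

        pairwise_frame["p_adjusted"] = estimate_qvalues(
            pairwise_frame["p_value"].to_numpy(), method="bh"
        )

    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        pairwise=pairwise_frame,
    )
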