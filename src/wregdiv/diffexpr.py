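"""Two-population differential expression by exact tests on integerized counts.

The contrast scheme: fold change on mean TPM (with a small pseudo-value),
replicate TPM summed per population and scaled to integer pseudo-counts, a
two-sided exact binomial test against the population's share of the total
integerized library, a two-sided Fisher exact test on the gene-vs-library 2x2
table, q-value FDR on both test families, and a combined verdict requiring
the fold-change window plus FDR (both tests by default, either by config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from wregdiv.expression_io import ExpressionMatrix

__all__ = [
    "ContrastSpec",
    "fold_change",
    "integerize_counts",
    "binomial_divergence_test",
    "fisher_divergence_test",
    "estimate_qvalues",
    "call_contrast",
]

#: TPM sums to one million within each sample by construction.
NOMINAL_LIBRARY_TPM = 1_000_000

RESULT_COLUMNS = [
    "gene_id",
    "mean_A",
    "mean_B",
    "fold_change",
    "p_binom",
    "q_binom",
    "p_fisher",
    "q_fisher",
    "significant",
    "direction",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One two-population comparison: sample sets plus decision thresholds.

    ``combine`` selects whether significance requires FDR on *both* exact
    tests (default) or on *either* one.
    """

    name: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]
    fc_high: float = 1.25
    fc_low: float = 0.8
    fdr_alpha: float = 0.05
    pseudo_tpm: float = 0.01
    library_scale: float = 10.0
    qvalue_method: str = "storey"
    combine: str = "both"

    def __post_init__(self) -> None:
        if not self.samples_a:
            raise ValueError(f"contrast {self.name!r}: population A has zero samples")
        if not self.samples_b:
            raise ValueError(f"contrast {self.name!r}: population B has zero samples")
        overlap = set(self.samples_a) & set(self.samples_b)
        if overlap:
            raise ValueError(
                f"contrast {self.name!r}: populations overlap: {sorted(overlap)}"
            )
        if not (self.fc_low < 1.0 < self.fc_high):
            raise ValueError("thresholds must satisfy fc_low < 1 < fc_high")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.pseudo_tpm <= 0:
            raise ValueError("pseudo_tpm must be > 0")
        if self.library_scale <= 0:
            raise ValueError("library_scale must be > 0")
        if self.combine not in ("both", "either"):
            raise ValueError("combine must be 'both' or 'either'")
        if self.qvalue_method not in ("storey", "bh"):
            raise ValueError("qvalue_method must be 'storey' or 'bh'")


def fold_change(mean_a: float, mean_b: float, pseudo: float = 0.01) -> float:
    """Pseudo-stabilized ratio of mean expression: (mean_a + pseudo)/(mean_b + pseudo)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return (mean_a + pseudo) / (mean_b + pseudo)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; exact tests need a deterministic half-up.
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def integerize_counts(values: np.ndarray, library_scale: float = 10.0) -> np.ndarray:
    """Aggregate replicate TPM into per-gene integer pseudo-counts.

    ``values`` is genes x replicates for one population; replicates are summed,
    multiplied by ``library_scale`` and rounded half-up.
    """
    if library_scale <= 0:
        raise ValueError("library_scale must be > 0")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return _round_half_up(values.sum(axis=1) * library_scale)


def binomial_divergence_test(
    count_a: int, count_b: int, expected_a_fraction: float = 0.5
) -> float:
    """Two-sided exact binomial p for count_a of (count_a + count_b) trials.

    Two-sidedness follows the minlike convention (sum of outcome
    probabilities <= that of the observed outcome), matching Fisher's test.
    Both counts zero -> p = 1.
    """
    for name, c in (("count_a", count_a), ("count_b", count_b)):
        if c != int(c):
            raise ValueError(f"{name} must be an integer, got {c!r}")
        if c < 0:
            raise ValueError(f"{name} must be >= 0")
    if not (0.0 < expected_a_fraction < 1.0):
        raise ValueError("expected_a_fraction must lie in (0, 1)")
    n = int(count_a) + int(count_b)
    if n == 0:
        return 1.0
    return float(stats.binomtest(int(count_a), n, expected_a_fraction).pvalue)


def fisher_divergence_test(
    count_a: int, count_b: int, total_a: int, total_b: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 table gene-count vs rest-of-library."""
    if count_a > total_a or count_b > total_b:
        raise ValueError("gene count exceeds its library total")
    if min(count_a, count_b, total_a, total_b) < 0:
        raise ValueError("counts must be >= 0")
    table = [[int(count_a), int(total_a) - int(count_a)],
             [int(count_b), int(total_b) - int(count_b)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """FDR q-values from p-values by Benjamini-Hochberg or Storey's method.

    Storey estimates pi0 at lambda = 0.5 (clamped to (0, 1]) and scales the
    BH step-up values; with fewer than 20 p-values it falls back to plain BH,
    where the pi0 estimate is too unstable to help.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")
    q = _bh_qvalues(p)
    if method == "bh" or p.size < 20:
        return q
    lam = 0.5
    pi0 = np.mean(p > lam) / (1.0 - lam)
    pi0 = min(1.0, pi0)
    if pi0 <= 0.0:
        pi0 = 1.0 / p.size  # keep within (0, 1] when no p exceeds lambda
    return np.minimum(pi0 * q, 1.0)


def call_contrast(matrix: ExpressionMatrix, spec: ContrastSpec) -> pd.DataFrame:
    """Run the full per-gene contrast defined by ``spec`` over ``matrix``.

    Returns a DataFrame with one row per gene (matrix order) and the columns
    in :data:`RESULT_COLUMNS`. ``significant`` is True iff the fold change
    lies outside [fc_low, fc_high] and the q-values pass ``fdr_alpha`` under
    the configured test combination. ``direction`` is ``A_up``/``B_up`` for
    significant genes, else ``none``.
    """
    sub_a = matrix.select_samples(spec.samples_a)
    sub_b = matrix.select_samples(spec.samples_b)

    mean_a = sub_a.values.mean(axis=1)
    mean_b = sub_b.values.mean(axis=1)
    fc = (mean_a + spec.pseudo_tpm) / (mean_b + spec.pseudo_tpm)

    counts_a = integerize_counts(sub_a.values, spec.library_scale)
    counts_b = integerize_counts(sub_b.values, spec.library_scale)
    # TPM is normalized within sample (1e6 per library), so each population's
    # total integerized library is proportional to its replicate count; under
    # equal expression a gene's counts split by that share (0.5 when balanced).
    per_sample = int(round(NOMINAL_LIBRARY_TPM * spec.library_scale))
    total_a = sub_a.n_samples * per_sample
    total_b = sub_b.n_samples * per_sample
    frac_a = total_a / (total_a + total_b)

    p_binom = np.array(
        [binomial_divergence_test(a, b, frac_a) for a, b in zip(counts_a, counts_b)]
    )
    p_fisher = np.array(
        [
            fisher_divergence_test(a, b, total_a, total_b)
            for a, b in zip(counts_a, counts_b)
        ]
    )
    q_binom = estimate_qvalues(p_binom, spec.qvalue_method)
    q_fisher = estimate_qvalues(p_fisher, spec.qvalue_method)

    fc_pass = (fc > spec.fc_high) | (fc < spec.fc_low)
    if spec.combine == "both":
        fdr_pass = (q_binom < spec.fdr_alpha) & (q_fisher < spec.fdr_alpha)
    else:
        fdr_pass = (q_binom < spec.fdr_alpha) | (q_fisher < spec.fdr_alpha)
    significant = fc_pass & fdr_pass

    direction = np.where(
        significant, np.where(fc > 1.0, "A_up", "B_up"), "none"
    )

    return pd.DataFrame(
        {
            "gene_id": list(matrix.gene_ids),
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fc,
            "p_binom": p_binom,
            "q_binom": q_binom,
            "p_fisher": p_fisher,
            "q_fisher": q_fisher,
            "significant": significant,
            "direction": direction,
        }
    )


def write_contrast_table(result: pd.DataFrame, path) -> None:
    result[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
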