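"""Aggregate per-gene regulatory calls into summary statistics.

Covers category cross-tabulation per (tissue, group), cis/trans fractions,
dominant-pattern fractions with breed-skew tallies, the parental fold-change
spectrum, and cross-group category consistency. A reference table of
published per-tissue category counts for the Cornish x White Leghorn
reciprocal cross ships with the package for worked-example tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from wregdiv.expression_io import GROUP1, GROUP2
from wregdiv.regclass import CLASSIFIED_CATEGORIES, RegulatoryCategory

__all__ = [
    "CategorySummary",
    "FoldChangeSpectrum",
    "load_reference_counts",
    "counts_to_calls",
    "tabulate_categories",
    "cis_trans_fractions",
    "dominance_report",
    "fold_change_spectrum",
    "cross_group_consistency",
]

CATEGORY_COLUMNS = [c.value for c in CLASSIFIED_CATEGORIES]
EXCLUDED_COLUMNS = [
    RegulatoryCategory.NO_PARENTAL_DIVERGENCE.value,
    RegulatoryCategory.AMBIGUOUS.value,
]

_TRANS_COLUMNS = [
    RegulatoryCategory.TRANS_DOMINANT.value,
    RegulatoryCategory.TRANS_ADDITIVE.value,
    RegulatoryCategory.TRANS_OVERDOMINANT.value,
    RegulatoryCategory.TRANS_UNDERDOMINANT.value,
]
_DOMINANT_COLUMNS = [
    RegulatoryCategory.CIS_DOMINANT.value,
    RegulatoryCategory.TRANS_DOMINANT.value,
]


@dataclass(frozen=True)
class CategorySummary:
    """Category counts per (tissue, group), excluded genes tallied apart.

    ``counts`` is indexed by (tissue, group) with one column per classified
    category; ``excluded`` has the same index with columns for genes outside
    the six-category scheme (no parental divergence, ambiguous).
    """

    counts: pd.DataFrame
    excluded: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("category counts must be >= 0")

    @property
    def tissues(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tissue, _ in self.counts.index:
            seen.setdefault(tissue)
        return tuple(seen)

    def group_total(self, tissue: str, group: int) -> int:
        """Six-category sum for one (tissue, group) row."""
        return int(self.counts.loc[(tissue, group)].sum())

    def tissue_total(self, tissue: str) -> int:
        """Six-category sum over both groups of a tissue."""
        return int(self.counts.loc[tissue].to_numpy().sum())


@dataclass(frozen=True)
class FoldChangeSpectrum:
    """Signed log2 parental fold changes with a binned histogram."""

    log2_fold_changes: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    fraction_under_twofold: float | None  # None when no genes


def load_reference_counts() -> pd.DataFrame:
    """The packaged reference category-count table (tissue x group x category)."""
    path = resources.files("wregdiv").joinpath("data/reference_category_counts.tsv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t", comment="#")
    return frame


def counts_to_calls(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand a category-count table into one synthetic call row per gene.

    Inverse of :func:`tabulate_categories` up to gene identity; used to feed
    count-level fixtures through the call-level summary operations. Means are
    placeholders (dominant-call skew is still well-defined, via the group's
    maternal/paternal roles).
    """
    groups = {GROUP1.group_id: GROUP1, GROUP2.group_id: GROUP2}
    rows = []
    for _, rec in counts.iterrows():
        tissue, group_id = str(rec["tissue"]), int(rec["group"])
        group = groups[group_id]
        for cat in CATEGORY_COLUMNS:
            for k in range(int(rec[cat])):
                if cat == RegulatoryCategory.CIS_DOMINANT.value:
                    skew = group.maternal_population
                elif cat == RegulatoryCategory.TRANS_DOMINANT.value:
                    skew = group.paternal_population
                else:
                    skew = "none"
                rows.append(
                    {
                        "gene_id": f"{tissue}_g{group_id}_{cat}_{k}",
                        "group": group_id,
                        "tissue": tissue,
                        "category": cat,
                        "skew": skew,
                        "maternal_mean": np.nan,
                        "paternal_mean": np.nan,
                        "f1_mean": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _as_call_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    from wregdiv.regclass import calls_to_frame

    return calls_to_frame(list(calls))


def tabulate_categories(calls) -> CategorySummary:
    """Cross-tabulate calls into category counts per (tissue, group).

    Accepts a call DataFrame or a list of RegulatoryCall. Genes with no
    parental divergence or an ambiguous call are counted in ``excluded``,
    not in the six-category table.
    """
    frame = _as_call_frame(calls)
    all_cols = CATEGORY_COLUMNS + EXCLUDED_COLUMNS
    if len(frame) == 0:
        idx = pd.MultiIndex.from_tuples([], names=["tissue", "group"])
        empty = pd.DataFrame(columns=CATEGORY_COLUMNS, index=idx, dtype=int)
        empty_ex = pd.DataFrame(columns=EXCLUDED_COLUMNS, index=idx, dtype=int)
        return CategorySummary(empty, empty_ex)
    unknown = set(frame["category"]) - set(all_cols)
    if unknown:
        raise ValueError(f"unknown category value(s): {sorted(unknown)}")
    tab = (
        frame.groupby(["tissue", "group"])["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=all_cols, fill_value=0)
        .astype(int)
    )
    return CategorySummary(tab[CATEGORY_COLUMNS], tab[EXCLUDED_COLUMNS])


def _pct(numerator: float, denominator: float) -> float | None:
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def cis_trans_fractions(summary: CategorySummary) -> dict:
    """Cis percentages and trans ratios per group, per tissue, and pooled.

    Percentages are rounded to one decimal; ratios to two decimals (with a
    truncated-to-two-decimals rendering alongside, since published ratios
    are sometimes truncated rather than rounded). Zero denominators yield
    ``None`` rather than a number.
    """
    counts = summary.counts
    if len(counts) == 0:
        raise ValueError("empty summary")
    cis = RegulatoryCategory.CIS_DOMINANT.value

    per_group = {}
    for (tissue, group), row in counts.iterrows():
        total = int(row.sum())
        per_group[(tissue, int(group))] = {
            "cis_pct": _pct(row[cis], total),
            "trans_ratio": None
            if total == 0
            else round(row[_TRANS_COLUMNS].sum() / total, 2),
            "total": total,
        }

    per_tissue = {}
    for tissue in summary.tissues:
        block = counts.loc[tissue]
        total = int(block.to_numpy().sum())
        trans = int(block[_TRANS_COLUMNS].to_numpy().sum())
        cis_n = int(block[cis].sum())
        conserved_n = int(block[RegulatoryCategory.CONSERVED.value].sum())
        per_tissue[tissue] = {
            "cis_pct": _pct(cis_n, total),
            "trans_pct": _pct(trans, total),
            "conserved_pct": _pct(conserved_n, total),
            "trans_ratio": None if total == 0 else round(trans / total, 2),
            "trans_ratio_truncated": None
            if total == 0
            else math.floor(100.0 * trans / total) / 100.0,
            "total": total,
        }

    grand_total = int(counts.to_numpy().sum())
    grand_cis = int(counts[cis].sum())
    # pooled split is cis vs everything else (trans subtypes + conserved),
    # the complement framing used when quoting an overall cis share
    pooled = {
        "cis_pct": _pct(grand_cis, grand_total),
        "trans_pct": _pct(grand_total - grand_cis, grand_total),
        "total": grand_total,
    }
    return {"per_group": per_group, "per_tissue": per_tissue, "pooled": pooled}


def dominance_report(calls, summary: CategorySummary | None = None) -> dict:
    """Dominant-pattern counts, fractions and breed-skew tallies per tissue.

    Dominant = cis-dominant + trans-dominant over both groups; the fraction
    is taken over the tissue's six-category total. Skew tallies count the
    dominant genes biased toward each breed.
    """
    frame = _as_call_frame(calls)
    if summary is None:
        summary = tabulate_categories(frame)
    report = {}
    for tissue in summary.tissues:
        block = summary.counts.loc[tissue]
        dominant = int(block[_DOMINANT_COLUMNS].to_numpy().sum())
        total = int(block.to_numpy().sum())
        in_tissue = frame["tissue"] == tissue
        is_dominant = frame["category"].isin(_DOMINANT_COLUMNS)
        skews = frame.loc[in_tissue & is_dominant, "skew"]
        tally = skews[skews != "none"].value_counts().to_dict()
        report[tissue] = {
            "dominant_count": dominant,
            "dominant_pct": _pct(dominant, total),
            "skew_tally": {str(k): int(v) for k, v in tally.items()},
            "total": total,
        }
    return report


def fold_change_spectrum(
    contrast: pd.DataFrame,
    significant_only: bool = True,
    flip_sign: bool = False,
    bin_width: float = 0.25,
) -> FoldChangeSpectrum:
    """Signed log2 fold-change spectrum of a parental contrast.

    Sign convention: positive = population A up. Pass ``flip_sign=True``
    when the contrast was computed the other way round from the desired
    display orientation. Reports the fraction of genes with a less than
    two-fold difference (|log2 fc| < 1).
    """
    rows = contrast
    if significant_only:
        rows = rows[rows["significant"]]
    lfc = np.log2(rows["fold_change"].to_numpy(dtype=float))
    if flip_sign:
        lfc = -lfc
    if lfc.size == 0:
        return FoldChangeSpectrum(
            lfc, np.array([0.0]), np.array([], dtype=int), None
        )
    lo = math.floor(lfc.min() / bin_width) * bin_width
    hi = math.ceil(lfc.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(lfc, bins=edges)
    return FoldChangeSpectrum(
        log2_fold_changes=lfc,
        bin_edges=edges,
        bin_counts=hist,
        fraction_under_twofold=float(np.mean(np.abs(lfc) < 1.0)),
    )


def cross_group_consistency(calls) -> dict[str, float | None]:
    """Per-tissue fraction of genes with the same category in both groups.

    Only genes falling in one of the six classified categories in *both*
    groups enter the denominator. ``None`` when no gene qualifies.
    """
    frame = _as_call_frame(calls)
    result: dict[str, float | None] = {}
    for tissue in dict.fromkeys(frame["tissue"]):
        sub = frame[
            (frame["tissue"] == tissue) & frame["category"].isin(CATEGORY_COLUMNS)
        ]
        by_group = {
            g: dict(zip(block["gene_id"], block["category"]))
            for g, block in sub.groupby("group")
        }
        if len(by_group) < 2:
            result[str(tissue)] = None
            continue
        g1, g2 = (by_group[g] for g in sorted(by_group)[:2])
        shared = set(g1) & set(g2)
        if not shared:
            result[str(tissue)] = None
            continue
        agree = sum(1 for g in shared if g1[g] == g2[g])
        result[str(tissue)] = agree / len(shared)
    return result


def write_summary_table(summary: CategorySummary, path: str | Path) -> None:
    out = summary.counts.join(summary.excluded)
    out.to_csv(path, sep="\t")
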