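"""Regulatory-divergence category per W-linked gene from three contrasts.

For one cross group (maternal parent, paternal parent, F1 female) three
two-population contrasts feed a decision tree:

* parents not significantly different        -> NO_PARENTAL_DIVERGENCE
* parents differ, F1 == maternal, != paternal -> CIS_DOMINANT (maternal dominance)
* parents differ, F1 == both parents          -> CONSERVED
* parents differ, F1 != maternal, == paternal -> TRANS_DOMINANT (paternal dominance)
* parents differ, F1 != both parents          -> TRANS_ADDITIVE / TRANS_OVERDOMINANT /
  TRANS_UNDERDOMINANT by the F1 mean's position relative to the parental means;
  an exact tie with a parental mean -> AMBIGUOUS.

"==" / "!=" above mean not-significant / significant under the configured
fold-change window and FDR thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from wregdiv.diffexpr import ContrastSpec, call_contrast
from wregdiv.expression_io import CrossGroup, ExpressionMatrix, SampleSheet

__all__ = [
    "RegulatoryCategory",
    "RegulatoryCall",
    "classify_gene",
    "classify_group",
    "enumerate_decision_table",
    "CALL_COLUMNS",
]


class RegulatoryCategory(str, Enum):
    CIS_DOMINANT = "cis_dominant"
    TRANS_DOMINANT = "trans_dominant"
    TRANS_ADDITIVE = "trans_additive"
    TRANS_OVERDOMINANT = "trans_overdominant"
    TRANS_UNDERDOMINANT = "trans_underdominant"
    CONSERVED = "conserved"
    NO_PARENTAL_DIVERGENCE = "no_parental_divergence"
    AMBIGUOUS = "ambiguous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The six categories counted in summary tables (excluded/ambiguous reported apart).
CLASSIFIED_CATEGORIES = (
    RegulatoryCategory.CIS_DOMINANT,
    RegulatoryCategory.TRANS_DOMINANT,
    RegulatoryCategory.TRANS_ADDITIVE,
    RegulatoryCategory.TRANS_OVERDOMINANT,
    RegulatoryCategory.TRANS_UNDERDOMINANT,
    RegulatoryCategory.CONSERVED,
)

CALL_COLUMNS = [
    "gene_id",
    "group",
    "tissue",
    "category",
    "skew",
    "maternal_mean",
    "paternal_mean",
    "f1_mean",
]


@dataclass(frozen=True)
class RegulatoryCall:
    gene_id: str
    group_id: int
    category: RegulatoryCategory
    skew: str  # breed the F1 is biased toward: maternal/paternal population or "none"
    maternal_mean: float
    paternal_mean: float
    f1_mean: float
    tissue: str = ""


def _position(f1_mean: float, maternal_mean: float, paternal_mean: float) -> str:
    lo = min(maternal_mean, paternal_mean)
    hi = max(maternal_mean, paternal_mean)
    if f1_mean == lo or f1_mean == hi:
        return "tie"
    if f1_mean > hi:
        return "above"
    if f1_mean < lo:
        return "below"
    return "between"


def _categorize(
    parental_sig: bool, maternal_sig: bool, paternal_sig: bool, position: str
) -> RegulatoryCategory:
    """Pure decision tree on the significance triple and the F1 position."""
    if not parental_sig:
        return RegulatoryCategory.NO_PARENTAL_DIVERGENCE
    if not maternal_sig:
        if paternal_sig:
            return RegulatoryCategory.CIS_DOMINANT
        return RegulatoryCategory.CONSERVED
    if not paternal_sig:
        return RegulatoryCategory.TRANS_DOMINANT
    if position == "above":
        return RegulatoryCategory.TRANS_OVERDOMINANT
    if position == "below":
        return RegulatoryCategory.TRANS_UNDERDOMINANT
    if position == "between":
        return RegulatoryCategory.TRANS_ADDITIVE
    return RegulatoryCategory.AMBIGUOUS


def classify_gene(
    parental: pd.Series,
    f1_vs_maternal: pd.Series,
    f1_vs_paternal: pd.Series,
    group: CrossGroup,
    tissue: str = "",
) -> RegulatoryCall:
    """Classify one gene from its three contrast rows for one cross group.

    Rows are contrast-result rows (``gene_id``, ``mean_A``, ``mean_B``,
    ``significant``): ``parental`` compares maternal (A) vs paternal (B)
    breed females, the F1 rows compare F1 (A) vs the named parent (B).
    """
    gene = str(parental["gene_id"])
    if not (gene == str(f1_vs_maternal["gene_id"]) == str(f1_vs_paternal["gene_id"])):
        raise ValueError(
            "contrast rows refer to different genes: "
            f"{gene!r}, {f1_vs_maternal['gene_id']!r}, {f1_vs_paternal['gene_id']!r}"
        )
    maternal_mean = float(parental["mean_A"])
    paternal_mean = float(parental["mean_B"])
    f1_mean = float(f1_vs_maternal["mean_A"])

    category = _categorize(
        bool(parental["significant"]),
        bool(f1_vs_maternal["significant"]),
        bool(f1_vs_paternal["significant"]),
        _position(f1_mean, maternal_mean, paternal_mean),
    )

    if category is RegulatoryCategory.CIS_DOMINANT:
        skew = group.maternal_population
    elif category is RegulatoryCategory.TRANS_DOMINANT:
        skew = group.paternal_population
    else:
        skew = "none"

    return RegulatoryCall(
        gene_id=gene,
        group_id=group.group_id,
        category=category,
        skew=skew,
        maternal_mean=maternal_mean,
        paternal_mean=paternal_mean,
        f1_mean=f1_mean,
        tissue=tissue,
    )


def classify_group(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    group: CrossGroup,
    tissue: str,
    spec: ContrastSpec | None = None,
    **threshold_kwargs,
) -> list[RegulatoryCall]:
    """Run the three contrasts for one cross group and tissue; classify every gene.

    ``matrix`` should already be restricted to the genes under study (e.g.
    W-linked, expression-filtered). Only female samples of ``tissue`` are
    used. Threshold keyword arguments (fc_high, fc_low, fdr_alpha, ...) are
    forwarded to :class:`ContrastSpec`; alternatively pass a template
    ``spec`` whose sample sets are ignored.
    """
    pops = {
        "maternal": group.maternal_population,
        "paternal": group.paternal_population,
        "F1": group.f1_population,
    }
    samples = {}
    for role, pop in pops.items():
        ids = sheet.select(population=pop, sex="F", tissue=tissue)
        if not ids:
            raise ValueError(
                f"no female {tissue!r} samples for {role} population {pop!r}"
            )
        samples[role] = ids

    base = {} if spec is None else {
        k: getattr(spec, k)
        for k in (
            "fc_high",
            "fc_low",
            "fdr_alpha",
            "pseudo_tpm",
            "library_scale",
            "qvalue_method",
            "combine",
        )
    }
    base.update(threshold_kwargs)

    def contrast(name: str, a: tuple[str, ...], b: tuple[str, ...]) -> pd.DataFrame:
        return call_contrast(
            matrix, ContrastSpec(name=name, samples_a=a, samples_b=b, **base)
        )

    parental = contrast("parental", samples["maternal"], samples["paternal"])
    f1_mat = contrast("f1_vs_maternal", samples["F1"], samples["maternal"])
    f1_pat = contrast("f1_vs_paternal", samples["F1"], samples["paternal"])

    calls = []
    for i in range(len(parental)):
        calls.append(
            classify_gene(
                parental.iloc[i], f1_mat.iloc[i], f1_pat.iloc[i], group, tissue
            )
        )
    return calls


def enumerate_decision_table() -> pd.DataFrame:
    """Exhaustive (significance triple x F1 position) -> category table.

    Serves as an independent oracle for :func:`classify_gene`: all
    2 x 2 x 2 significance combinations crossed with the four F1 positions
    (below / between / above the parental means, or exactly tied with one).
    """
    rows = []
    for parental_sig in (False, True):
        for maternal_sig in (False, True):
            for paternal_sig in (False, True):
                for position in ("below", "between", "above", "tie"):
                    rows.append(
                        {
                            "parental_sig": parental_sig,
                            "f1_vs_maternal_sig": maternal_sig,
                            "f1_vs_paternal_sig": paternal_sig,
                            "f1_position": position,
                            "category": _categorize(
                                parental_sig, maternal_sig, paternal_sig, position
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[RegulatoryCall]) -> pd.DataFrame:
    """Flatten RegulatoryCalls to the TSV layout used by the CLI."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "group": [c.group_id for c in calls],
            "tissue": [c.tissue for c in calls],
            "category": [c.category.value for c in calls],
            "skew": [c.skew for c in calls],
            "maternal_mean": [c.maternal_mean for c in calls],
            "paternal_mean": [c.paternal_mean for c in calls],
            "f1_mean": [c.f1_mean for c in calls],
        },
        columns=CALL_COLUMNS,
    )
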