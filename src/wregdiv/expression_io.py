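"""I/O and filtering for expression matrices, sample sheets and gene annotations.

File conventions (all plain TSV, UTF-8):

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  non-negative numeric values (TPM), no missing cells;
* sample sheet — header ``sample_id population sex tissue replicate``;
* gene annotation — either BED (0-based half-open; the ``name`` column maps to
  the gene id) or a two-column TSV ``gene_id  chromosome``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "CrossGroup",
    "GeneAnnotation",
    "GROUP1",
    "GROUP2",
    "DEFAULT_POPULATIONS",
    "read_expression_table",
    "write_expression_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_annotation",
    "filter_low_expression",
    "subset_by_chromosome",
    "subset_samples",
]

#: Population labels accepted without extra declaration: the two parental
#: breeds (Cornish game = Cor, White Leghorn = WL) and the reciprocal F1s
#: (CL = Cor dam x WL sire, LC = WL dam x Cor sire).
DEFAULT_POPULATIONS = ("Cor", "WL", "CL", "LC")

VALID_SEXES = ("F", "M")


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative genes x samples expression matrix (TPM units).

    Invariants enforced at construction: unique gene and sample ids, finite
    non-negative values, shape consistent with the id lists.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} id(s): {', '.join(dups)}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            idx = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[idx[0]]!r}, "
                f"sample {self.sample_ids[idx[1]]!r}"
            )
        if np.any(values < 0):
            idx = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[idx[0]]!r}, "
                f"sample {self.sample_ids[idx[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by gene id with sample-id columns."""
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        )

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"gene id(s) not in matrix: {', '.join(missing)}")
        rows = [pos[g] for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[rows, :])

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"sample id(s) not in matrix: {', '.join(missing)}")
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols])


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: population, sex, tissue and replicate index."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "population", "sex", "tissue")

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {', '.join(missing)}")
        if len(frame) == 0:
            raise ValueError("no samples in sample sheet")
        if "replicate" not in frame.columns:
            frame["replicate"] = (
                frame.groupby(["population", "sex", "tissue"], sort=False).cumcount() + 1
            )
        dups = _find_duplicates(frame["sample_id"].astype(str))
        if dups:
            raise ValueError(f"duplicate sample id(s): {', '.join(dups)}")
        bad_sex = sorted(set(frame["sex"]) - set(VALID_SEXES))
        if bad_sex:
            raise ValueError(f"unknown sex label(s) {bad_sex}; allowed: {list(VALID_SEXES)}")
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["sample_id"].astype(str))

    @property
    def tissues(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.frame["tissue"]:
            seen.setdefault(str(t))
        return tuple(seen)

    def select(
        self,
        population: str | None = None,
        sex: str | None = None,
        tissue: str | None = None,
    ) -> tuple[str, ...]:
        """Sample ids matching every given criterion, sheet order preserved."""
        mask = pd.Series(True, index=self.frame.index)
        if population is not None:
            mask &= self.frame["population"] == population
        if sex is not None:
            mask &= self.frame["sex"] == sex
        if tissue is not None:
            mask &= self.frame["tissue"] == tissue
        return tuple(self.frame.loc[mask, "sample_id"].astype(str))

    def females_only(self) -> "SampleSheet":
        """Drop male samples; the W analysis is female-only."""
        kept = self.frame[self.frame["sex"] == "F"]
        if len(kept) == 0:
            raise ValueError("no female samples in sample sheet")
        return SampleSheet(kept)


@dataclass(frozen=True)
class CrossGroup:
    """One reciprocal-cross analysis group: maternal parent, paternal parent, F1."""

    group_id: int
    maternal_population: str
    paternal_population: str
    f1_population: str


GROUP1 = CrossGroup(1, "Cor", "WL", "CL")
GROUP2 = CrossGroup(2, "WL", "Cor", "LC")


@dataclass(frozen=True)
class GeneAnnotation:
    """gene_id -> chromosome mapping with optional coordinates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        for col in ("gene_id", "chromosome"):
            if col not in frame.columns:
                raise ValueError(f"gene annotation missing column {col!r}")
        dups = _find_duplicates(frame["gene_id"].astype(str))
        if dups:
            raise ValueError(f"duplicate gene id(s) in annotation: {', '.join(dups)}")
        if (frame["chromosome"].astype(str).str.len() == 0).any():
            raise ValueError("empty chromosome label in annotation")
        object.__setattr__(self, "frame", frame)

    def chromosome_of(self) -> dict[str, str]:
        return dict(
            zip(self.frame["gene_id"].astype(str), self.frame["chromosome"].astype(str))
        )

    def genes_on(self, chromosome: str) -> tuple[str, ...]:
        mask = self.frame["chromosome"].astype(str) == chromosome
        return tuple(self.frame.loc[mask, "gene_id"].astype(str))


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene ids, header sample ids)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup_samples = _find_duplicates(header[1:])  # pandas would mangle these
    if dup_samples:
        raise ValueError(f"{path}: duplicate sample id(s): {', '.join(dup_samples)}")
    frame = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected gene-id column plus at least one sample")
    gene_col = frame.columns[0]
    frame = frame.set_index(gene_col)
    frame.index.name = "gene_id"
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            gene = frame.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric or missing value at gene {gene!r}, sample {col!r}"
            )
        frame[col] = coerced
    return ExpressionMatrix.from_frame(frame)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.6g"
) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=float_format)


def read_sample_sheet(
    path: str | Path, allowed_populations: Sequence[str] = DEFAULT_POPULATIONS
) -> SampleSheet:
    """Read and validate a TSV sample sheet.

    Population labels outside ``allowed_populations`` are rejected; pass an
    extended sequence to declare extra labels.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if len(frame) == 0:
        raise ValueError(f"{path}: no samples")
    sheet = SampleSheet(frame)
    unknown = sorted(set(sheet.frame["population"]) - set(allowed_populations))
    if unknown:
        raise ValueError(
            f"{path}: unknown population label(s) {unknown}; "
            f"allowed: {list(allowed_populations)}"
        )
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    cols = ["sample_id", "population", "sex", "tissue", "replicate"]
    sheet.frame[cols].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation from BED or a two-column ``gene_id<TAB>chromosome`` TSV.

    BED is detected by a numeric second column (start coordinate); names in
    BED column 4 become gene ids.
    """
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if rows.shape[1] >= 4 and rows[1].str.fullmatch(r"\d+").all():
        frame = pd.DataFrame(
            {
                "gene_id": rows[3],
                "chromosome": rows[0],
                "start": rows[1].astype(int),
                "end": rows[2].astype(int),
            }
        )
    elif rows.shape[1] >= 2:
        first = str(rows.iloc[0, 0]).lower()
        if first == "gene_id":  # tolerate a header line
            rows = rows.iloc[1:].reset_index(drop=True)
        frame = pd.DataFrame({"gene_id": rows[0], "chromosome": rows[1]})
    else:
        raise ValueError(f"{path}: expected BED or two-column gene_id/chromosome TSV")
    return GeneAnnotation(frame)


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float = 0.5
) -> ExpressionMatrix:
    """Drop genes whose expression is below ``threshold`` in every sample.

    A gene is kept iff max over samples >= threshold; the sample set is
    unchanged. Idempotent by construction.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = matrix.values.max(axis=1) >= threshold
    kept_ids = tuple(g for g, k in zip(matrix.gene_ids, keep) if k)
    return ExpressionMatrix(kept_ids, matrix.sample_ids, matrix.values[keep, :])


def subset_by_chromosome(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    chromosome: str,
    missing: str = "error",
) -> ExpressionMatrix:
    """Keep genes annotated to ``chromosome``, preserving matrix order.

    ``missing`` controls genes absent from the annotation: ``"error"`` raises,
    ``"drop"`` silently excludes them.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    chrom_of = annotation.chromosome_of()
    absent = [g for g in matrix.gene_ids if g not in chrom_of]
    if absent and missing == "error":
        raise KeyError(f"gene(s) missing from annotation: {', '.join(absent)}")
    kept = tuple(g for g in matrix.gene_ids if chrom_of.get(g) == chromosome)
    return matrix.select_genes(kept)


def subset_samples(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    population: str | None = None,
    sex: str | None = None,
    tissue: str | None = None,
) -> ExpressionMatrix:
    """Matrix restricted to the sheet samples matching the given criteria."""
    ids = sheet.select(population=population, sex=sex, tissue=tissue)
    return matrix.select_samples(ids)
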