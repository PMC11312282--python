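"""Reading, writing and assembling differential-expression lookup matrices.

Each input dataset is a per-gene differential gene expression (DGE) summary:
a log2 fold change (LFC; positive = higher in the experimental condition)
and a multiple-comparison-corrected p-value.  Datasets belonging to one
cohort (one contrast: disease vs control, ketogenic intervention vs standard
diet, drug vs vehicle) are stacked into a gene x dataset *lookup matrix*.

p-values are assumed to be already corrected upstream (the usual output of
GEO2R/edgeR-style pipelines); no further correction is applied here.  A gene
absent from a dataset is "no evidence" — distinct from measured-but-not-
significant — and is represented by an absent cell, never by a zero.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COHORTS = ("SCZ", "BPD", "MDD", "KI", "AP", "MS")
TISSUES = ("brain", "liver", "other")
PLATFORMS = ("rnaseq", "microarray")

CELL_COLUMNS = ("gene", "dataset_id", "lfc", "adj_p")


class DgeFormatError(ValueError):
    """Raised for malformed DGE tables or lookup-matrix files."""


class DgeRecord(NamedTuple):
    """One gene's summary in one dataset."""

    gene: str
    lfc: float
    adj_p: float


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    cohort: str
    tissue: str = "brain"
    species: str = "human"
    platform: str = "rnaseq"

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be nonempty")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )


@dataclass
class LookupMatrix:
    """Gene x dataset table of (LFC, adjusted p) pairs for one cohort.

    ``cells`` is a tidy frame with columns gene, dataset_id, lfc, adj_p; a
    missing (gene, dataset) pair simply has no row.
    """

    cohort: str
    datasets: tuple[DatasetMeta, ...]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.cells.columns) != list(CELL_COLUMNS):
            self.cells = self.cells.reindex(columns=list(CELL_COLUMNS))
        known = {m.dataset_id for m in self.datasets}
        present = set(self.cells["dataset_id"].unique())
        stray = present - known
        if stray:
            raise DgeFormatError(
                f"cells reference unknown dataset ids: {sorted(stray)}"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.cells["gene"].unique())

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def tissue_of(self, dataset_id: str) -> str:
        for m in self.datasets:
            if m.dataset_id == dataset_id:
                return m.tissue
        raise KeyError(dataset_id)


def read_dge_table(path: Union[str, Path], meta: DatasetMeta | None = None) -> list[DgeRecord]:
    """Read one per-dataset DGE summary TSV (columns gene, lfc, adj_p).

    Extra columns are ignored.  Duplicate gene rows keep the row with the
    smallest adjusted p-value (a warning is logged).  Rows with a
    non-numeric lfc/adj_p, a non-finite lfc, or adj_p outside [0, 1] raise
    :class:`DgeFormatError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "lfc", "adj_p") if c not in df.columns]
    if missing:
        raise DgeFormatError(f"{path}: missing required column(s) {missing}")

    lfc = pd.to_numeric(df["lfc"], errors="coerce")
    adj_p = pd.to_numeric(df["adj_p"], errors="coerce")
    # data rows are 1-based after the header line
    bad = df.index[lfc.isna() | adj_p.isna()].tolist()
    if bad:
        raise DgeFormatError(
            f"{path}: non-numeric lfc/adj_p in data row(s) {[i + 1 for i in bad]}"
        )
    nonfinite = df.index[~np.isfinite(lfc)].tolist()
    if nonfinite:
        raise DgeFormatError(
            f"{path}: non-finite lfc in data row(s) {[i + 1 for i in nonfinite]}"
        )
    out_of_range = df.index[(adj_p < 0) | (adj_p > 1)].tolist()
    if out_of_range:
        raise DgeFormatError(
            f"{path}: adj_p outside [0, 1] in data row(s) "
            f"{[i + 1 for i in out_of_range]}"
        )

    parsed = pd.DataFrame({"gene": df["gene"].astype(str), "lfc": lfc, "adj_p": adj_p})
    dupes = parsed["gene"][parsed["gene"].duplicated()].unique()
    if len(dupes):
        logger.warning(
            "%s: duplicate rows for gene(s) %s; keeping smallest adj_p",
            path,
            ", ".join(sorted(dupes)),
        )
        parsed = parsed.sort_values("adj_p", kind="stable").drop_duplicates(
            "gene", keep="first"
        )
        parsed = parsed.sort_index()
    return [DgeRecord(r.gene, float(r.lfc), float(r.adj_p)) for r in parsed.itertuples()]


def read_metadata(path: Union[str, Path]) -> list[DatasetMeta]:
    """Read a cohort metadata TSV (dataset_id, cohort, tissue, species, platform)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["dataset_id", "cohort", "tissue", "species", "platform"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DgeFormatError(f"{path}: missing required column(s) {missing}")
    return [
        DatasetMeta(
            dataset_id=row.dataset_id,
            cohort=row.cohort,
            tissue=row.tissue,
            species=row.species,
            platform=row.platform,
        )
        for row in df.itertuples()
    ]


def assemble_matrix(
    tables: Sequence[tuple[DatasetMeta, Sequence[DgeRecord]]],
    cohort: str,
) -> LookupMatrix:
    """Stack per-dataset record lists into one cohort lookup matrix.

    Matrix genes are the union over datasets; (gene, dataset) pairs absent
    from a table stay missing.  Content is order-insensitive: permuting the
    input tables yields the same cell mapping.
    """
    if not tables:
        logger.warning("assemble_matrix: no input tables for cohort %s", cohort)
        return LookupMatrix(
            cohort=cohort,
            datasets=(),
            cells=pd.DataFrame(columns=list(CELL_COLUMNS)),
        )
    seen_ids: set[str] = set()
    for meta, _ in tables:
        if meta.cohort != cohort:
            raise DgeFormatError(
                f"dataset {meta.dataset_id} has cohort {meta.cohort!r}, "
                f"expected {cohort!r}"
            )
        if meta.dataset_id in seen_ids:
            raise DgeFormatError(f"duplicate dataset_id {meta.dataset_id!r}")
        seen_ids.add(meta.dataset_id)

    frames = []
    for meta, records in tables:
        if not len(records):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "gene": [r.gene for r in records],
                    "dataset_id": meta.dataset_id,
                    "lfc": [r.lfc for r in records],
                    "adj_p": [r.adj_p for r in records],
                }
            )
        )
    cells = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CELL_COLUMNS))
    )
    cells = cells.sort_values(["gene", "dataset_id"], kind="stable").reset_index(drop=True)
    return LookupMatrix(
        cohort=cohort, datasets=tuple(m for m, _ in tables), cells=cells
    )


def write_matrix(matrix: LookupMatrix, path: Union[str, Path]) -> None:
    """Write a lookup matrix as a wide TSV that round-trips via read_matrix.

    Layout: ``#`` header lines carrying the cohort and per-dataset metadata,
    then one row per gene with ``<id>_lfc`` / ``<id>_p`` column pairs; an
    empty field marks a missing cell.
    """
    path = Path(path)
    ids = [m.dataset_id for m in matrix.datasets]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# cohort={matrix.cohort}\n")
        for m in matrix.datasets:
            fh.write(
                f"# dataset\t{m.dataset_id}\t{m.cohort}\t{m.tissue}"
                f"\t{m.species}\t{m.platform}\n"
            )
        header = ["gene"]
        for i in ids:
            header += [f"{i}_lfc", f"{i}_p"]
        fh.write("\t".join(header) + "\n")
        if matrix.n_cells == 0:
            return
        wide_lfc = matrix.cells.pivot(index="gene", columns="dataset_id", values="lfc")
        wide_p = matrix.cells.pivot(index="gene", columns="dataset_id", values="adj_p")
        for gene in wide_lfc.index:
            row = [gene]
            for i in ids:
                lfc = wide_lfc.at[gene, i] if i in wide_lfc.columns else math.nan
                p = wide_p.at[gene, i] if i in wide_p.columns else math.nan
                row.append("" if pd.isna(lfc) else repr(float(lfc)))
                row.append("" if pd.isna(p) else repr(float(p)))
            fh.write("\t".join(row) + "\n")


def read_matrix(path: Union[str, Path]) -> LookupMatrix:
    """Read a wide lookup-matrix TSV written by :func:`write_matrix`."""
    path = Path(path)
    cohort: str | None = None
    metas: list[DatasetMeta] = []
    data_lines: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("# cohort="):
            cohort = line.split("=", 1)[1].strip()
        elif line.startswith("# dataset\t"):
            _, ds_id, ds_cohort, tissue, species, platform = line.split("\t")
            metas.append(
                DatasetMeta(
                    dataset_id=ds_id,
                    cohort=ds_cohort,
                    tissue=tissue,
                    species=species,
                    platform=platform,
                )
            )
        elif line.strip():
            data_lines.append(line)
    if cohort is None:
        raise DgeFormatError(f"{path}: missing '# cohort=' header line")
    if not data_lines:
        raise DgeFormatError(f"{path}: missing column header line")

    header = data_lines[0].split("\t")
    if header[0] != "gene":
        raise DgeFormatError(f"{path}: first column must be 'gene', got {header[0]!r}")
    ids = [m.dataset_id for m in metas]
    expected = ["gene"]
    for i in ids:
        expected += [f"{i}_lfc", f"{i}_p"]
    if header != expected:
        raise DgeFormatError(f"{path}: column header does not match dataset metadata")

    rows = []
    for line in data_lines[1:]:
        fields = line.split("\t")
        gene = fields[0]
        for k, ds_id in enumerate(ids):
            lfc_s = fields[1 + 2 * k] if len(fields) > 1 + 2 * k else ""
            p_s = fields[2 + 2 * k] if len(fields) > 2 + 2 * k else ""
            if lfc_s == "" and p_s == "":
                continue
            rows.append(
                {
                    "gene": gene,
                    "dataset_id": ds_id,
                    "lfc": float(lfc_s),
                    "adj_p": float(p_s),
                }
            )
    cells = (
        pd.DataFrame(rows, columns=list(CELL_COLUMNS))
        .sort_values(["gene", "dataset_id"], kind="stable")
        .reset_index(drop=True)
    )
    return LookupMatrix(cohort=cohort, datasets=tuple(metas), cells=cells)
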