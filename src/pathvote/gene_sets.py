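"""Curated metabolic pathway gene sets.

The package ships twelve gene sets covering the major pathways of mammalian
macromolecule metabolism (glycolysis, the TCA cycle, the electron transport
chain, fatty acid synthesis/oxidation, ketogenesis, glycogen turnover, the
urea cycle, the lactate shuttle, gluconeogenesis and the pentose
phosphate/glutathione pathways).  Each set is an ordered list of human-style
gene symbols with the gene(s) encoding the pathway's rate-limiting enzyme
flagged, plus the declared set size used for whole-query totals.

Declared sizes are authoritative for totals even where a printed list
disagrees with its own token count; such discrepancies are surfaced as
validation notes on the loaded collection, never silently edited.  Gene
symbols are uppercase exact strings: no alias or ortholog mapping is
performed here (cross-species symbol resolution is an upstream concern).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)

_SYMBOL_RE = re.compile(r"^[A-Z0-9][A-Z0-9.-]*$")

#: Canonical names of the twelve packaged pathways.
PATHWAY_NAMES = (
    "Gluconeogenesis",
    "Glycolysis",
    "Lactate Shuttle (Neuron-Astrocyte)",
    "Tricarboxylic Acid (TCA) Cycle",
    "Electron Transport Chain (ETC)",
    "Fatty Acid Synthesis",
    "Fatty Acid Oxidation",
    "Ketogenesis",
    "Glycogenesis",
    "Glycogenolysis",
    "Urea Cycle",
    "Pentose Phosphate/Glutathione Pathways",
)


class GeneSetError(ValueError):
    """Raised for malformed or inconsistent gene-set files."""


def _check_symbol(symbol: str, context: str) -> None:
    if not symbol or not _SYMBOL_RE.match(symbol):
        raise GeneSetError(
            f"invalid gene symbol {symbol!r} in {context}: symbols must be "
            "nonempty, uppercase and whitespace-free"
        )


@dataclass(frozen=True)
class PathwayGeneSet:
    """One pathway's gene set.

    ``genes`` is the deduplicated, order-preserving gene list;
    ``raw_token_count`` counts the tokens as listed (before within-pathway
    deduplication) and is what ``declared_size`` is validated against.
    """

    pathway_name: str
    genes: tuple[str, ...]
    rate_limiting_genes: frozenset[str] = frozenset()
    declared_size: int = -1
    raw_token_count: int = -1

    def __post_init__(self) -> None:
        if not self.pathway_name:
            raise GeneSetError("pathway_name must be nonempty")
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise GeneSetError(
                f"pathway {self.pathway_name!r}: 'genes' must be deduplicated "
                "(use load_gene_sets for raw token lists)"
            )
        for g in genes:
            _check_symbol(g, f"pathway {self.pathway_name!r}")
        extra = frozenset(self.rate_limiting_genes) - set(genes)
        if extra:
            raise GeneSetError(
                f"pathway {self.pathway_name!r}: rate-limiting genes "
                f"{sorted(extra)} are not in the gene list"
            )
        if self.raw_token_count < 0:
            object.__setattr__(self, "raw_token_count", len(genes))
        if self.declared_size < 0:
            object.__setattr__(self, "declared_size", self.raw_token_count)

    @property
    def size_note(self) -> str | None:
        """Validation note when declared size and token count disagree."""
        if self.declared_size != self.raw_token_count:
            return (
                f"{self.pathway_name}: declared size {self.declared_size} != "
                f"{self.raw_token_count} listed tokens"
            )
        return None

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of pathway gene sets with validation notes."""

    sets: tuple[PathwayGeneSet, ...]
    validation_notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [s.pathway_name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GeneSetError(f"duplicate pathway names: {sorted(dupes)}")

    @property
    def pathway_names(self) -> tuple[str, ...]:
        return tuple(s.pathway_name for s in self.sets)

    @property
    def total_declared(self) -> int:
        return sum(s.declared_size for s in self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pathway_name: str) -> PathwayGeneSet:
        for s in self.sets:
            if s.pathway_name == pathway_name:
                return s
        raise KeyError(pathway_name)

    def gene_union(self) -> tuple[str, ...]:
        """Deduplicated union of all genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sets:
            for g in s.genes:
                seen.setdefault(g)
        return tuple(seen)


def _parse_tokens(raw: str, pathway: str, line_no: int) -> tuple[list[str], set[str]]:
    genes: list[str] = []
    rate_limiting: set[str] = set()
    for token in raw.split(","):
        token = token.strip()
        if not token:
            raise GeneSetError(f"line {line_no}: empty gene token in {pathway!r}")
        flagged = token.startswith("*")
        symbol = token.lstrip("*")
        _check_symbol(symbol, f"line {line_no} ({pathway!r})")
        genes.append(symbol)
        if flagged:
            rate_limiting.add(symbol)
    return genes, rate_limiting


def load_gene_sets(path: Union[str, Path]) -> GeneSetCollection:
    """Load a structured gene-set file.

    The file is a TSV with columns ``pathway``, ``declared_size`` and
    ``genes`` (comma-separated symbols; a leading ``*`` flags a gene encoding
    the rate-limiting enzyme).  Duplicate tokens within one pathway are
    deduplicated in the gene list but retained in the token count used to
    validate ``declared_size``; each duplicate logs a warning.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise GeneSetError(f"{path}: empty gene-set file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["pathway", "declared_size", "genes"]
    if header != expected:
        raise GeneSetError(f"{path} line 1: expected header {expected}, got {header}")

    sets: list[PathwayGeneSet] = []
    notes: list[str] = []
    seen_names: set[str] = set()
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise GeneSetError(
                f"{path} line {line_no}: expected 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, size_str, gene_field = (f.strip() for f in fields)
        try:
            declared = int(size_str)
        except ValueError as exc:
            raise GeneSetError(
                f"{path} line {line_no}: declared_size {size_str!r} is not an integer"
            ) from exc
        if declared < 0:
            raise GeneSetError(f"{path} line {line_no}: declared_size must be >= 0")
        if name in seen_names:
            raise GeneSetError(f"{path} line {line_no}: duplicate pathway name {name!r}")
        seen_names.add(name)

        tokens, rate_limiting = _parse_tokens(gene_field, name, line_no)
        deduped: list[str] = []
        for g in tokens:
            if g in deduped:
                msg = f"{name}: gene {g} listed more than once (kept one copy)"
                logger.warning(msg)
                notes.append(msg)
            else:
                deduped.append(g)
        gene_set = PathwayGeneSet(
            pathway_name=name,
            genes=tuple(deduped),
            rate_limiting_genes=frozenset(rate_limiting),
            declared_size=declared,
            raw_token_count=len(tokens),
        )
        if gene_set.size_note:
            logger.warning(gene_set.size_note)
            notes.append(gene_set.size_note)
        sets.append(gene_set)

    return GeneSetCollection(sets=tuple(sets), validation_notes=tuple(notes))


def default_gene_sets() -> GeneSetCollection:
    """Load the twelve packaged metabolic pathway gene sets (242 entries)."""
    with resources.as_file(
        resources.files("pathvote").joinpath("data/gene_sets.tsv")
    ) as p:
        return load_gene_sets(p)


def write_gene_sets(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    """Serialize a collection back to the structured gene-set format.

    Note: within-pathway duplicate tokens are not recoverable from a loaded
    collection's gene list, so a round trip preserves the deduplicated lists
    and the declared sizes (the validated content), not raw duplicates.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pathway\tdeclared_size\tgenes\n")
        for s in collection:
            tokens = [
                ("*" + g) if g in s.rate_limiting_genes else g for g in s.genes
            ]
            fh.write(f"{s.pathway_name}\t{s.declared_size}\t{', '.join(tokens)}\n")


def export_membership_tsv(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    """Write a long-format TSV with columns pathway, gene, is_rate_limiting."""
    rows = [
        {
            "pathway": s.pathway_name,
            "gene": g,
            "is_rate_limiting": g in s.rate_limiting_genes,
        }
        for s in collection
        for g in s.genes
    ]
    pd.DataFrame(rows, columns=["pathway", "gene", "is_rate_limiting"]).to_csv(
        path, sep="\t", index=False
    )


def total_query_count(collection: GeneSetCollection) -> int:
    """Total gene-pathway entries queried (sum of declared sizes, not a union)."""
    return collection.total_declared


def cross_pathway_membership(collection: GeneSetCollection) -> pd.DataFrame:
    """Map every gene to the pathways containing it.

    Returns a DataFrame with one row per distinct gene (first-appearance
    order) and columns ``gene``, ``pathways`` (tuple of pathway names) and
    ``n_pathways``.  Genes such as HK1 or SDHA appear in several pathways.
    """
    membership: dict[str, list[str]] = {}
    for s in collection:
        for g in s.genes:
            membership.setdefault(g, []).append(s.pathway_name)
    return pd.DataFrame(
        {
            "gene": list(membership),
            "pathways": [tuple(v) for v in membership.values()],
            "n_pathways": [len(v) for v in membership.values()],
        }
    )
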