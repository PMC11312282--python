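"""Per-pathway and per-cohort summaries: hit lists, mean LFCs, counts, percents.

Pathway-level "average LFC" is a two-stage mean: gene-level consensus means
(over the significant datasets in each gene's winning direction) are
averaged, unweighted, over the genes of each direction group.  Integer
percentages use round-half-up.  Fold-change phrasing converts an LFC to a
2^|LFC| magnitude rounded to one decimal with a higher/lower qualifier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

from .consensus import ConsensusResult, GeneVote
from .gene_sets import GeneSetCollection, PathwayGeneSet
from .profiles import CohortProfile, DirectionalProfile

logger = logging.getLogger(__name__)


def integer_percent(numerator: int, denominator: int) -> int:
    """Round-half-up integer percent of numerator/denominator.

    A zero denominator is defined as 0 with a warning.
    """
    if denominator == 0:
        logger.warning("integer_percent: zero denominator; returning 0")
        return 0
    return int((Fraction(100 * numerator, denominator) + Fraction(1, 2)).__floor__())


def fold_change_phrase(lfc: float) -> tuple[float, str]:
    """Express an LFC as a (fold-change magnitude, qualifier) pair.

    The magnitude is 2^|lfc| rounded half-up to one decimal; the qualifier
    is "higher" for positive LFC, "lower" for negative, "unchanged" for 0.
    """
    magnitude = float(
        Decimal(repr(2.0 ** abs(lfc))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
    if lfc > 0:
        return magnitude, "higher"
    if lfc < 0:
        return magnitude, "lower"
    return 1.0, "unchanged"


@dataclass(frozen=True)
class PathwaySummary:
    """One pathway's consensus summary for one cohort (one table column)."""

    pathway_name: str
    cohort: str
    up_genes: tuple[tuple[str, float | None], ...]
    down_genes: tuple[tuple[str, float | None], ...]
    mean_lfc_up: float | None
    mean_lfc_down: float | None
    n_hits: int
    pct_perturbed: int
    pct_up: int
    pct_down: int
    min_lfc: float | None = None
    max_lfc: float | None = None

    def __post_init__(self) -> None:
        if self.up_genes and self.mean_lfc_up is not None and self.mean_lfc_up <= 0:
            raise ValueError(f"{self.pathway_name}: mean_lfc_up must be positive")
        if self.down_genes and self.mean_lfc_down is not None and self.mean_lfc_down >= 0:
            raise ValueError(f"{self.pathway_name}: mean_lfc_down must be negative")


@dataclass(frozen=True)
class CohortSummary:
    cohort: str
    pathway_summaries: tuple[PathwaySummary, ...]
    total_hits: int
    pct_of_queried: int


def _mean(values: Sequence[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None


def summarize_pathway(
    pathway: PathwayGeneSet,
    advanced: Sequence[GeneVote],
    cohort: str = "",
) -> PathwaySummary:
    """Summarize the advanced consensus votes attributed to one pathway."""
    for v in advanced:
        if v.gene not in pathway:
            raise ValueError(
                f"gene {v.gene} is not a member of pathway {pathway.pathway_name!r}"
            )
        if not v.advanced:
            raise ValueError(f"gene {v.gene} has no consensus direction")
    up = tuple(
        (v.gene, float(v.consensus_mean_lfc)) for v in advanced if v.direction == "up"
    )
    down = tuple(
        (v.gene, float(v.consensus_mean_lfc)) for v in advanced if v.direction == "down"
    )
    return _build_summary(
        pathway, cohort, up, down,
        mean_up=_mean([x for _, x in up]),
        mean_down=_mean([x for _, x in down]),
    )


def summarize_profile(
    pathway: PathwayGeneSet,
    profile: DirectionalProfile,
    cohort: str = "",
) -> PathwaySummary:
    """Summarize a restored profile (group means known, per-gene LFCs maybe not)."""
    for g in profile.up + profile.down:
        if g not in pathway:
            raise ValueError(
                f"gene {g} is not a member of pathway {pathway.pathway_name!r}"
            )
    lfcs = profile.gene_lfcs or {}
    up = tuple((g, lfcs.get(g)) for g in profile.up)
    down = tuple((g, lfcs.get(g)) for g in profile.down)
    return _build_summary(
        pathway, cohort, up, down,
        mean_up=profile.mean_lfc_up,
        mean_down=profile.mean_lfc_down,
    )


def _build_summary(
    pathway: PathwayGeneSet,
    cohort: str,
    up: tuple[tuple[str, float | None], ...],
    down: tuple[tuple[str, float | None], ...],
    mean_up: float | None,
    mean_down: float | None,
) -> PathwaySummary:
    n_hits = len(up) + len(down)
    known = [x for _, x in up + down if x is not None]
    return PathwaySummary(
        pathway_name=pathway.pathway_name,
        cohort=cohort,
        up_genes=up,
        down_genes=down,
        mean_lfc_up=mean_up,
        mean_lfc_down=mean_down,
        n_hits=n_hits,
        pct_perturbed=integer_percent(n_hits, pathway.declared_size),
        pct_up=integer_percent(len(up), n_hits) if n_hits else 0,
        pct_down=integer_percent(len(down), n_hits) if n_hits else 0,
        min_lfc=min(known) if known else None,
        max_lfc=max(known) if known else None,
    )


def summarize_cohort(
    collection: GeneSetCollection,
    consensus: ConsensusResult | CohortProfile,
) -> CohortSummary:
    """Summarize a whole cohort; totals count gene-pathway pairs."""
    summaries: list[PathwaySummary] = []
    if isinstance(consensus, ConsensusResult):
        cohort = consensus.cohort
        for s in collection:
            summaries.append(
                summarize_pathway(s, consensus.by_pathway.get(s.pathway_name, ()), cohort)
            )
    else:
        cohort = consensus.cohort
        empty = DirectionalProfile(pathway_name="")
        for s in collection:
            prof = consensus.pathways.get(s.pathway_name)
            if prof is None:
                prof = DirectionalProfile(pathway_name=s.pathway_name)
            summaries.append(summarize_profile(s, prof, cohort))
    total = sum(s.n_hits for s in summaries)
    return CohortSummary(
        cohort=cohort,
        pathway_summaries=tuple(summaries),
        total_hits=total,
        pct_of_queried=integer_percent(total, collection.total_declared),
    )


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.2f}"


def summary_frame(summary: CohortSummary):
    """Tidy per-pathway TSV-ready frame for one cohort summary."""
    import pandas as pd

    rows = []
    for s in summary.pathway_summaries:
        for direction, genes, mean in (
            ("up", s.up_genes, s.mean_lfc_up),
            ("down", s.down_genes, s.mean_lfc_down),
        ):
            rows.append(
                {
                    "pathway": s.pathway_name,
                    "direction": direction,
                    "genes": ", ".join(g for g, _ in genes),
                    "mean_lfc": _fmt(mean),
                    "n": len(genes),
                    "pct_of_pathway": integer_percent(
                        len(genes), s.n_hits
                    ) if s.n_hits else 0,
                }
            )
        rows.append(
            {
                "pathway": s.pathway_name,
                "direction": "total",
                "genes": "",
                "mean_lfc": "",
                "n": s.n_hits,
                "pct_of_pathway": s.pct_perturbed,
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway", "direction", "genes", "mean_lfc", "n", "pct_of_pathway"]
    )


def render_markdown(summary: CohortSummary) -> str:
    """Render a cohort summary as a markdown table mirroring the report layout."""
    lines = [
        f"### {summary.cohort}: {summary.total_hits} significant gene-pathway "
        f"entries ({summary.pct_of_queried}% of genes queried)",
        "",
        "| Metabolic Pathway | Significant Genes | Average LFC |",
        "| --- | --- | --- |",
    ]
    for s in summary.pathway_summaries:
        cell_genes, cell_lfc = [], []
        if s.up_genes:
            cell_genes.append("Upregulated: " + ", ".join(g for g, _ in s.up_genes))
            cell_lfc.append(_fmt(s.mean_lfc_up))
        if s.down_genes:
            cell_genes.append("Downregulated: " + ", ".join(g for g, _ in s.down_genes))
            cell_lfc.append(_fmt(s.mean_lfc_down))
        lines.append(
            f"| {s.pathway_name} | {'<br>'.join(cell_genes)} | {'<br>'.join(cell_lfc)} |"
        )
    return "\n".join(lines) + "\n"
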