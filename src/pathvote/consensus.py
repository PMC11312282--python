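"""Per-gene vote tallying and the consensus advancement criterion.

Rather than pooling effect sizes, the consensus layer counts votes: for each
gene, the number of datasets in which it is significantly (adjusted p <
alpha, strict) upregulated and downregulated are tallied independently.  A
gene advances with a consensus direction when

* it is significant in at least two datasets in the predominant direction, and
* the predominant direction has at least twice as many supporting datasets
  as the minority direction (a 2:1 ratio; ties never advance, and a zero
  minority count satisfies the ratio vacuously).

The consensus mean LFC of an advanced gene averages the LFCs of the
significant datasets in the winning direction only.  Every dataset carries
one vote regardless of size or platform.  Significant cells with LFC
exactly 0 carry no direction and are excluded from both tallies (logged).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dge_io import LookupMatrix
from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

DIRECTIONS = ("up", "down", "none")


@dataclass(frozen=True)
class GeneVote:
    """Tally of significant up/down datasets for one gene in one cohort."""

    gene: str
    n_up: int
    n_down: int
    mean_lfc_up: float | None = None
    mean_lfc_down: float | None = None
    up_datasets: tuple[tuple[str, str], ...] = ()  # (dataset_id, tissue)
    down_datasets: tuple[tuple[str, str], ...] = ()
    direction: str = "none"
    consensus_mean_lfc: float | None = None

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("tallies must be nonnegative")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.direction == "up" and not (self.consensus_mean_lfc or 0) > 0:
            raise ValueError(f"{self.gene}: direction 'up' requires a positive consensus LFC")
        if self.direction == "down" and not (self.consensus_mean_lfc or 0) < 0:
            raise ValueError(f"{self.gene}: direction 'down' requires a negative consensus LFC")

    @property
    def supporting_datasets(self) -> tuple[tuple[str, str], ...]:
        """Datasets backing the predominant direction, with tissue labels."""
        if self.direction == "up":
            return self.up_datasets
        if self.direction == "down":
            return self.down_datasets
        return ()

    @property
    def advanced(self) -> bool:
        return self.direction != "none"


def tally_votes(matrix: LookupMatrix, alpha: float = DEFAULT_ALPHA) -> list[GeneVote]:
    """Tally significant up/down datasets for every gene in the matrix.

    Only non-missing cells vote; significance is strict (adj_p < alpha).
    Returns one (un-advanced) vote per gene, sorted by gene symbol.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    cells = matrix.cells
    if cells.empty:
        return []
    tissue_by_id = {m.dataset_id: m.tissue for m in matrix.datasets}

    sig = cells[cells["adj_p"] < alpha]
    zero_sig = sig[sig["lfc"] == 0.0]
    for row in zero_sig.itertuples():
        logger.warning(
            "gene %s in dataset %s: significant cell with LFC = 0 carries no "
            "direction; excluded from both tallies",
            row.gene,
            row.dataset_id,
        )

    def _by_gene(frame: pd.DataFrame) -> tuple[dict, dict, dict]:
        if frame.empty:
            return {}, {}, {}
        grouped = frame.groupby("gene", sort=False)
        counts = grouped.size().to_dict()
        means = grouped["lfc"].mean().to_dict()
        supporters = grouped["dataset_id"].agg(list).to_dict()
        return counts, means, supporters

    up_n, up_mean, up_ds = _by_gene(sig[sig["lfc"] > 0])
    down_n, down_mean, down_ds = _by_gene(sig[sig["lfc"] < 0])

    votes: list[GeneVote] = []
    for gene in sorted(cells["gene"].unique()):
        votes.append(
            GeneVote(
                gene=gene,
                n_up=int(up_n.get(gene, 0)),
                n_down=int(down_n.get(gene, 0)),
                mean_lfc_up=float(up_mean[gene]) if gene in up_mean else None,
                mean_lfc_down=float(down_mean[gene]) if gene in down_mean else None,
                up_datasets=tuple(
                    (d, tissue_by_id[d]) for d in up_ds.get(gene, ())
                ),
                down_datasets=tuple(
                    (d, tissue_by_id[d]) for d in down_ds.get(gene, ())
                ),
            )
        )
    return votes


def _advancement_direction(n_up: int, n_down: int) -> str:
    if n_up >= 2 and n_up >= 2 * n_down:
        return "up"
    if n_down >= 2 and n_down >= 2 * n_up:
        return "down"
    return "none"


def apply_advancement(vote: GeneVote) -> GeneVote:
    """Apply the advancement criterion, setting direction and consensus LFC."""
    direction = _advancement_direction(vote.n_up, vote.n_down)
    if direction == "up":
        consensus = vote.mean_lfc_up
    elif direction == "down":
        consensus = vote.mean_lfc_down
    else:
        consensus = None
    if direction != "none" and consensus is None:
        # can only happen for hand-built votes missing their direction mean
        raise ValueError(
            f"{vote.gene}: cannot advance {direction} without mean_lfc_{direction}"
        )
    return replace(vote, direction=direction, consensus_mean_lfc=consensus)


@dataclass
class ConsensusResult:
    """Advanced consensus votes for one cohort, attributed to pathways.

    A gene is voted once per cohort; the identical vote is attributed to
    every pathway containing it, so cohort totals count gene-pathway pairs.
    ``unqueried`` lists gene-set members absent from the lookup matrix.
    """

    cohort: str
    alpha: float
    votes: dict[str, GeneVote]  # all genes, advancement applied
    by_pathway: dict[str, tuple[GeneVote, ...]]  # advanced genes only
    unqueried: dict[str, tuple[str, ...]]

    @property
    def total_hits(self) -> int:
        return sum(len(v) for v in self.by_pathway.values())

    def advanced_genes(self) -> dict[str, GeneVote]:
        return {g: v for g, v in self.votes.items() if v.advanced}

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per advanced gene-pathway pair."""
        rows = []
        for pathway, pathway_votes in self.by_pathway.items():
            for v in pathway_votes:
                rows.append(
                    {
                        "pathway": pathway,
                        "gene": v.gene,
                        "direction": v.direction,
                        "n_up": v.n_up,
                        "n_down": v.n_down,
                        "consensus_mean_lfc": v.consensus_mean_lfc,
                        "supporting_datasets": ";".join(
                            d for d, _ in v.supporting_datasets
                        ),
                        "tissues": ";".join(t for _, t in v.supporting_datasets),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "pathway",
                "gene",
                "direction",
                "n_up",
                "n_down",
                "consensus_mean_lfc",
                "supporting_datasets",
                "tissues",
            ],
        )


def consensus_table(
    matrix: LookupMatrix,
    gene_sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> ConsensusResult:
    """Tally, advance and attribute votes to pathways for one cohort."""
    advanced = {v.gene: apply_advancement(v) for v in tally_votes(matrix, alpha)}
    matrix_genes = set(advanced)
    by_pathway: dict[str, tuple[GeneVote, ...]] = {}
    unqueried: dict[str, tuple[str, ...]] = {}
    for s in gene_sets:
        by_pathway[s.pathway_name] = tuple(
            advanced[g] for g in s.genes if g in advanced and advanced[g].advanced
        )
        unqueried[s.pathway_name] = tuple(g for g in s.genes if g not in matrix_genes)
    return ConsensusResult(
        cohort=matrix.cohort,
        alpha=alpha,
        votes=advanced,
        by_pathway=by_pathway,
        unqueried=unqueried,
    )
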