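"""Concordance/discordance classification between two cohort profiles.

A gene advanced in both a disease cohort and the ketogenic-intervention
cohort within the same pathway is *concordant* when the two consensus
directions agree and *discordant* when they oppose (the italic/bold
annotation semantics of the source tables).  Genes advanced in only one of
the two cohorts land in a disease-only or ketosis-only group; within each
pathway the four groups partition the union of the two cohorts' advanced
genes.  Comparison is pathway-scoped: a gene shared by two pathways is
compared within each.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .profiles import CohortProfile, DirectionalProfile


@dataclass(frozen=True)
class ConcordanceRecord:
    gene: str
    pathway_name: str
    disease_direction: str
    ketosis_direction: str
    classification: str
    disease_mean_lfc: float | None = None
    ketosis_mean_lfc: float | None = None

    def __post_init__(self) -> None:
        for d in (self.disease_direction, self.ketosis_direction):
            if d not in ("up", "down"):
                raise ValueError(
                    f"{self.gene}: directions must be 'up'/'down', got {d!r} "
                    "(inputs must be advanced genes only)"
                )
        expected = (
            "concordant"
            if self.disease_direction == self.ketosis_direction
            else "discordant"
        )
        if self.classification != expected:
            raise ValueError(
                f"{self.gene}: classification {self.classification!r} inconsistent "
                f"with directions ({self.disease_direction}/{self.ketosis_direction})"
            )


@dataclass(frozen=True)
class PathwayComparison:
    pathway_name: str
    concordant: tuple[ConcordanceRecord, ...]
    discordant: tuple[ConcordanceRecord, ...]
    disease_only: tuple[str, ...]
    ketosis_only: tuple[str, ...]


@dataclass(frozen=True)
class ComparisonReport:
    disease_cohort: str
    ketosis_cohort: str
    pathways: Mapping[str, PathwayComparison]


def _compare_pathway(
    name: str, disease: DirectionalProfile, ketosis: DirectionalProfile
) -> PathwayComparison:
    disease_genes = {g: "up" for g in disease.up} | {g: "down" for g in disease.down}
    ketosis_genes = {g: "up" for g in ketosis.up} | {g: "down" for g in ketosis.down}
    concordant, discordant = [], []
    for gene in disease_genes:
        if gene not in ketosis_genes:
            continue
        d_dir, k_dir = disease_genes[gene], ketosis_genes[gene]
        record = ConcordanceRecord(
            gene=gene,
            pathway_name=name,
            disease_direction=d_dir,
            ketosis_direction=k_dir,
            classification="concordant" if d_dir == k_dir else "discordant",
            disease_mean_lfc=disease.lfc_of(gene),
            ketosis_mean_lfc=ketosis.lfc_of(gene),
        )
        (concordant if record.classification == "concordant" else discordant).append(record)
    return PathwayComparison(
        pathway_name=name,
        concordant=tuple(concordant),
        discordant=tuple(discordant),
        disease_only=tuple(g for g in disease_genes if g not in ketosis_genes),
        ketosis_only=tuple(g for g in ketosis_genes if g not in disease_genes),
    )


def compare_profiles(disease: CohortProfile, ketosis: CohortProfile) -> ComparisonReport:
    """Classify every shared pathway's genes as concordant/discordant/only-one."""
    empty = lambda n: DirectionalProfile(pathway_name=n)  # noqa: E731
    names = list(disease.pathways)
    names += [n for n in ketosis.pathways if n not in disease.pathways]
    pathways = {
        name: _compare_pathway(
            name,
            disease.pathways.get(name, empty(name)),
            ketosis.pathways.get(name, empty(name)),
        )
        for name in names
    }
    return ComparisonReport(
        disease_cohort=disease.cohort,
        ketosis_cohort=ketosis.cohort,
        pathways=pathways,
    )


def comparison_counts(report: ComparisonReport) -> pd.DataFrame:
    """Per-pathway concordant/discordant counts."""
    return pd.DataFrame(
        [
            {
                "pathway": c.pathway_name,
                "n_concordant": len(c.concordant),
                "n_discordant": len(c.discordant),
            }
            for c in report.pathways.values()
        ],
        columns=["pathway", "n_concordant", "n_discordant"],
    )


def comparison_frame(report: ComparisonReport) -> pd.DataFrame:
    """Tidy export: one row per compared gene-pathway pair."""
    rows = []
    for comp in report.pathways.values():
        for rec in comp.concordant + comp.discordant:
            rows.append(
                {
                    "pathway": rec.pathway_name,
                    "gene": rec.gene,
                    "disease_direction": rec.disease_direction,
                    "ketosis_direction": rec.ketosis_direction,
                    "classification": rec.classification,
                    "disease_mean_lfc": rec.disease_mean_lfc,
                    "ketosis_mean_lfc": rec.ketosis_mean_lfc,
                }
            )
        for g in comp.disease_only:
            rows.append(
                {
                    "pathway": comp.pathway_name,
                    "gene": g,
                    "disease_direction": "",
                    "ketosis_direction": "",
                    "classification": "disease_only",
                    "disease_mean_lfc": None,
                    "ketosis_mean_lfc": None,
                }
            )
        for g in comp.ketosis_only:
            rows.append(
                {
                    "pathway": comp.pathway_name,
                    "gene": g,
                    "disease_direction": "",
                    "ketosis_direction": "",
                    "classification": "ketosis_only",
                    "disease_mean_lfc": None,
                    "ketosis_mean_lfc": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "gene",
            "disease_direction",
            "ketosis_direction",
            "classification",
            "disease_mean_lfc",
            "ketosis_mean_lfc",
        ],
    )


def render_markdown(report: ComparisonReport) -> str:
    """Markdown report with **bold** = discordant, *italic* = concordant."""
    lines = [
        f"### {report.disease_cohort} vs {report.ketosis_cohort}",
        "",
        "Bold genes are discordant (opposite consensus directions); italic "
        "genes are concordant (same direction).",
        "",
        "| Pathway | Compared genes | Disease-only | Ketosis-only |",
        "| --- | --- | --- | --- |",
    ]
    for comp in report.pathways.values():
        marked = [f"**{r.gene}**" for r in comp.discordant] + [
            f"*{r.gene}*" for r in comp.concordant
        ]
        lines.append(
            f"| {comp.pathway_name} | {', '.join(marked)} | "
            f"{', '.join(comp.disease_only)} | {', '.join(comp.ketosis_only)} |"
        )
    return "\n".join(lines) + "\n"
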