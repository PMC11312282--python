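"""Cohort expression profiles: per-pathway up/down gene lists with mean LFCs.

A *profile* is the distilled, direction-stratified output of the consensus
stage for one cohort: for each pathway, which genes advanced up, which
advanced down, and the average LFC of each group.  Profiles are the unit of
disease-vs-ketosis comparison and the format in which the packaged
published-table fixtures are shipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

logger = logging.getLogger(__name__)


class ProfileError(ValueError):
    """Raised for internally inconsistent profiles."""


@dataclass(frozen=True)
class DirectionalProfile:
    """One pathway's advanced genes for one cohort, split by direction.

    ``gene_lfcs`` carries per-gene consensus mean LFCs when the profile was
    computed from a lookup matrix; profiles restored from published summary
    tables only know the per-direction group means.
    """

    pathway_name: str
    up: tuple[str, ...] = ()
    down: tuple[str, ...] = ()
    mean_lfc_up: float | None = None
    mean_lfc_down: float | None = None
    gene_lfcs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ProfileError(
                f"{self.pathway_name}: gene(s) {sorted(overlap)} listed both up and down"
            )
        if self.up and self.mean_lfc_up is not None and self.mean_lfc_up <= 0:
            raise ProfileError(
                f"{self.pathway_name}: mean_lfc_up must be positive, got {self.mean_lfc_up}"
            )
        if self.down and self.mean_lfc_down is not None and self.mean_lfc_down >= 0:
            raise ProfileError(
                f"{self.pathway_name}: mean_lfc_down must be negative, got {self.mean_lfc_down}"
            )

    @property
    def n_hits(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self, gene: str) -> str | None:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return None

    def lfc_of(self, gene: str) -> float | None:
        """Per-gene consensus LFC if known, else the gene's group mean."""
        if self.gene_lfcs is not None and gene in self.gene_lfcs:
            return self.gene_lfcs[gene]
        direction = self.direction_of(gene)
        if direction == "up":
            return self.mean_lfc_up
        if direction == "down":
            return self.mean_lfc_down
        return None


@dataclass(frozen=True)
class CohortProfile:
    """All pathway profiles for one cohort, keyed by pathway name."""

    cohort: str
    pathways: Mapping[str, DirectionalProfile]

    def __post_init__(self) -> None:
        for name, prof in self.pathways.items():
            if prof.pathway_name != name:
                raise ProfileError(
                    f"profile keyed {name!r} names pathway {prof.pathway_name!r}"
                )
        # a gene advanced in two pathways must carry the same direction in
        # both: votes are per-gene per-cohort (defensive; see consensus).
        seen: dict[str, str] = {}
        for prof in self.pathways.values():
            for direction, genes in (("up", prof.up), ("down", prof.down)):
                for g in genes:
                    if seen.setdefault(g, direction) != direction:
                        raise ProfileError(
                            f"cohort {self.cohort}: gene {g} advanced in opposite "
                            "directions in different pathways"
                        )

    @property
    def total_hits(self) -> int:
        """Advanced gene-pathway pairs (a shared gene counts once per pathway)."""
        return sum(p.n_hits for p in self.pathways.values())

    def __getitem__(self, pathway_name: str) -> DirectionalProfile:
        return self.pathways[pathway_name]


def profile_from_consensus(result) -> CohortProfile:
    """Distill a :class:`~pathvote.consensus.ConsensusResult` into a profile."""
    pathways: dict[str, DirectionalProfile] = {}
    for pathway, votes in result.by_pathway.items():
        up = tuple(v.gene for v in votes if v.direction == "up")
        down = tuple(v.gene for v in votes if v.direction == "down")
        gene_lfcs = {v.gene: float(v.consensus_mean_lfc) for v in votes}
        up_vals = [gene_lfcs[g] for g in up]
        down_vals = [gene_lfcs[g] for g in down]
        pathways[pathway] = DirectionalProfile(
            pathway_name=pathway,
            up=up,
            down=down,
            mean_lfc_up=sum(up_vals) / len(up_vals) if up_vals else None,
            mean_lfc_down=sum(down_vals) / len(down_vals) if down_vals else None,
            gene_lfcs=gene_lfcs,
        )
    return CohortProfile(cohort=result.cohort, pathways=pathways)


def write_profile(profile: CohortProfile, path: Union[str, Path]) -> None:
    """Write a cohort profile as a TSV (cohort, pathway, direction, mean_lfc, genes)."""
    rows = []
    for pathway, prof in profile.pathways.items():
        for direction, genes, mean in (
            ("up", prof.up, prof.mean_lfc_up),
            ("down", prof.down, prof.mean_lfc_down),
        ):
            if genes:
                rows.append(
                    {
                        "cohort": profile.cohort,
                        "pathway": pathway,
                        "direction": direction,
                        "mean_lfc": "" if mean is None else f"{mean:.6g}",
                        "genes": ", ".join(genes),
                    }
                )
    pd.DataFrame(
        rows, columns=["cohort", "pathway", "direction", "mean_lfc", "genes"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(
    path: Union[str, Path],
    symbol_fixes: Mapping[str, str] | None = None,
) -> dict[str, CohortProfile]:
    """Read cohort profiles from a TSV written by :func:`write_profile`.

    ``symbol_fixes`` maps typographical gene-symbol variants to canonical
    symbols and is applied to every gene list on load (with a log record per
    substitution).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cohort", "pathway", "direction", "mean_lfc", "genes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ProfileError(f"{path}: missing required column(s) {missing}")

    fixes = dict(symbol_fixes or {})

    def _clean(raw: str) -> tuple[str, ...]:
        out = []
        for token in raw.split(","):
            g = token.strip()
            if g in fixes:
                logger.info("normalizing symbol %s -> %s", g, fixes[g])
                g = fixes[g]
            out.append(g)
        return tuple(out)

    profiles: dict[str, CohortProfile] = {}
    for cohort, group in df.groupby("cohort", sort=False):
        pathways: dict[str, dict] = {}
        for row in group.itertuples():
            entry = pathways.setdefault(row.pathway, {})
            if row.direction not in ("up", "down"):
                raise ProfileError(
                    f"{path}: direction must be 'up' or 'down', got {row.direction!r}"
                )
            if row.direction in entry:
                raise ProfileError(
                    f"{path}: duplicate {row.cohort}/{row.pathway}/{row.direction} row"
                )
            entry[row.direction] = (
                _clean(row.genes),
                None if pd.isna(row.mean_lfc) else float(row.mean_lfc),
            )
        profiles[str(cohort)] = CohortProfile(
            cohort=str(cohort),
            pathways={
                name: DirectionalProfile(
                    pathway_name=name,
                    up=entry.get("up", ((), None))[0],
                    down=entry.get("down", ((), None))[0],
                    mean_lfc_up=entry.get("up", ((), None))[1],
                    mean_lfc_down=entry.get("down", ((), None))[1],
                )
                for name, entry in pathways.items()
            },
        )
    return profiles
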