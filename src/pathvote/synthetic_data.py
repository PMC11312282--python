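"""Synthetic DGE cohorts with planted consensus structure.

The generator emulates what an expression-lookup query returns — a gene x
dataset matrix of (LFC, adjusted p) pairs — at the summary level, never raw
counts.  A chosen fraction of genes carries a true consensus direction: in
each dataset such a gene is called significant with probability
``replication_prob``; a significant call draws its adjusted p uniformly
below alpha and its LFC around the signed true effect, with the sign flipped
with probability ``1 - sign_fidelity``.  Null genes produce false positives
at rate ``false_pos_rate`` with a sign that is random by symmetry.  The
truth table lets recovery of the planted signal be scored exactly.

Defaults mirror the study conditions the pipeline targets: 242 genes (the
size of the packaged query universe), eight datasets with a 5 brain / 3
liver split (the composition of the ketogenic-intervention module), and
effect magnitudes around 0.6 resembling the printed consensus LFC range
(~0.2-1.6).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import GeneVote, _advancement_direction
from .dge_io import CELL_COLUMNS, DatasetMeta, LookupMatrix


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; all randomness flows from ``seed``."""

    n_genes: int = 242
    n_datasets: int = 8
    frac_perturbed: float = 0.16
    effect_mu: float = 0.6        # |LFC| of a true consensus effect
    effect_sigma: float = 0.2     # per-dataset spread around the effect
    replication_prob: float = 0.8
    sign_fidelity: float = 0.95
    false_pos_rate: float = 0.02
    null_lfc_sigma: float = 0.2
    alpha: float = 0.05
    seed: int = 0
    cohort: str = "KI"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_datasets < 1:
            raise ValueError("n_genes and n_datasets must be >= 1")
        for name in ("frac_perturbed", "replication_prob", "sign_fidelity", "false_pos_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_sigma", "null_lfc_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _dataset_metas(params: SimParams) -> tuple[DatasetMeta, ...]:
    # brain-majority tissue split (5:3 at K=8), alternating platforms
    k = params.n_datasets
    n_brain = math.ceil(k * 5 / 8)
    return tuple(
        DatasetMeta(
            dataset_id=f"SIM{j + 1:02d}",
            cohort=params.cohort,
            tissue="brain" if j < n_brain else "liver",
            species="mouse",
            platform="rnaseq" if j % 2 == 0 else "microarray",
        )
        for j in range(k)
    )


def generate_cohort(params: SimParams) -> tuple[LookupMatrix, pd.DataFrame]:
    """Generate one cohort matrix and its truth table, deterministic by seed.

    The truth table has columns ``gene``, ``true_direction`` (up/down/none)
    and ``true_effect_lfc`` (0 for null genes).
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_genes, params.n_datasets
    genes = np.array([f"G{i + 1:05d}" for i in range(n)])

    n_perturbed = int(round(params.frac_perturbed * n))
    perturbed_idx = rng.choice(n, size=n_perturbed, replace=False)
    is_perturbed = np.zeros(n, dtype=bool)
    is_perturbed[perturbed_idx] = True
    signs = np.zeros(n)
    signs[perturbed_idx] = rng.choice([1.0, -1.0], size=n_perturbed)
    true_effect = signs * params.effect_mu

    # per-cell draws, shape (n, k)
    u_sig = rng.random((n, k))
    sig = np.where(
        is_perturbed[:, None],
        u_sig < params.replication_prob,
        u_sig < params.false_pos_rate,
    )
    p_below = rng.uniform(0.0, params.alpha, size=(n, k))
    p_above = rng.uniform(params.alpha, 1.0, size=(n, k))
    adj_p = np.where(sig, p_below, p_above)

    flip = rng.random((n, k)) < (1.0 - params.sign_fidelity)
    cell_sign = np.where(flip, -signs[:, None], signs[:, None])
    noise = rng.normal(0.0, params.effect_sigma, size=(n, k))
    true_cell_lfc = cell_sign * params.effect_mu + noise
    null_lfc = rng.normal(0.0, params.null_lfc_sigma, size=(n, k))
    # a perturbed gene's non-significant cells look like noise; a null
    # gene's false positives carry a random sign through the symmetric draw
    lfc = np.where(is_perturbed[:, None] & sig, true_cell_lfc, null_lfc)

    cells = pd.DataFrame(
        {
            "gene": np.repeat(genes, k),
            "dataset_id": np.tile([f"SIM{j + 1:02d}" for j in range(k)], n),
            "lfc": lfc.ravel(),
            "adj_p": adj_p.ravel(),
        }
    )
    cells = cells.sort_values(["gene", "dataset_id"], kind="stable").reset_index(drop=True)
    matrix = LookupMatrix(
        cohort=params.cohort, datasets=_dataset_metas(params), cells=cells
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_direction": np.where(
                ~is_perturbed, "none", np.where(signs > 0, "up", "down")
            ),
            "true_effect_lfc": true_effect,
        }
    )
    return matrix, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    specificity: float
    direction_accuracy: float
    n_true_perturbed: int
    n_true_null: int
    n_advanced: int


def recovery_metrics(
    votes: Iterable[GeneVote] | Mapping[str, str],
    truth: pd.DataFrame,
) -> RecoveryMetrics:
    """Score advancement calls against the planted truth.

    ``votes`` is either the full post-advancement vote list or a mapping
    gene -> consensus direction.  Sensitivity counts true-perturbed genes
    advanced with the correct direction; specificity counts true-null genes
    not advanced; direction accuracy is scored among advanced true-perturbed
    genes.  Empty denominators yield NaN.
    """
    if isinstance(votes, Mapping):
        called = dict(votes)
    else:
        called = {v.gene: v.direction for v in votes}
    truth_dir = dict(zip(truth["gene"], truth["true_direction"]))

    n_true = sum(1 for d in truth_dir.values() if d != "none")
    n_null = sum(1 for d in truth_dir.values() if d == "none")
    correct = sum(
        1
        for g, d in truth_dir.items()
        if d != "none" and called.get(g, "none") == d
    )
    advanced_true = sum(
        1
        for g, d in truth_dir.items()
        if d != "none" and called.get(g, "none") != "none"
    )
    null_not_advanced = sum(
        1
        for g, d in truth_dir.items()
        if d == "none" and called.get(g, "none") == "none"
    )
    n_advanced = sum(1 for g in truth_dir if called.get(g, "none") != "none")
    return RecoveryMetrics(
        sensitivity=correct / n_true if n_true else math.nan,
        specificity=null_not_advanced / n_null if n_null else math.nan,
        direction_accuracy=correct / advanced_true if advanced_true else math.nan,
        n_true_perturbed=n_true,
        n_true_null=n_null,
        n_advanced=n_advanced,
    )


def null_advancement_probability(n_datasets: int, false_pos_rate: float) -> float:
    """Exact P(a null gene advances) under K independent datasets.

    A null gene is called significant in each dataset independently with
    probability f, with a random sign; it advances when the (n_up, n_down)
    outcome satisfies the criterion.  Computed by summing binomial
    probabilities over all outcomes.
    """
    k, f = n_datasets, false_pos_rate
    total = 0.0
    for s in range(k + 1):
        p_s = stats.binom.pmf(s, k, f)
        if p_s == 0.0:
            continue
        for u in range(s + 1):
            if _advancement_direction(u, s - u) != "none":
                total += p_s * stats.binom.pmf(u, s, 0.5)
    return float(total)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth table TSV (gene, true_direction, true_effect_lfc)."""
    truth.to_csv(path, sep="\t", index=False)


# Published-table fixture profiles live beside the profile data model but
# are re-exported here as part of the simulation/fixture toolkit.
from .fixtures import make_fixture_profiles  # noqa: E402,F401
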