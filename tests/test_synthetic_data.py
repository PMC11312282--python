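"""Synthetic cohort generation and recovery of the planted consensus signal."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pathvote import (
    SimParams,
    generate_cohort,
    null_advancement_probability,
    recovery_metrics,
)
from pathvote.consensus import apply_advancement, tally_votes


def advanced_directions(matrix, alpha):
    return {
        v.gene: v.direction
        for v in (apply_advancement(t) for t in tally_votes(matrix, alpha))
    }


def exhaustive_null_advance_probability(k, f):
    """Independent oracle: enumerate every per-dataset outcome sequence
    (non-significant / significant-up / significant-down) with its
    probability and apply the criterion as stated in text."""
    total = 0.0
    for seq in itertools.product(("ns", "up", "down"), repeat=k):
        p = 1.0
        for s in seq:
            p *= (1 - f) if s == "ns" else f / 2
        n_up, n_down = seq.count("up"), seq.count("down")
        wins = (n_up >= 2 and n_up >= 2 * n_down and n_up > n_down) or (
            n_down >= 2 and n_down >= 2 * n_up and n_down > n_up
        )
        if wins:
            total += p
    return total


class TestGenerator:
    def test_same_seed_reproduces_exactly_distinct_seeds_differ(self):
        params = SimParams(n_genes=40, n_datasets=4, seed=7)
        m1, t1 = generate_cohort(params)
        m2, t2 = generate_cohort(params)
        assert m1.cells.equals(m2.cells) and t1.equals(t2)
        m3, _ = generate_cohort(SimParams(n_genes=40, n_datasets=4, seed=8))
        assert not m1.cells.equals(m3.cells)

    def test_no_signal_no_false_positives_means_no_significant_cells(self):
        params = SimParams(
            n_genes=60, n_datasets=5, frac_perturbed=0.0, false_pos_rate=0.0, seed=1
        )
        matrix, truth = generate_cohort(params)
        assert int((matrix.cells["adj_p"] < params.alpha).sum()) == 0
        assert (truth["true_direction"] == "none").all()

    def test_truth_table_invariant(self):
        _, truth = generate_cohort(SimParams(n_genes=80, seed=2))
        nulls = truth["true_direction"] == "none"
        assert (truth.loc[nulls, "true_effect_lfc"] == 0).all()
        assert (truth.loc[~nulls, "true_effect_lfc"] != 0).all()

    def test_null_significance_rate_matches_false_pos_rate(self):
        f = 0.05
        params = SimParams(
            n_genes=2500, n_datasets=8, frac_perturbed=0.0, false_pos_rate=f, seed=3
        )
        matrix, _ = generate_cohort(params)
        n_cells = params.n_genes * params.n_datasets
        n_sig = int((matrix.cells["adj_p"] < params.alpha).sum())
        lo, hi = stats.binom.interval(0.9999, n_cells, f)
        assert lo <= n_sig <= hi

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(replication_prob=1.5)
        with pytest.raises(ValueError):
            SimParams(n_genes=0)
        with pytest.raises(ValueError):
            SimParams(effect_sigma=0.0)


class TestRecovery:
    def test_perfect_regime_recovers_everything(self):
        params = SimParams(
            n_genes=50,
            n_datasets=4,
            frac_perturbed=0.3,
            replication_prob=1.0,
            sign_fidelity=1.0,
            false_pos_rate=0.0,
            seed=5,
        )
        matrix, truth = generate_cohort(params)
        metrics = recovery_metrics(advanced_directions(matrix, params.alpha), truth)
        assert metrics.sensitivity == 1.0
        assert metrics.specificity == 1.0
        assert metrics.direction_accuracy == 1.0

    def test_all_null_cohort_without_false_positives_is_clean(self):
        params = SimParams(
            n_genes=50, n_datasets=6, frac_perturbed=0.0, false_pos_rate=0.0, seed=6
        )
        matrix, truth = generate_cohort(params)
        metrics = recovery_metrics(advanced_directions(matrix, params.alpha), truth)
        assert metrics.specificity == 1.0
        assert metrics.n_advanced == 0
        assert math.isnan(metrics.sensitivity)

    def test_sensitivity_nondecreasing_in_replication_and_dataset_count(self):
        # Monte-Carlo monotonicity over a small grid, one seed per cell,
        # tolerating sampling error
        tol = 0.05

        def sensitivity(r, k, seed):
            matrix, truth = _gen(r=r, k=k, seed=seed)
            return recovery_metrics(advanced_directions(matrix, 0.05), truth).sensitivity

        by_r = [sensitivity(r, 8, 21) for r in (0.3, 0.6, 0.9)]
        assert by_r[0] <= by_r[1] + tol <= by_r[2] + 2 * tol
        by_k = [sensitivity(0.6, k, 22) for k in (2, 4, 8)]
        assert by_k[0] <= by_k[1] + tol <= by_k[2] + 2 * tol


def _gen(r, k, seed):
    params = SimParams(
        n_genes=400,
        n_datasets=k,
        frac_perturbed=0.25,
        replication_prob=r,
        sign_fidelity=1.0,
        false_pos_rate=0.01,
        seed=seed,
    )
    matrix, truth = generate_cohort(params)
    return matrix, truth


class TestNullAdvancement:
    @pytest.mark.parametrize("k, f", [(2, 0.2), (4, 0.1), (8, 0.3), (8, 0.05)])
    def test_closed_form_matches_exhaustive_enumeration(self, k, f):
        assert null_advancement_probability(k, f) == pytest.approx(
            exhaustive_null_advance_probability(k, f), abs=1e-12
        )

    def test_simulated_null_advancement_rate_matches_exact_value(self):
        k, f, n = 8, 0.3, 20000
        params = SimParams(
            n_genes=n, n_datasets=k, frac_perturbed=0.0, false_pos_rate=f, seed=13
        )
        matrix, truth = generate_cohort(params)
        calls = advanced_directions(matrix, params.alpha)
        empirical = sum(1 for d in calls.values() if d != "none") / n
        exact = exhaustive_null_advance_probability(k, f)
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(empirical - exact) <= 3 * se
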