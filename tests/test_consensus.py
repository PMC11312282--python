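"""Vote tallying and the consensus advancement criterion."""
import itertools

import pytest

from pathvote import (
    GeneVote,
    apply_advancement,
    consensus_table,
    tally_votes,
)
from pathvote.gene_sets import GeneSetCollection, PathwayGeneSet

from conftest import build_matrix


def text_rule(n_up, n_down):
    """The advancement rule restated directly: significant in at least two
    datasets in one direction, and that direction's count at least twice the
    other's ('or vice versa'); anything else does not advance."""
    if n_up >= 2 and n_up >= 2 * n_down and n_up > n_down:
        return "up"
    if n_down >= 2 and n_down >= 2 * n_up and n_down > n_up:
        return "down"
    return "none"


def vote(n_up, n_down):
    return GeneVote(
        gene="G",
        n_up=n_up,
        n_down=n_down,
        mean_lfc_up=0.5 if n_up else None,
        mean_lfc_down=-0.5 if n_down else None,
    )


class TestTally:
    def test_hand_tally_counts_and_means(self):
        m = build_matrix(
            [
                ("G", "D1", 0.5, 0.01),
                ("G", "D2", 0.7, 0.04),
                ("G", "D3", -0.2, 0.3),
            ]
        )
        [v] = tally_votes(m)
        assert (v.n_up, v.n_down) == (2, 0)
        assert v.mean_lfc_up == pytest.approx(0.6)
        assert v.mean_lfc_down is None
        assert [d for d, _ in v.up_datasets] == ["D1", "D2"]

    def test_nowhere_significant_gene_gets_empty_tally(self):
        m = build_matrix([("G", "D1", 0.5, 0.2), ("G", "D2", -0.5, 0.9)])
        [v] = tally_votes(m)
        assert (v.n_up, v.n_down) == (0, 0)
        assert apply_advancement(v).direction == "none"

    def test_significance_is_strict(self):
        m = build_matrix([("G", "D1", 0.5, 0.05)])
        [v] = tally_votes(m)
        assert (v.n_up, v.n_down) == (0, 0)

    def test_zero_lfc_significant_cell_counts_nowhere_and_warns(self, caplog):
        m = build_matrix([("G", "D1", 0.0, 0.001)])
        with caplog.at_level("WARNING"):
            [v] = tally_votes(m)
        assert (v.n_up, v.n_down) == (0, 0)
        assert any("LFC = 0" in msg for msg in caplog.messages)

    def test_empty_matrix_yields_empty_list(self):
        m = build_matrix([("G", "D1", 0.5, 0.01)])
        m.cells = m.cells.iloc[:0]
        assert tally_votes(m) == []

    def test_invalid_alpha_rejected(self):
        m = build_matrix([("G", "D1", 0.5, 0.01)])
        with pytest.raises(ValueError, match="alpha"):
            tally_votes(m, alpha=1.5)


class TestAdvancement:
    @pytest.mark.parametrize(
        "n_up, n_down, expected",
        [
            (2, 0, "up"),      # the two-dataset floor alone suffices
            (3, 2, "none"),    # 3 < 2 * 2
            (2, 1, "up"),      # 2 >= 2 * 1
            (2, 2, "none"),    # ties never advance
            (1, 0, "none"),    # below the floor
            (0, 4, "down"),
            (1, 1, "none"),
        ],
    )
    def test_examples(self, n_up, n_down, expected):
        assert apply_advancement(vote(n_up, n_down)).direction == expected

    def test_matches_text_rule_for_all_tallies_up_to_eight_datasets(self):
        for n_up, n_down in itertools.product(range(9), repeat=2):
            if n_up + n_down > 8:
                continue
            assert apply_advancement(vote(n_up, n_down)).direction == text_rule(
                n_up, n_down
            ), (n_up, n_down)

    def test_consensus_mean_is_winning_directions_mean(self):
        v = apply_advancement(vote(3, 1))
        assert v.direction == "up"
        assert v.consensus_mean_lfc == 0.5

    def test_monotone_in_winning_direction(self):
        # adding a significant dataset in the winning direction never flips
        # the call to none or to the opposite direction
        for n_up in range(9):
            for n_down in range(9):
                d = apply_advancement(vote(n_up, n_down)).direction
                if d == "up":
                    assert apply_advancement(vote(n_up + 1, n_down)).direction == "up"
                elif d == "down":
                    assert apply_advancement(vote(n_up, n_down + 1)).direction == "down"

    def test_sign_symmetry_of_full_tally(self):
        specs = [
            ("A1", "D1", 0.5, 0.01),
            ("A1", "D2", 0.7, 0.02),
            ("A1", "D3", -0.4, 0.03),
            ("B1", "D1", -0.6, 0.01),
            ("B1", "D2", -0.2, 0.04),
            ("B1", "D3", 0.9, 0.2),
        ]
        flipped = [(g, d, -lfc, p) for g, d, lfc, p in specs]
        votes = {v.gene: apply_advancement(v) for v in tally_votes(build_matrix(specs))}
        mirror = {v.gene: apply_advancement(v) for v in tally_votes(build_matrix(flipped))}
        for gene in votes:
            v, w = votes[gene], mirror[gene]
            assert (v.n_up, v.n_down) == (w.n_down, w.n_up)
            if v.direction == "none":
                assert w.direction == "none"
            else:
                assert {v.direction, w.direction} == {"up", "down"}
                assert v.consensus_mean_lfc == pytest.approx(-w.consensus_mean_lfc)


class TestConsensusTable:
    @pytest.fixture
    def two_pathways(self):
        return GeneSetCollection(
            sets=(
                PathwayGeneSet("TCA", ("CS", "SDHA", "SDHB"), declared_size=3),
                PathwayGeneSet("ETC", ("SDHA", "CYCS"), declared_size=2),
            )
        )

    def test_shared_gene_vote_attributed_to_every_containing_pathway(self, two_pathways):
        m = build_matrix(
            [
                ("SDHA", "D1", -0.5, 0.01),
                ("SDHA", "D2", -0.7, 0.02),
                ("CS", "D1", 0.3, 0.5),
            ]
        )
        result = consensus_table(m, two_pathways)
        tca = {v.gene: v for v in result.by_pathway["TCA"]}
        etc = {v.gene: v for v in result.by_pathway["ETC"]}
        assert tca["SDHA"].direction == "down"
        assert etc["SDHA"] is tca["SDHA"]  # one vote per gene per cohort
        assert result.total_hits == 2  # gene-pathway pairs

    def test_unqueried_gene_set_members_reported(self, two_pathways):
        m = build_matrix([("CS", "D1", 0.3, 0.01), ("CS", "D2", 0.4, 0.01)])
        result = consensus_table(m, two_pathways)
        assert result.unqueried["TCA"] == ("SDHA", "SDHB")
        assert result.unqueried["ETC"] == ("SDHA", "CYCS")

    def test_empty_matrix_maps_every_pathway_to_empty(self, two_pathways):
        m = build_matrix([("CS", "D1", 0.3, 0.01)])
        m.cells = m.cells.iloc[:0]
        result = consensus_table(m, two_pathways)
        assert all(len(v) == 0 for v in result.by_pathway.values())

    def test_alpha_tightening_shrinks_each_direction(self, two_pathways):
        m = build_matrix(
            [
                ("CS", "D1", 0.5, 0.001),
                ("CS", "D2", 0.5, 0.002),
                ("SDHB", "D1", 0.4, 0.03),
                ("SDHB", "D2", 0.4, 0.04),
            ]
        )
        loose = consensus_table(m, two_pathways, alpha=0.05)
        tight = consensus_table(m, two_pathways, alpha=0.01)
        for pathway in loose.by_pathway:
            for direction in ("up", "down"):
                loose_set = {
                    v.gene for v in loose.by_pathway[pathway] if v.direction == direction
                }
                tight_set = {
                    v.gene for v in tight.by_pathway[pathway] if v.direction == direction
                }
                assert tight_set <= loose_set
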