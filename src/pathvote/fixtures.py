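"""Packaged consensus profiles restored from published summary tables.

The package ships, as structured text, the per-pathway hit lists and average
LFC values of a published cross-dataset consensus analysis covering six
cohorts: three severe-mental-illness contrasts (SCZ — schizophrenia, BPD —
bipolar disorder, MDD — major depressive disorder), a ketogenic-intervention
contrast (KI), and two chronic-medication contrasts (AP — antipsychotics,
MS — mood stabilizers).  These fixtures let every downstream stage (pathway
summaries, concordance comparison, report rendering) be exercised and
checked against the printed numbers without any raw data.

Gene lists are stored exactly as printed; a small, explicit mapping of
obvious typographical symbol variants (:data:`SYMBOL_FIXES`) is applied on
load so the fixtures line up with the canonical gene-set symbols.
"""
from __future__ import annotations

from importlib import resources

from .profiles import CohortProfile, read_profiles

#: Typographical gene-symbol variants in the source tables -> canonical
#: symbols as they appear in the packaged gene sets.
SYMBOL_FIXES = {
    "SLCIA3": "SLC1A3",   # SCZ lactate-shuttle up list
    "SLOVL6": "ELOVL6",   # BPD fatty-acid-synthesis down list
    "COX411": "COX4I1",   # KI ETC down list
    "SDAHF2": "SDHAF2",   # MS ETC down list
}

#: Cohort totals as printed in the source's running text (gene-pathway pairs).
PRINTED_COHORT_TOTALS = {"KI": 38, "SCZ": 126, "BPD": 130, "MDD": 141, "AP": 91, "MS": 44}

#: Cohorts whose printed total disagrees with the sum of their table entries.
#: The BPD table sums to 129 against a printed total of 130; the fixture
#: ships the table as printed and the discrepancy is flagged, not reconciled.
FLAGGED_TOTALS = {"BPD": {"printed": 130, "table_sum": 129}}


def make_fixture_profiles() -> dict[str, CohortProfile]:
    """Load the packaged cohort profiles, typo-normalized, keyed by cohort."""
    with resources.as_file(
        resources.files("pathvote").joinpath("data/cohort_profiles.tsv")
    ) as p:
        return read_profiles(p, symbol_fixes=SYMBOL_FIXES)


# The published-table fixtures are the natural companions of the synthetic
# generator for end-to-end testing; keep the historical alias.
load_fixture_profiles = make_fixture_profiles
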