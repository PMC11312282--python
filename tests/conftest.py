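import pandas as pd
import pytest

from pathvote import (
    DatasetMeta,
    LookupMatrix,
    default_gene_sets,
    make_fixture_profiles,
)

PATHWAY_ETC = "Electron Transport Chain (ETC)"
PATHWAY_TCA = "Tricarboxylic Acid (TCA) Cycle"
PATHWAY_GLY = "Glycolysis"


@pytest.fixture(scope="session")
def collection():
    return default_gene_sets()


@pytest.fixture(scope="session")
def profiles():
    return make_fixture_profiles()


def build_matrix(cell_specs, cohort="KI", tissues=None):
    """Build a LookupMatrix from (gene, dataset_id, lfc, adj_p) tuples."""
    ids = []
    for _, ds, _, _ in cell_specs:
        if ds not in ids:
            ids.append(ds)
    tissues = tissues or {}
    metas = tuple(
        DatasetMeta(dataset_id=i, cohort=cohort, tissue=tissues.get(i, "brain"))
        for i in ids
    )
    cells = pd.DataFrame(cell_specs, columns=["gene", "dataset_id", "lfc", "adj_p"])
    return LookupMatrix(cohort=cohort, datasets=metas, cells=cells)
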