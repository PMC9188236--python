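import numpy as np
import pytest

from woodid.forest_views import ForestConfig
from woodid.taxonomy_io import DatasetIndex, ImageRecord, TaxonomyTable


@pytest.fixture(scope="session")
def toy_taxonomy() -> TaxonomyTable:
    """3 families, 4 genera, 6 species: enough for every cost level."""
    return TaxonomyTable({
        "Afzelia africana": ("Afzelia", "Fabaceae-Detarioideae"),
        "Afzelia bella": ("Afzelia", "Fabaceae-Detarioideae"),
        "Cynometra alexandri": ("Cynometra", "Fabaceae-Detarioideae"),
        "Alstonia boonei": ("Alstonia", "Apocynaceae"),
        "Khaya anthotheca": ("Khaya", "Meliaceae"),
        "Entandrophragma utile": ("Entandrophragma", "Meliaceae"),
    })


@pytest.fixture(scope="session")
def toy_index(toy_taxonomy) -> DatasetIndex:
    """2 species x 2 trees x 1 specimen x 3 views = 12 records."""
    records = []
    for sp in ("Afzelia africana", "Alstonia boonei"):
        slug = sp.split()[0]
        for t in range(2):
            for view in ("transverse", "tangential", "radial"):
                records.append(ImageRecord(
                    image_id=f"{slug}_t{t}_{view}",
                    path=f"{slug}_t{t}_{view}.png",
                    species=sp,
                    tree_id=f"{slug}/t{t}",
                    view=view,
                    specimen_id=f"{slug}_t{t}_s0",
                ))
    return DatasetIndex(records, toy_taxonomy)


@pytest.fixture(scope="session")
def separable_classes():
    """Two well-separated Gaussian blobs in 256-d descriptor space."""
    rng = np.random.default_rng(7)
    n = 40
    mu_a = np.zeros(256)
    mu_b = np.zeros(256)
    mu_a[:8] = 1.0
    mu_b[8:16] = 1.0
    X = np.vstack([
        rng.normal(mu_a, 0.08, size=(n, 256)),
        rng.normal(mu_b, 0.08, size=(n, 256)),
    ])
    y = np.array(["Afzelia africana"] * n + ["Alstonia boonei"] * n)
    return X, y


@pytest.fixture(scope="session")
def small_forest_cfg() -> ForestConfig:
    return ForestConfig(n_trees=60, mtry=15, seed=0)
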