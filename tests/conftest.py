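import numpy as np
import pandas as pd
import pytest

from lakediv import synthetic
from lakediv.diversity import build_trait_space, gower_matrix
from lakediv.trees import build_tree


@pytest.fixture(scope="session")
def tiny_taxa() -> pd.DataFrame:
    """Hand-built 8-taxon pool: two classes, nested lineages, one coarse
    (genus-level) record, one non-target harpacticoid, full traits."""
    rows = [
        # taxon_id, species, genus, family, order, class, rank, length, guild
        ("Daphnia_pulex", "Daphnia pulex", "Daphnia", "Daphniidae",
         "Anomopoda", "Branchiopoda", "species", 1.5, 2),
        ("Daphnia_rosea", "Daphnia rosea", "Daphnia", "Daphniidae",
         "Anomopoda", "Branchiopoda", "species", 1.2, 2),
        ("Daphnia_spp", None, "Daphnia", "Daphniidae",
         "Anomopoda", "Branchiopoda", "genus", 1.3, 2),
        ("Ceriodaphnia_quadrangula", "Ceriodaphnia quadrangula",
         "Ceriodaphnia", "Daphniidae", "Anomopoda", "Branchiopoda",
         "species", 0.5, 2),
        ("Holopedium_gibberum", "Holopedium gibberum", "Holopedium",
         "Holopediidae", "Ctenopoda", "Branchiopoda", "species", 1.0, 3),
        ("Cyclops_scutifer", "Cyclops scutifer", "Cyclops", "Cyclopidae",
         "Cyclopoida", "Copepoda", "species", 1.1, 4),
        ("Leptodiaptomus_tyrrelli", "Leptodiaptomus tyrrelli",
         "Leptodiaptomus", "Diaptomidae", "Calanoida", "Copepoda",
         "species", 1.4, 3),
        ("Bryocamptus_sp", "Bryocamptus sp", "Bryocamptus", "Canthocamptidae",
         "Harpacticoida", "Copepoda", "species", 0.6, 1),
    ]
    return pd.DataFrame(rows, columns=[
        "taxon_id", "species", "genus", "family", "order", "class", "rank",
        "body_length", "guild",
    ])


@pytest.fixture(scope="session")
def small_sim() -> synthetic.SimConfig:
    return synthetic.SimConfig(
        n_lakes=150, n_species=30, taxonomy_shape=(2, 4, 8, 15), seed=42)


@pytest.fixture(scope="session")
def small_world(small_sim):
    """Generated lakes+climate, pool, and incidence for the small config."""
    lakes = synthetic.generate_climate(synthetic.generate_lakes(small_sim), small_sim)
    taxa = synthetic.generate_species_pool(small_sim)
    occ = synthetic.generate_occurrences(lakes, taxa, small_sim)
    return lakes, taxa, occ


@pytest.fixture(scope="session")
def small_tree(small_world):
    _, taxa, _ = small_world
    return build_tree(taxa[taxa["rank"] == "species"].reset_index(drop=True))


@pytest.fixture(scope="session")
def small_space(small_world):
    _, taxa, _ = small_world
    return build_trait_space(gower_matrix(taxa))
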