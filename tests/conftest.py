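import numpy as np
import pandas as pd
import pytest

from eivsdm.simulate import (
    LandscapeConfig,
    LatentLayerConfig,
    MappedLayerConfig,
    SpeciesConfig,
    assemble_communities,
    generate_landscape,
    generate_species_pool,
)
from eivsdm.site_eiv import SpeciesEIVTable


def small_landscape_config(**mapped_overrides) -> LandscapeConfig:
    latent = {
        "temperature": LatentLayerConfig(length_scale=4.0),
        "moisture": LatentLayerConfig(length_scale=3.0),
        "light": LatentLayerConfig(length_scale=3.0),
    }
    mapped = {
        "temperature": MappedLayerConfig("temperature", 0.0),
        "precipitation": MappedLayerConfig("moisture", 1.0),
        "radiation": MappedLayerConfig("light", 1.0),
        "ph": MappedLayerConfig("moisture", 0.5),
        "slope": MappedLayerConfig("light", 2.0),
    }
    mapped.update(mapped_overrides)
    return LandscapeConfig(
        grid_shape=(40, 40), cell_size=25.0, latent=latent, mapped=mapped
    )


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(small_landscape_config(), seed=101)


@pytest.fixture(scope="session")
def small_pool(small_landscape):
    cfg = SpeciesConfig(
        always_driving=("temperature",),
        n_extra_driving=2,
        breadth_range=(1.0, 2.0),
        prevalence_range=(0.5, 1.0),
        eiv_missing_fraction=0.0,
    )
    return generate_species_pool(small_landscape, 40, cfg, seed=102)


@pytest.fixture(scope="session")
def small_plots(small_landscape, small_pool):
    return assemble_communities(small_landscape, small_pool, 300, seed=103)


@pytest.fixture(scope="session")
def small_eivs(small_pool):
    return SpeciesEIVTable.from_species_pool(small_pool)


@pytest.fixture()
def toy_eiv_table():
    """Four species with hand-set indicator values (NaN = missing)."""
    df = pd.DataFrame(
        {
            "T": [2.0, 4.0, 5.0, 3.0],
            "M": [1.0, np.nan, 2.0, 5.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="species_id"),
    )
    return SpeciesEIVTable(values=df)


def toy_plots(presence_rows: dict, predictors: dict | None = None):
    """Build a PlotCommunityMatrix from a {plot: [species...]} mapping."""
    from eivsdm.simulate import PlotCommunityMatrix

    plot_ids = list(presence_rows)
    species = sorted({s for lst in presence_rows.values() for s in lst})
    presence = pd.DataFrame(
        0, index=pd.Index(plot_ids, name="plot_id"), columns=species,
        dtype=np.int8,
    )
    for p, lst in presence_rows.items():
        presence.loc[p, lst] = 1
    pred = pd.DataFrame(predictors or {}, index=presence.index)
    return PlotCommunityMatrix(
        plot_ids=np.array(plot_ids),
        plot_xy=np.zeros((len(plot_ids), 2), dtype=int),
        presence=presence,
        plot_predictors=pred,
    )
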