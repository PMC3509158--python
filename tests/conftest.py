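import logging

import pandas as pd
import pytest

import fallowfun as ff

logging.getLogger("fallowfun").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset() -> ff.synth.FallowDataset:
    """One study-sized synthetic dataset shared across read-only tests."""
    return ff.generate_fallow_survey(ff.GeneratorConfig(seed=42))


@pytest.fixture()
def simple_traits() -> pd.DataFrame:
    """Tiny hand-built trait table for arithmetic checks."""
    return pd.DataFrame(
        {
            "growth_form": ["tree", "shrub", "herb", "herb"],
            "n_pct": [2.0, 1.5, 2.0, 0.8],
            "lignin_pct": [12.0, 10.0, 10.0, 10.0],
            "polyphenol_pct": [3.0, 2.0, 1.0, 1.0],
            "green_fraction": [0.3, 0.4, 0.85, 0.85],
            "woody_fraction": [0.65, 0.5, 0.0, 0.0],
            "conv_factor": [3.0, 2.5, 2.0, 2.0],
        },
        index=pd.Index(["tree1", "shrub1", "grass1", "poorgrass"], name="species_id"),
    )


def make_survey(rows):
    """Survey frame from (plot, species, form, height, cover, dbh_list, biovol)."""
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "species_id",
            "growth_form",
            "avg_height_m",
            "cover_class",
            "dbh_cm",
            "biovolume_m3",
        ],
    )
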