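import numpy as np
import pandas as pd
import pytest

from gridmig import PipelineConfig, WorldConfig, generate_world
from gridmig.pipeline import Pipeline


def small_config(**kw) -> WorldConfig:
    base = dict(
        grid_height=8, grid_width=8, n_countries=2, units_per_country=2,
        subunits_per_unit=2, years=tuple(range(2000, 2005)), seed=7,
    )
    base.update(kw)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    """8×8, 2 countries, 5 years, no noise, no missingness."""
    return generate_world(small_config())


@pytest.fixture(scope="session")
def study_config():
    """Study-scale conditions: 64×64, 8 countries × 8 units, 12 years."""
    def make(noise=0.0, seed=11, missing=None):
        return WorldConfig(
            grid_height=64, grid_width=64, n_countries=8, units_per_country=8,
            subunits_per_unit=2, years=tuple(range(2000, 2012)), seed=seed,
            rate_noise_sd=noise,
            missingness_fractions=missing or dict(combine=0, split=0, partial=0, absent=0),
        )
    return make


@pytest.fixture(scope="session")
def clean_world(study_config):
    return generate_world(study_config(noise=0.0))


@pytest.fixture(scope="session")
def noisy_world(study_config):
    return generate_world(study_config(noise=1.0))


@pytest.fixture(scope="session")
def clean_pipeline(study_config):
    """Pipeline run end-to-end on the clean study-scale world."""
    pipe = Pipeline(PipelineConfig(world=study_config(noise=0.0), write_outputs=False))
    pipe.run()
    return pipe


@pytest.fixture(scope="session")
def noisy_pipeline(study_config):
    pipe = Pipeline(PipelineConfig(world=study_config(noise=1.0), write_outputs=False))
    pipe.run()
    return pipe


@pytest.fixture(scope="session")
def world64():
    """64×64, 16 admin-1 units (4 countries × 4), 5 years."""
    return generate_world(WorldConfig(
        grid_height=64, grid_width=64, n_countries=4, units_per_country=4,
        subunits_per_unit=2, years=tuple(range(2000, 2005)), seed=5,
    ))


def make_series(records) -> pd.DataFrame:
    """Rate-series DataFrame from (unit, country, year, rate_type, value, pop) tuples."""
    return pd.DataFrame(
        records,
        columns=["unit_id", "country_id", "year", "rate_type", "value", "population"],
    ).assign(source_flag="reported")


def weighted_unit_rates(world, labels=None):
    """Independent population-weighted aggregation of true rates (oracle)."""
    labels = world.admin1 if labels is None else labels
    rows = []
    for rt, rates in (("birth", world.true_birth_rate), ("death", world.true_death_rate)):
        for yi, year in enumerate(world.years):
            for uid in np.unique(labels):
                if uid <= 0:
                    continue
                sel = labels == uid
                p = world.population[yi][sel]
                rows.append(dict(unit_id=int(uid), year=year, rate_type=rt,
                                 value=float(np.average(rates[yi][sel], weights=p))))
    return pd.DataFrame(rows)
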