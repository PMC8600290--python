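"""Shared fixtures: a desk-scale synthetic study, small enough for unit tests."""

import numpy as np
import pandas as pd
import pytest

from fieldeqtl import SimConfig, run_study, simulate_bundle
from fieldeqtl.synthetic import simulate_genotypes, simulate_meteo, simulate_schedule


def tiny_config(**overrides) -> SimConfig:
    base = dict(
        n_chrom=4,
        markers_per_chrom=6,
        n_cssl_per_background=8,
        n_bil=1,
        n_genes=40,
        n_filler_genes=8,
        n_sampling_days=6,
        n_transplant_sets=2,
        season_span_days=80,
        sampling_start_day=25,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    return simulate_bundle(tiny_config())


@pytest.fixture(scope="session")
def main_bundle():
    """The default study design: 80 CSSLs + 2 parents + 2 BILs, 144 markers,
    300 modelled genes (20% polymorphic, planted |dmu| = 4 x noise sd),
    8 bihourly sampling days x 2 transplant sets."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def main_study(main_bundle):
    return run_study(main_bundle, n_perm_poly=200, n_perm_scan=200, seed=1)


@pytest.fixture(scope="session")
def main_validation(main_bundle, main_study):
    """A second season for the same panel: shifted weather trend, fresh
    schedule and noise, preprocessed on the training gene list."""
    from fieldeqtl import pipeline
    from fieldeqtl.synthetic import simulate_validation_bundle

    vb = simulate_validation_bundle(main_bundle, seed=77, temp_offset=2.0, n_days=4)
    vexpr = pipeline.validation_expression(vb, main_study.expr)
    return vb, vexpr


@pytest.fixture(scope="session")
def tiny_study(tiny_bundle):
    return run_study(tiny_bundle, n_perm_poly=150, n_perm_scan=150, seed=3)


@pytest.fixture(scope="session")
def tiny_panel():
    panel, segments = simulate_genotypes(tiny_config(), np.random.default_rng(1))
    return panel, segments


@pytest.fixture(scope="session")
def tiny_meteo():
    return simulate_meteo(tiny_config(), seed=4)


@pytest.fixture()
def toy_meteo():
    """Two days of perfectly regular weather for hand-computed feature checks."""
    idx = pd.date_range("2015-06-01", periods=2 * 1440, freq="1min")
    temp = np.full(len(idx), 25.0)
    rad = np.zeros(len(idx))
    frame = pd.DataFrame({"temperature": temp, "radiation": rad}, index=idx)
    from fieldeqtl.data_io import MeteoSeries

    return MeteoSeries(frame)
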