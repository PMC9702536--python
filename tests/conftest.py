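"""Shared fixtures: the reference bath and noiseless factorial data.

The noiseless factorial kinetics grid and the per-cell inverse-De fits
are expensive (dozens of PDE solves), so they are computed once per
session and shared between the module tests and the acceptance suite.
"""

import numpy as np
import pytest

from atpex import (
    GRAPE_POMACE_DE_SURFACE,
    SynthConfig,
    default_system,
    fit_de,
    gen_kinetics_grid,
)

#: sampling cadence of the extraction experiments, minutes
TIMES_MIN = (2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@pytest.fixture(scope="session")
def system():
    return default_system()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SynthConfig(seed=1, noise_model="none", noise_rel=0.0, times_min=TIMES_MIN)


@pytest.fixture(scope="session")
def noiseless_grid(noiseless_cfg, system):
    """(table, curves) of the noiseless 4 AED x 3 T factorial design."""
    return gen_kinetics_grid(noiseless_cfg, system, GRAPE_POMACE_DE_SURFACE)


@pytest.fixture(scope="session")
def de_roundtrip_fits(noiseless_grid, system):
    """Per-cell inverse-De estimates from the noiseless factorial curves."""
    _, curves = noiseless_grid
    fits = {}
    for (aed, temp), curve in sorted(curves.items()):
        fits[(aed, temp)] = fit_de(curve, system)
    return fits


@pytest.fixture(scope="session")
def times_s():
    return np.asarray(TIMES_MIN) * 60.0


@pytest.fixture(scope="session")
def demo_report_pair():
    """Two independent end-to-end pipeline runs with the same seed."""
    from atpex import run_demo_pipeline

    return (
        run_demo_pipeline(seed=11, noise_rel=0.03),
        run_demo_pipeline(seed=11, noise_rel=0.03),
    )
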