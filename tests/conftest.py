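"""Shared fixtures: small seeded synthetic datasets sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from ptxmux.design import make_problem
from ptxmux.sar import compress_vop, concat_rows
from ptxmux.synth import generate_dataset

FIXTURE_SEED = 1
DESIGN_GRID_N = 14
DESIGN_SPACING_M = 0.014


@pytest.fixture(scope="session")
def dataset():
    """Design-scale synthetic two-row array dataset (14^3 grid, 14 mm)."""
    return generate_dataset(FIXTURE_SEED, grid_n=DESIGN_GRID_N,
                            spacing_m=DESIGN_SPACING_M)


@pytest.fixture(scope="session")
def qcombined(dataset):
    return concat_rows(dataset.qtop, dataset.qbottom)


@pytest.fixture(scope="session")
def vops(dataset, qcombined):
    """VOP sets for all scenarios at a compression level giving tens of
    VOPs (tractable constraint counts for the design sweeps)."""
    return {
        "full": dataset.qfull,
        "full_vop": compress_vop(dataset.qfull, 0.2, probe_modes=0),
        "combined_vop": compress_vop(qcombined, 0.2, probe_modes=0),
        "top_vop": compress_vop(dataset.qtop, 0.2, probe_modes=0),
        "bottom_vop": compress_vop(dataset.qbottom, 0.2, probe_modes=0),
    }


@pytest.fixture(scope="session")
def designed_full16(dataset, vops):
    """A 3-kT-points pulse homogenized to the 5-degree target (full16)."""
    from ptxmux.design import build_scenario, design_pulse, random_init

    sc = build_scenario("full16", dataset.fields, vops)
    prob = make_problem(sc, dataset.db0, 3)
    sol = design_pulse(prob, random_init(prob, np.random.default_rng(42)),
                       maxiter=1500)
    return sol


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small dataset for cheap structural tests."""
    return generate_dataset(FIXTURE_SEED, grid_n=10, spacing_m=0.02)


def toy_problem(dataset, vops, scenario_name: str, n_kt: int = 3, **kw):
    from ptxmux.design import build_scenario

    sc = build_scenario(scenario_name, dataset.fields, vops)
    return make_problem(sc, dataset.db0, n_kt, **kw)
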