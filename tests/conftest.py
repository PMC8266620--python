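"""Shared fixtures: panels, layouts and Monte-Carlo simulations.

The heavier simulations are session-scoped and reused across unit and
acceptance tests.  Problem sizes follow the recovery design: 200 features x
500 molecules x 67 nt for the two headline parameter-recovery runs, smaller
panels for directional contrasts.
"""

from __future__ import annotations

import numpy as np
import pytest

import maskless as mk
from maskless.layout import generate_masks

PERFECT_COUPLING = {b: 1.0 for b in "ACGT"}
#: photochemistry with no stray light and flat illumination
CLEAN_OPTICS = dict(global_scatter_coeff=0.0, side_leak=0.0,
                    corner_leak=0.0, edge_falloff_amplitude=0.0)


def quick_sim(lib, design="2SZ", rows=90, cols=90, n_features=None,
              molecules=100, photo=None, chem_kw=None, seed=0):
    """Build layout + masks and simulate; returns (layout, readset, events)."""
    n_features = n_features or len(lib)
    ids = (lib.ids * (n_features // len(lib.ids) + 1))[:n_features]
    lay = mk.build_layout(design, mk.DmdGeometry(rows=rows, cols=cols),
                          n_features=n_features, seed=seed, oligo_ids=ids)
    stack = generate_masks(lay, lib.sequences)
    photo = photo or mk.PhotochemParams(**CLEAN_OPTICS)
    chem = mk.ChemParams(molecules_per_feature=molecules, seed=seed,
                         baseline_substitution_rate=0.0, **(chem_kw or {}))
    rs = mk.simulate_synthesis(lib.sequences, lay, stack, photo, chem)
    em = mk.align_readset(rs, lib.sequences)
    return lay, rs, em


@pytest.fixture(scope="session")
def panel200():
    spec = mk.DesignSpec(n_oligos=200, oligo_len=67, k=5,
                         min_oligo_coverage=2, seed=11)
    return mk.design_library(spec)


@pytest.fixture(scope="session")
def panel100():
    spec = mk.DesignSpec(n_oligos=100, oligo_len=67, k=4,
                         min_oligo_coverage=1, seed=7)
    return mk.design_library(spec)


@pytest.fixture(scope="session")
def deletion_recovery(panel200):
    """95% photolysis, perfect coupling, no stray: the deletion channel alone."""
    return quick_sim(panel200, molecules=500,
                     chem_kw={"coupling_efficiency": PERFECT_COUPLING},
                     seed=3)


@pytest.fixture(scope="session")
def coupling_recovery(panel200):
    """Perfect photolysis, e_G = 99.7% (A/C/T 99.95%), uncapped, no stray."""
    photo = mk.PhotochemParams(k_rate=1e9, **CLEAN_OPTICS)
    return quick_sim(panel200, molecules=500, photo=photo, seed=4)


@pytest.fixture(scope="session")
def capping_pair(panel100):
    """Same chemistry with and without capping (95% photolysis, real e_G)."""
    unc = quick_sim(panel100, molecules=200, seed=5)
    cap = quick_sim(panel100, molecules=200,
                    chem_kw={"capping_enabled": True}, seed=5)
    return unc, cap


@pytest.fixture(scope="session")
def stray_sim(panel100):
    """Default stray-light model (calibrated scatter + leaks), no chemistry
    errors: the insertion channel alone."""
    photo = mk.PhotochemParams(edge_falloff_amplitude=0.0)
    return quick_sim(panel100, molecules=200, photo=photo,
                     chem_kw={"coupling_efficiency": PERFECT_COUPLING},
                     seed=6)


@pytest.fixture(scope="session")
def falloff_pair(panel100):
    """Flat vs edge-falloff illumination on a full 15x15-cell 2SZ grid."""
    flat = quick_sim(panel100, n_features=225, molecules=40, seed=8)
    photo = mk.PhotochemParams(global_scatter_coeff=0.0, side_leak=0.0,
                               corner_leak=0.0, edge_falloff_amplitude=0.1)
    fall = quick_sim(panel100, n_features=225, molecules=40, photo=photo,
                     seed=8)
    return flat, fall
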