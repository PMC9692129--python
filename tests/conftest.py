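"""Shared fixtures: moderately sized default cohorts reused across tests."""

import numpy as np
import pytest

from neutroflow import calcium_analysis as ca
from neutroflow import calcium_sim as cs
from neutroflow import tether_sim as ts


@pytest.fixture(scope="session")
def default_tether_events_02():
    """Paired selectin-only / ICAM-1 event tables at 0.2 dyne/cm^2 (n=10^4 each)."""
    conditions = [ts.SubstrateCondition(), ts.SubstrateCondition(ligand="ICAM1")]
    return ts.generate_tether_dataset(conditions, [0.2], 10_000, seed=20_240_101)


@pytest.fixture(scope="session")
def default_calcium_recovery():
    """P-selectin-alone cohort at 0.2 dyne/cm^2 with burst calls and truth.

    n=500 cells, default noise; used by the detector-recovery tests.
    """
    cohort = cs.generate_calcium_cohort(["P-selectin"], [0.2], 500, seed=777)
    calls = ca.detect_bursts(cohort)
    merged = calls.merge(cohort.truth, on="cell_id")
    return cohort, calls, merged


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
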