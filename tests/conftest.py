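"""Shared fixtures: standard scenarios and frozen-state FRAP populations."""

import numpy as np
import pytest

from polfate import assay_sim as A
from polfate.kinetics import (
    Event,
    PerturbationSchedule,
    build_rate_set,
    default_rates,
    propagate_mean_field,
    simulate_molecules,
)


@pytest.fixture(scope="session")
def uv_thz1_schedule():
    """UV 4 J/m2 at t=0, transcription-initiation block at 30 min."""
    return PerturbationSchedule((Event(0.0, "UV_DOSE", 4.0),
                                 Event(30.0, "THZ1_ON")))


@pytest.fixture(scope="session")
def mock_thz1_schedule():
    return PerturbationSchedule((Event(30.0, "THZ1_ON"),))


@pytest.fixture(scope="session")
def cs_trajectory(uv_thz1_schedule):
    """Mean-field CSA-KO residence-time scenario out to 2 h."""
    return propagate_mean_field(build_rate_set("CSA_KO", uv_thz1_schedule),
                                n0=50_000, horizon=120.0, step=0.05)


@pytest.fixture(scope="session")
def frozen_rates():
    """A rate set with every transition switched off: states are frozen, so
    FRAP populations with a chosen immobile fraction can be injected."""
    base = default_rates(k_init=0.0, k_escape=0.0, k_pre_release=0.0,
                         k_pdeg_uv=0.0, tau_elong=0.0, k_stall=0.0,
                         k_repair=0.0, k_degrade_stalled=0.0, k_syn=0.0)
    return build_rate_set("WT", PerturbationSchedule(()), base=base)


@pytest.fixture(scope="session")
def make_injected_history(frozen_rates):
    """Factory: molecule history with an exact immobile (stalled) fraction."""

    def _make(immobile_fraction: float, n_molecules: int, seed: int,
              protocol=A.GFP_RPB1):
        k = int(round(immobile_fraction * n_molecules))
        return simulate_molecules(
            frozen_rates, n_molecules=n_molecules, seed=seed,
            record_times=protocol.frame_offsets_min(),
            initial_counts={"free": n_molecules - k, "stalled": k})

    return _make
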