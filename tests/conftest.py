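"""Shared fixtures: the 8-shell protocol, tissue presets, recovery batches.

The recovery-study fixtures are session-scoped because they drive several
tests (accuracy, diameter ordering, SNR-bias ordering) from one MCMC batch.
"""

from __future__ import annotations

import numpy as np
import pytest

from axomyelin import (
    MCMCConfig,
    PriorSet,
    default_exvivo_protocol,
)
from axomyelin.synthetic import SimulationDesign, run_recovery_study

RECOVERY_SEED = 7
RECOVERY_N = 60


@pytest.fixture(scope="session")
def protocol():
    return default_exvivo_protocol()


@pytest.fixture(scope="session")
def priors():
    return PriorSet()


@pytest.fixture()
def fast_config():
    """Short chain for unit tests whose contract is qualitative."""
    return MCMCConfig(burn_in=4000, thin=20, n_samples=200, seed=11)


@pytest.fixture(scope="session")
def macaque_recovery(protocol):
    """Macaque-preset recovery over d_a 2..8 µm at SNR 150 and 50.

    Returns (summary, per-realization estimates) DataFrames.
    """
    design = SimulationDesign(
        parameter_set="macaque",
        gt_diameters=tuple(float(d) for d in range(2, 9)),
        snr_levels=(150.0, 50.0),
        n_realizations=RECOVERY_N,
        seed=RECOVERY_SEED,
    )
    return run_recovery_study(design, protocol, PriorSet(),
                              MCMCConfig(seed=RECOVERY_SEED),
                              return_estimates=True)


@pytest.fixture(scope="session")
def human_recovery(protocol):
    """Human-preset recovery at GT d_a = 4 µm, SNR 150."""
    design = SimulationDesign(
        parameter_set="human",
        gt_diameters=(4.0,),
        snr_levels=(150.0,),
        n_realizations=RECOVERY_N,
        seed=RECOVERY_SEED,
    )
    return run_recovery_study(design, protocol, PriorSet(),
                              MCMCConfig(seed=RECOVERY_SEED),
                              return_estimates=True)


def summary_value(summary, parameter: str, snr: float, gt_d_a: float,
                  column: str = "estimate_mean") -> float:
    row = summary[(summary.parameter == parameter)
                  & (summary.snr == snr)
                  & (summary.gt_d_a == gt_d_a)]
    assert len(row) == 1
    return float(row[column].iloc[0])
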