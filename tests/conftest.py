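"""Shared fixtures: calibrated parameter sets and the (expensive)
parameter-recovery study reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promec import PROMembraneParams
from promec.calibration import (
    CalibrationProblem,
    ExperimentSeries,
    fit,
    make_fixture,
    pro_feed_volume_series,
)
from promec.defaults import DEFAULT_MEMBRANE, default_mec_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def membrane() -> PROMembraneParams:
    """The calibrated default membrane."""
    return DEFAULT_MEMBRANE


@pytest.fixture(scope="session")
def mec_params():
    """Calibrated MEC parameter set for the standard coupled anolyte."""
    return default_mec_params(0.8)


# ---------------------------------------------------------------------------
# Parameter recovery study (shared by the calibration tests and the
# acceptance property suite): simulate constant-pressure feed-volume
# trajectories with known (A, S_struct), perturb with multiplicative noise,
# refit, and record the relative parameter errors.
# ---------------------------------------------------------------------------

TRUE_PARAMS = {"A": DEFAULT_MEMBRANE.A, "S_struct": DEFAULT_MEMBRANE.S_struct}
#: 2-minute logging interval over a 6 h run, as in the bench study.
_RECOVERY_GRID = np.arange(120.0, 6.0 * 3600.0 + 1.0, 120.0)


def _recovery_simulate(params):
    out = {}
    for M in (0.8, 2.0):
        out[f"V_F@{M}"] = pro_feed_volume_series(
            {**params, "B": DEFAULT_MEMBRANE.B}, M, 1.0, _RECOVERY_GRID,
            dt=300.0,
        )
    return out


def _recovery_templates():
    return [
        ExperimentSeries(
            name=f"V_F@{M}", t=_RECOVERY_GRID,
            values=np.zeros_like(_RECOVERY_GRID),
        )
        for M in (0.8, 2.0)
    ]


def run_recovery(noise_pct: float, seed: int) -> dict[str, float]:
    """One simulate-perturb-refit cycle; relative errors per parameter."""
    series = make_fixture(
        _recovery_simulate, TRUE_PARAMS, _recovery_templates(),
        noise_pct=noise_pct, seed=seed,
    )
    problem = CalibrationProblem(
        simulate=_recovery_simulate,
        free={"A": (5e-8, 5e-6), "S_struct": (1e-4, 1e-2)},
        series=series,
        n_starts=1,
    )
    result = fit(problem, seed=seed)
    return {
        name: abs(result.params[name] - TRUE_PARAMS[name])
        / TRUE_PARAMS[name]
        for name in TRUE_PARAMS
    }


@pytest.fixture(scope="session")
def recovery_errors_2pct() -> list[dict[str, float]]:
    """Recovery errors at 2 % multiplicative noise over ten seeds."""
    return [run_recovery(2.0, seed) for seed in range(10)]
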