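"""Shared fixtures.  The expensive objects — converged strings and the
Müller–Brown reference path — are session-scoped so every test file reuses
one computation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from pathpmf import (CVMetric, StringConfig, muller_brown, optimize_string,
                     reference_mfep, two_step_surface)


@pytest.fixture(scope="session")
def mb_surface():
    return muller_brown()


MB_MIN_A = np.array([-0.558, 1.442])
MB_MIN_B = np.array([0.623, 0.028])


@pytest.fixture(scope="session")
def mb_reference(mb_surface):
    return reference_mfep(mb_surface, MB_MIN_A, MB_MIN_B)


@pytest.fixture(scope="session")
def mb_string(mb_surface):
    cfg = StringConfig(n_nodes=96, eta=0.8, k_factor=1.0, samples_per_node=250,
                       ramp_steps=250, max_iter=150, tol=0.0, reparam_every=6)
    return optimize_string(mb_surface, MB_MIN_A, MB_MIN_B, cfg=cfg, seed=1,
                           full_end_a=MB_MIN_A, full_end_b=MB_MIN_B)


@pytest.fixture(scope="session")
def acyl_surface():
    return two_step_surface()


@pytest.fixture(scope="session")
def acyl_basins(acyl_surface):
    def basin(guess):
        return minimize(lambda x: float(acyl_surface.energy(x)), guess,
                        jac=lambda x: acyl_surface.gradient(x),
                        method="BFGS", options={"gtol": 1e-10}).x

    return basin([0.0, 0.0]), basin([1.0, 90.0])


@pytest.fixture(scope="session")
def acyl_metric():
    return CVMetric([1.0, 30.0], [False, True])


@pytest.fixture(scope="session")
def acyl_string(acyl_surface, acyl_basins, acyl_metric):
    """Full-size converged string on the two-step surface."""
    mc, ae = acyl_basins
    cfg = StringConfig(n_nodes=96, samples_per_node=250, ramp_steps=250,
                       max_iter=100, tol=0.0, reparam_every=3)
    return optimize_string(acyl_surface, mc, ae, metric=acyl_metric, cfg=cfg,
                           seed=3, full_end_a=mc, full_end_b=ae)


@pytest.fixture(scope="session")
def acyl_string_small(acyl_surface, acyl_basins, acyl_metric):
    """Reduced string for cheaper umbrella-stage tests."""
    mc, ae = acyl_basins
    cfg = StringConfig(n_nodes=48, samples_per_node=150, ramp_steps=150,
                       max_iter=40, tol=0.0, reparam_every=3)
    return optimize_string(acyl_surface, mc, ae, metric=acyl_metric, cfg=cfg,
                           seed=5, full_end_a=mc, full_end_b=ae)
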