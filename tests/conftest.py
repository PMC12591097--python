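"""Shared fixtures: reference scenarios, cached simulations, the calibrated fit.

The expensive pieces (ICL calibration, dense suspension simulations) are
session-scoped so every test reuses one computation.
"""

from __future__ import annotations

import dataclasses

import pytest

from depotsim import FitTarget, fit_icl, fixtures, simulate


@pytest.fixture(scope="session")
def observed():
    return fixtures.observed_metrics()


@pytest.fixture(scope="session")
def suspension_scenarios():
    """The three suspension dose levels, default (ICL-enabled) settings."""
    return {
        label: fixtures.build_scenario(label)
        for label in ("arl_im_150", "arl_im_300", "arl_im_400")
    }


@pytest.fixture(scope="session")
def no_icl_results():
    """Simulations of all three doses with the ICL barrier disabled."""
    return {
        label: simulate(fixtures.build_scenario(label, icl_enabled=False))
        for label in ("arl_im_150", "arl_im_300", "arl_im_400")
    }


@pytest.fixture(scope="session")
def icl_fit(observed, suspension_scenarios):
    """ICL kinetics calibrated to the 400 mg-eq observed metrics."""
    target = FitTarget(kind="metrics", metrics=observed["arl_im_400"])
    return fit_icl(suspension_scenarios["arl_im_400"], target)


def make_fast_suspension(**overrides):
    """A reduced-fidelity 400 mg-eq suspension scenario for fitting studies.

    Coarser bins, looser solver tolerances and a shorter horizon keep each
    simulation a few hundredths of a second; the physics is unchanged.
    """
    sc = fixtures.build_scenario("arl_im_400")
    sc.psd = dataclasses.replace(sc.psd, n_bins=6)
    sc.rtol, sc.atol = 1e-6, 1e-10
    sc.horizon_h = 1800.0
    sc.output_dt_h = 1.0
    for key, value in overrides.items():
        setattr(sc, key, value)
    return sc


@pytest.fixture()
def fast_suspension():
    return make_fast_suspension()
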