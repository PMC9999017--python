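"""Shared fixtures: small phantom cohorts for module tests and the
default-size calibrated cohorts for the study-level checks.

Everything is generated at test time from seeds; no stored data.
"""
from __future__ import annotations

import numpy as np
import pytest

from stirqmri import PhantomParams, generate_fshd_cohort, generate_hc_cohort

SMALL = dict(image_size=(96, 96))


@pytest.fixture(scope="session")
def hc_small():
    return generate_hc_cohort(PhantomParams(n_subjects=3, seed=7, **SMALL))


@pytest.fixture(scope="session")
def fshd_small():
    return generate_fshd_cohort(PhantomParams(n_subjects=8, seed=11, **SMALL))


@pytest.fixture(scope="session")
def hc_default():
    """The calibrated healthy-control cohort (6 subjects, seed 7)."""
    return generate_hc_cohort(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def fshd_default():
    """The calibrated FSHD cohort (25 subjects, seed 1234)."""
    return generate_fshd_cohort(PhantomParams(seed=1234))


@pytest.fixture(scope="session")
def wf3_default_tables(hc_default, fshd_default):
    from stirqmri import build_wf3_tables, compute_reference_limits
    limits = compute_reference_limits(hc_default)
    return limits, build_wf3_tables(fshd_default, limits)
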