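"""Shared fixtures: small synthetic sessions with known ground truth."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from assemblage.core import select_units
from assemblage.synthetic import AssemblySpec, GeneratorConfig, generate_session


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_session():
    """A compact tuned session: 8+8 units, 24 trials, one inter assembly."""
    cfg = GeneratorConfig(
        n_units_dca1=8,
        n_units_mpfc=8,
        trials_per_delay=12,
        delays_s=(4.0, 8.0),
        assemblies=(AssemblySpec("inter", 6),),
        error_frac=0.0,
        seed=11,
    )
    session, truth = generate_session(cfg)
    return select_units(session), truth


@pytest.fixture(scope="session")
def null_session():
    """No cue tuning, no assemblies, no rhythm: labels carry no information."""
    cfg = GeneratorConfig(
        n_units_dca1=5,
        n_units_mpfc=5,
        trials_per_delay=48,
        delays_s=(4.0,),
        dca1_tuned_frac=0.0,
        mpfc_tuned_frac=0.0,
        mpfc_tiling_frac=0.0,
        assemblies=(),
        rhythm_m=0.0,
        error_frac=0.0,
        seed=5,
    )
    session, truth = generate_session(cfg)
    return select_units(session), truth


def tensor_of(session, trials=None, window=(1.0, 1.0), bandwidth=0.1):
    """50-ms sample-aligned KDE tensor with a common bandwidth (fast)."""
    from assemblage.rates import build_rate_tensor

    bw = {u.unit_id: bandwidth for u in session.units}
    pool = trials if trials is not None else [
        t for t in session.completed_trials() if t.outcome == "correct"
    ]
    return build_rate_tensor(session, "sample", window, 0.05, bw, pool)


def labels_of(session, trials=None):
    pool = trials if trials is not None else [
        t for t in session.completed_trials() if t.outcome == "correct"
    ]
    return np.asarray([t.cue_side for t in pool])
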