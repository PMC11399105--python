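"""Shared fixtures.

MCMC runs are expensive, so replicate-run batches used by several
benchmark tests are computed once per session.  The analysis protocol for
simulated benchmarks mirrors the simulation conditions: brightness held
fixed at the generating value and a constant-in-time background, with the
diffusion coefficient and background inferred.
"""

from __future__ import annotations

import numpy as np
import pytest

from emitrack.core import TrackSet
from emitrack.metrics import tracking_error
from emitrack.sampler import map_estimate, run_chain
from emitrack.simulator import default_camera, default_optics, default_timing, make_fixture


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture(scope="session")
def timing():
    return default_timing()


def analysis_config(scenario, iterations, seed, burn_in=None, **model_kw):
    """Benchmark-protocol inference settings for a simulated scenario."""
    kw = dict(M=10, gamma=2.0, fixed_brightness=scenario.brightness, constant_background=True)
    kw.update(model_kw)
    burn = iterations // 2 if burn_in is None else burn_in
    return scenario.config(**kw).with_run(iterations=iterations, burn_in=burn, seed=seed)


def run_fixture(name, data_seed, chain_seed, iterations, burn_in=None):
    """Simulate one replicate of a named scenario and run the sampler."""
    stack, truth, scenario = make_fixture(name, seed=data_seed)
    chain = run_chain(stack, analysis_config(scenario, iterations, chain_seed, burn_in=burn_in))
    return truth, chain


def lateral(ts: TrackSet) -> TrackSet:
    return TrackSet(ts.positions[..., :2])


@pytest.fixture(scope="session")
def one_emitter_runs():
    """Ten replicate one-emitter movies analyzed with fresh chains; the
    first replicate is the canonical fixture itself."""
    out = []
    for i in range(10):
        truth, chain = run_fixture("one-emitter", None if i == 0 else 200 + i, i, iterations=3000, burn_in=1200)
        out.append((truth, chain, map_estimate(chain)))
    return out


@pytest.fixture(scope="session")
def three_emitter_runs():
    out = []
    for i in range(10):
        truth, chain = run_fixture("three-emitter", None if i == 0 else 300 + i, i, iterations=1200)
        out.append((truth, chain, map_estimate(chain)))
    return out


@pytest.fixture(scope="session")
def displacement_runs():
    """Ten replicates of the two-emitter scenario at each controlled mean
    displacement; returns {displacement: [(B_map, lateral tracking error)]}."""
    out = {}
    for disp, iterations in ((724, 1200), (434, 1600), (289, 1200)):
        rows = []
        for i in range(10):
            truth, chain = run_fixture(f"displacement-{disp}", 100 + i, i, iterations=iterations)
            est = map_estimate(chain)
            err = tracking_error(lateral(est.trackset()), lateral(truth), 5 * 133.0)
            rows.append((est.n_emitters, err))
        out[disp] = rows
    return out


@pytest.fixture(scope="session")
def prior_only_chain():
    """Long prior-only chain (likelihood disabled) on a tiny stack; used to
    check that the sampler reproduces its priors."""
    from emitrack.sampler import run_chain as _run
    from emitrack.simulator import Scenario, render_stack, simulate_tracks

    sc = Scenario(
        n_emitters=1,
        brightness=3000.0,
        camera=default_camera(8, 8),
        timing=default_timing(5),
        K=2,
        seed=3,
        starts=((530.0, 530.0, 0.0),),
    )
    stack, _ = render_stack(simulate_tracks(sc), sc)
    cfg = sc.config(M=12, gamma=3.0).with_run(iterations=12_000, burn_in=2_000, seed=4, prior_only=True)
    return _run(stack, cfg), cfg
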