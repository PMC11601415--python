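"""Shared fixtures: expensive simulated ensembles are session-scoped so the
property tests and the acceptance tests draw on the same runs."""

from __future__ import annotations

import numpy as np
import pytest

from isingdm import ModelParams, simulate_ensemble_arrays
from isingdm.experiments import fit_bias_to_error, inhibition_shift_analysis
from isingdm.stats import summarize

#: single master seed for the whole suite; child seeds derive from it
SUITE_SEED = 20240

# study conditions used throughout: N = 100 spins, threshold L = 5 in the
# threshold-sensitive checks, L = 2 where only matched-error ratios matter
# (those are threshold-independent in the diffusive regime) to keep first
# passages short.


@pytest.fixture(scope="session")
def disordered_point():
    """A representative disordered-phase parameter point."""
    return dict(T=0.45, eta=0.65)


@pytest.fixture(scope="session")
def disordered_fits(disordered_point):
    """Gain/loss bias fits to the observed error rates at one disordered point."""
    fg = fit_bias_to_error(
        disordered_point["T"], disordered_point["eta"], 0.09,
        seed=SUITE_SEED + 1, N=100, L=2.0, sim_budget=1500, final_budget=6000,
    )
    fl = fit_bias_to_error(
        disordered_point["T"], disordered_point["eta"], 0.24,
        seed=SUITE_SEED + 2, N=100, L=2.0, sim_budget=1500, final_budget=6000,
    )
    return fg, fl


@pytest.fixture(scope="session")
def bias_ladder():
    """Ensemble summaries for an increasing ladder of biases near the
    tricritical point (fixed T=0.29, eta=0.44, L=2)."""
    out = []
    for i, eps in enumerate([0.005, 0.01, 0.02, 0.04]):
        params = ModelParams(T=0.29, eta=0.44, eps1=eps, N=100, L=2.0)
        dec, rts, _, _ = simulate_ensemble_arrays(
            params, 4000, SUITE_SEED + 10 + i, warn_timeouts=False
        )
        out.append((eps, summarize((dec, rts))))
    return out


@pytest.fixture(scope="session")
def shift_report():
    """Fixed-error contour shifted by a small inhibition increment."""
    return inhibition_shift_analysis(
        [0.10, 0.20, 0.30], target_error=0.3, d_eta=0.05, eps1=0.01,
        sim_budget=1000, final_budget=4000, seed=SUITE_SEED + 30, N=100, L=2.0,
    )


@pytest.fixture(scope="session")
def regime_ensembles():
    """Decided-trial ensembles at a small fixed bias in three regimes:
    ordered (ballistic), near-tricritical (run-and-tumble), disordered."""
    out = {}
    for name, T, eta, n in [
        ("ordered", 0.25, 0.30, 3000),
        ("rnt", 0.29, 0.44, 3000),
        ("disordered", 0.42, 0.60, 3000),
    ]:
        params = ModelParams(T=T, eta=eta, eps1=0.01, N=100, L=5.0)
        dec, rts, _, _ = simulate_ensemble_arrays(
            params, n, SUITE_SEED + 50, warn_timeouts=False
        )
        out[name] = (dec, rts)
    return out
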