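"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spmscea import load_and_validate
from spmscea.disease_model import DEAD, N_STATES, ON


@pytest.fixture(scope="session")
def loaded():
    """Packaged default configuration, loaded once per session."""
    return load_and_validate()


@pytest.fixture(scope="session")
def params(loaded):
    return loaded.params


@pytest.fixture(scope="session")
def bia_inputs(loaded):
    return loaded.bia


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def microsim_occupancy(params, arm, n_walkers, record_cycles, seed):
    """Individual-level Monte-Carlo oracle for the cohort expectation.

    Walks ``n_walkers`` exchangeable patients through the same annual cycle
    operators as the cohort run, sampling each patient's destination, and
    returns the observed occupancy fractions at the requested cycles.
    Exchangeability lets the per-state multinomial draws stand in for
    per-patient draws exactly.
    """
    from spmscea.disease_model import build_cycle_operator

    rng = np.random.default_rng(seed)
    v0 = np.zeros(N_STATES)
    v0[ON] = params.baseline_distribution
    counts = rng.multinomial(n_walkers, v0)
    out = {}
    if 0 in record_cycles:
        out[0] = counts / n_walkers
    for t in range(1, max(record_cycles) + 1):
        op = build_cycle_operator(
            arm,
            params.natural_matrix,
            params.mortality,
            params.start_age + t - 1,
            params.male_fraction,
        )
        nxt = np.zeros(N_STATES, dtype=np.int64)
        for s in range(N_STATES):
            if counts[s]:
                nxt += rng.multinomial(counts[s], op[s])
        counts = nxt
        if t in record_cycles:
            out[t] = counts / n_walkers
    return out


def recover_hr(natural, adjusted, lo=1e-3, hi=5.0, rounds=60):
    """Estimate the progression hazard ratio linking two matrices.

    Least-squares fit of the aggregate upward-move probabilities under the
    rate-scale model ``p' = 1 - (1 - p)**h``, by bisection on the gradient;
    independent of the adjustment code path.
    """
    p = np.array([row[i + 1 :].sum() for i, row in enumerate(natural.probs[:-1])])
    q = np.array([row[i + 1 :].sum() for i, row in enumerate(adjusted.probs[:-1])])
    keep = p > 0
    p, q = p[keep], q[keep]
    log1p = np.log1p(-p)

    def grad(h):
        resid = (1.0 - (1.0 - p) ** h) - q
        return float(np.sum(resid * (-((1.0 - p) ** h)) * log1p))

    a, b = lo, hi
    for _ in range(rounds):
        mid = 0.5 * (a + b)
        if grad(a) * grad(mid) <= 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


def mass_is_conserved(trace, tol=1e-9):
    total = trace.occupancy.sum(axis=1)
    return bool(np.all(np.abs(total - 1.0) <= tol))


def dead_fraction(trace):
    return trace.occupancy[:, DEAD]
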