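import numpy as np
import pytest

import brainpbpk as bp


@pytest.fixture(scope="session")
def human():
    return bp.species_params("human")


@pytest.fixture(scope="session")
def human_derived(human):
    return bp.derive_params(human)


@pytest.fixture(scope="session")
def human_subject():
    return bp.SubjectSpec(body_weight=70.0, molecular_weight=150_000.0)


@pytest.fixture(scope="session")
def bolus_10():
    return bp.DoseEvent(time=0.0, dose=10.0)


@pytest.fixture(scope="session")
def human_sim_1000h(human, human_subject, bolus_10):
    """Reference human 10 mg/kg simulation, 1000 h, with degradation tracking."""
    return bp.simulate(
        human, human_subject, bolus_10, t_end=1000.0, dt_out=0.5,
        track_degradation=True,
    )


def random_state(rng, p, scale=1e-6):
    """Random admissible model state: non-negative drug, FcRn split freely."""
    y = rng.uniform(0.0, scale, bp.N_STATES)
    for i in bp.FCRN_STATE_INDEX:
        split = rng.uniform(0.0, 1.0)
        y[i] = p.FcRn_total * split
        y[i - 1] = p.FcRn_total * (1.0 - split)  # bound state precedes free FcRn
    return y


def rk4_integrate(f, y0, t_end, dt):
    """Fixed-step classical Runge-Kutta integrator (independent oracle)."""
    n_steps = int(round(t_end / dt))
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y
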