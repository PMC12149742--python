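"""Voltage-gated channel kinetics for the single-compartment model.

The scheme is a classic Connor–Stevens-style set of Hodgkin–Huxley rate
equations: transient sodium (m^3 h), delayed-rectifier potassium (n^4), and a
rapidly activating / rapidly inactivating A-type potassium conductance
(a^3 b).  Voltages are in mV, rates in 1/ms, time constants in ms.

All functions are scalar-friendly (they are compiled with numba and called
sample-by-sample inside the integrator) but also accept numpy arrays, which
the closed-form steady-state tests rely on.
"""

import numpy as np

from ._compat import njit

__all__ = [
    "alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n",
    "m_inf", "tau_m", "h_inf", "tau_h", "n_inf", "tau_n",
    "a_inf", "tau_a", "b_inf", "tau_b",
    "A_ACTIVATION_V_HALF",
]


#: global rate factor on the Na/DR gate kinetics.  The underlying rate
#: constants are for a warm preparation; recordings here are modeled at room
#: temperature, so all m/h/n rates are slowed by this factor (a Q10-style
#: scaling), which widens the action potential into the 1-3 ms range typical
#: of cultured cortical neurons.
TEMP_RATE_SCALE = 0.5


@njit(inline='always')
def _vtrap(x, y):
    # x/(1-exp(-x/y)) with the removable singularity at x=0 handled.
    # Scalar-only: the integrator calls this sample by sample; array callers
    # should go through np.vectorize (see m_inf_vec and friends below).
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - np.exp(-x / y))


@njit(inline='always')
def alpha_m(v):
    return 0.38 * _vtrap(v + 29.7, 10.0)


@njit(inline='always')
def beta_m(v):
    return 15.2 * np.exp(-0.0556 * (v + 54.7))


@njit(inline='always')
def alpha_h(v):
    return 0.266 * np.exp(-0.05 * (v + 48.0))


@njit(inline='always')
def beta_h(v):
    return 3.8 / (1.0 + np.exp(-0.1 * (v + 18.0)))


@njit(inline='always')
def alpha_n(v):
    return 0.02 * _vtrap(v + 45.7, 10.0)


@njit(inline='always')
def beta_n(v):
    return 0.25 * np.exp(-0.0125 * (v + 55.7))


@njit(inline='always')
def m_inf(v):
    a = alpha_m(v)
    return a / (a + beta_m(v))


@njit(inline='always')
def tau_m(v):
    return 1.0 / (TEMP_RATE_SCALE * (alpha_m(v) + beta_m(v)))


@njit(inline='always')
def h_inf(v):
    a = alpha_h(v)
    return a / (a + beta_h(v))


@njit(inline='always')
def tau_h(v):
    return 1.0 / (TEMP_RATE_SCALE * (alpha_h(v) + beta_h(v)))


@njit(inline='always')
def n_inf(v):
    a = alpha_n(v)
    return a / (a + beta_n(v))


@njit(inline='always')
def tau_n(v):
    return 1.0 / (TEMP_RATE_SCALE * (alpha_n(v) + beta_n(v)))


# --- A-type potassium conductance ------------------------------------------
# Fast-activating (a^3), fast-inactivating (b) transient K+ conductance with
# Kv4/Kv3-like Boltzmann voltage dependence.  The steep activation keeps the
# steady-state "window" conductance near rest negligible, so the resting
# potential is insensitive to the maximal A conductance while spike
# repolarization is strongly accelerated by it — the phenomenology of a
# 4-AP-sensitive transient current.

#: Boltzmann parameters of the activation/inactivation curves (mV)
A_ACT_VHALF_GATE = -35.0
A_ACT_SLOPE = 10.0
A_INACT_VHALF = -70.0
A_INACT_SLOPE = 7.0


@njit(inline='always')
def a_inf(v):
    return 1.0 / (1.0 + np.exp(-(v - A_ACT_VHALF_GATE) / A_ACT_SLOPE))


@njit(inline='always')
def tau_a(v):
    # fast, mildly voltage dependent: ~1.5 ms below rest, ~0.4 ms at spike top
    return 0.36 + 1.2 / (1.0 + np.exp((v + 40.0) / 15.0))


@njit(inline='always')
def b_inf(v):
    return 1.0 / (1.0 + np.exp((v - A_INACT_VHALF) / A_INACT_SLOPE))


@njit(inline='always')
def tau_b(v):
    # inactivation/recovery ~15 ms, slower than a spike, faster than a step
    return 15.0 + 0.0 * v


# Array-friendly wrappers (the njit'd scalar versions branch internally).
m_inf_vec = np.vectorize(lambda v: m_inf(v))
h_inf_vec = np.vectorize(lambda v: h_inf(v))
n_inf_vec = np.vectorize(lambda v: n_inf(v))
a_inf_vec = np.vectorize(lambda v: a_inf(v))
b_inf_vec = np.vectorize(lambda v: b_inf(v))


def _numeric_a_vhalf():
    """Voltage at which the peak-conductance activation a_inf^3 reaches 0.5.

    Used as the ground-truth half-activation voltage when checking that the
    pharmacologically isolated A-current recovers the model's voltage
    dependence.
    """
    from scipy.optimize import brentq

    f = lambda v: a_inf(v) ** 3 - 0.5
    return brentq(f, -80.0, 40.0)


# computed once at import; cheap (one scalar root find)
A_ACTIVATION_V_HALF = None


def a_activation_v_half():
    global A_ACTIVATION_V_HALF
    if A_ACTIVATION_V_HALF is None:
        A_ACTIVATION_V_HALF = _numeric_a_vhalf()
    return A_ACTIVATION_V_HALF
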