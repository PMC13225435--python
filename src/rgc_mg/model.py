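"""Right-hand side of the retinal ganglion cell ODE system.

The model is a single electrical compartment with

* intrinsic currents: fast Na+ (m^3 h), delayed-rectifier K+ (n^4),
  A-type K+ (a^3 b), L-type Ca2+ (s^2), Ca2+-activated K+ (Hill
  coefficient 2 in [Ca2+]i), and ohmic leak;
* synaptic currents: AMPA and NMDA conductances driven by the glutamate
  transient through first-order gating, the NMDA current additionally
  scaled by the Jahr-Stevens voltage-dependent Mg2+ block
  ``B(V, Mg) = 1 / (1 + eta * Mg * exp(-gamma * V))``;
* a single intracellular Ca2+ pool fed by the NMDA and L-type currents
  and cleared first-order toward ``ca_rest`` with time constant ``tau_ca``.

Membrane equation (currents in uA/cm^2, V in mV, t in ms):

    Cm dV/dt = -(I_Na + I_Kdr + I_KA + I_CaL + I_KCa + I_L + I_AMPA + I_NMDA)

All functions are vectorised: the state may carry a trailing batch axis so
that many parameter combinations (e.g. a Mg2+ dose grid) integrate in
lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple, Tuple

import numpy as np

from .kinetics import GATE_NAMES, GatingKinetics, default_kinetics
from .params import ModelParameters

__all__ = [
    "STATE_NAMES",
    "SimState",
    "IntrinsicCurrents",
    "mg_block_factor",
    "intrinsic_currents",
    "synaptic_currents",
    "gating_derivative",
    "calcium_derivative",
    "rhs",
    "resting_state",
    "NumericalBlowupError",
]

#: Order of the state vector: membrane potential, six intrinsic gates,
#: the two synaptic gates and the intracellular calcium concentration.
STATE_NAMES = ("V", "m", "h", "n", "a", "b", "s", "sAMPA", "sNMDA", "Ca")

N_STATE = len(STATE_NAMES)
_GATE_SLICE = slice(1, 7)  # m..s
_SYN_SLICE = slice(7, 9)  # sAMPA, sNMDA


class NumericalBlowupError(RuntimeError):
    """Raised when the integration leaves the physically plausible range."""

    def __init__(self, variable: str, t: float, value: float):
        self.variable = variable
        self.t = t
        self.value = value
        super().__init__(f"numerical blowup: {variable} = {value:.3g} at t = {t:.3f} ms")


@dataclass
class SimState:
    """Named view of one model state (scalars or batched arrays)."""

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    sAMPA: np.ndarray
    sNMDA: np.ndarray
    Ca: np.ndarray

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SimState":
        return cls(**{name: y[i] for i, name in enumerate(STATE_NAMES)})


class IntrinsicCurrents(NamedTuple):
    """Intrinsic membrane currents in uA/cm^2 (positive = outward)."""

    i_na: np.ndarray
    i_kdr: np.ndarray
    i_ka: np.ndarray
    i_cal: np.ndarray
    i_kca: np.ndarray
    i_leak: np.ndarray


def mg_block_factor(v, mg, params: ModelParameters = None) -> np.ndarray:
    """Fraction of NMDA conductance left unblocked by extracellular Mg2+.

    Jahr-Stevens form ``1 / (1 + eta * Mg * exp(-gamma * V))``: strictly
    increasing in V (depolarisation relieves the block) and strictly
    decreasing in Mg.  Returns 1 for Mg = 0.

    Parameters
    ----------
    v : membrane potential (mV)
    mg : extracellular Mg2+ concentration (mM), must be >= 0
    params : model parameters supplying ``eta`` and ``gamma``
    """
    if params is None:
        params = ModelParameters()
    mg = np.asarray(mg, dtype=float)
    if np.any(mg < 0):
        raise ValueError("extracellular [Mg2+] must be non-negative")
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + params.eta * mg * np.exp(-params.gamma * v))


def intrinsic_currents(state: SimState, params: ModelParameters) -> IntrinsicCurrents:
    """Evaluate the six intrinsic currents for a given state (uA/cm^2)."""
    v = state.V
    i_na = params.g_na * state.m**3 * state.h * (v - params.e_na)
    i_kdr = params.g_kdr * state.n**4 * (v - params.e_k)
    i_ka = params.g_ka * state.a**3 * state.b * (v - params.e_k)
    i_cal = params.g_cal * state.s**2 * (v - params.e_ca)
    ca2 = state.Ca**2
    i_kca = params.g_kca * ca2 / (ca2 + params.kd_kca**2) * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    return IntrinsicCurrents(i_na, i_kdr, i_ka, i_cal, i_kca, i_leak)


def synaptic_currents(state: SimState, mg, params: ModelParameters) -> Tuple[np.ndarray, np.ndarray]:
    """AMPA and NMDA currents (uA/cm^2) for a given state and [Mg2+].

    ``I_AMPA = g_AMPA * s_AMPA * (V - E_exc)`` and
    ``I_NMDA = g_NMDA * s_NMDA * B(V, Mg) * (V - E_exc)``; both are inward
    (negative) at subthreshold potentials when their gates are open.
    """
    drive = state.V - params.e_exc
    i_ampa = params.g_ampa * state.sAMPA * drive
    i_nmda = params.g_nmda * state.sNMDA * mg_block_factor(state.V, mg, params) * drive
    return i_ampa, i_nmda


def gating_derivative(s, glu, ec50: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """ds/dt for a synaptic gate driven by the glutamate transient.

    ``ds/dt = [Glu]/([Glu]+EC50) * (1-s)/tau_rise - s/tau_decay`` -- a
    saturating activation term during transmitter exposure plus first-order
    closure.  The gate stays in [0, 1] for any non-negative glutamate input.
    """
    s = np.asarray(s, dtype=float)
    glu = np.asarray(glu, dtype=float)
    act = glu / (glu + ec50)
    return act * (1.0 - s) / tau_rise - s / tau_decay


def calcium_derivative(ca, i_nmda, i_cal, params: ModelParameters) -> np.ndarray:
    """d[Ca2+]i/dt (uM/ms) from NMDA/L-type influx and first-order clearance.

    ``dCa/dt = -k_Ca,NMDA * f_Ca * I_NMDA - k_Ca,CaL * I_CaL
    - (Ca - Ca_rest)/tau_Ca``.  Inward (negative) currents yield positive
    influx; the scaling factors absorb the conversion from current density
    to concentration for the single-compartment geometry.
    """
    influx = -params.k_ca_nmda * params.f_ca * np.asarray(i_nmda) - params.k_ca_cal * np.asarray(i_cal)
    return influx - (np.asarray(ca) - params.ca_rest) / params.tau_ca


def rhs(
    t: float,
    y: np.ndarray,
    glu,
    mg,
    params: ModelParameters,
    kin: GatingKinetics,
) -> np.ndarray:
    """Time derivative of the full state vector.

    Parameters
    ----------
    t : time (ms); the dynamics are autonomous given ``glu`` and ``mg``
    y : state array, shape ``(10,)`` or ``(10, n_batch)`` in
        :data:`STATE_NAMES` order
    glu : glutamate concentration(s) at ``t`` (mM)
    mg : extracellular Mg2+ concentration(s) at ``t`` (mM)
    """
    state = SimState.from_vector(y)
    dy = np.empty_like(y)

    intr = intrinsic_currents(state, params)
    i_ampa, i_nmda = synaptic_currents(state, mg, params)
    total = intr.i_na + intr.i_kdr + intr.i_ka + intr.i_cal + intr.i_kca + intr.i_leak + i_ampa + i_nmda
    dy[0] = -total / params.cm

    for i, gate in enumerate(GATE_NAMES, start=1):
        x_inf, tau = kin.gates[gate].rates(state.V)
        dy[i] = (x_inf - y[i]) / tau

    dy[7] = gating_derivative(state.sAMPA, glu, params.ec50_ampa, params.tau_rise_ampa, params.tau_decay_ampa)
    dy[8] = gating_derivative(state.sNMDA, glu, params.ec50_nmda, params.tau_rise_nmda, params.tau_decay_nmda)
    dy[9] = calcium_derivative(state.Ca, i_nmda, intr.i_cal, params)
    return dy


def resting_state(
    params: ModelParameters = None,
    kin: GatingKinetics = None,
    n_batch: int = None,
) -> np.ndarray:
    """Initial state: gates at their steady state at ``v_rest``, synaptic
    gates closed, Ca at ``ca_rest``.

    Returns a vector of shape ``(10,)``, or ``(10, n_batch)`` when a batch
    size is given.
    """
    if params is None:
        params = ModelParameters()
    if kin is None:
        kin = default_kinetics()
    ss = kin.steady_state(params.v_rest)
    y = np.array(
        [params.v_rest, *(float(ss[g]) for g in GATE_NAMES), 0.0, 0.0, params.ca_rest],
        dtype=float,
    )
    if n_batch is not None:
        y = np.repeat(y[:, None], n_batch, axis=1)
    return y
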