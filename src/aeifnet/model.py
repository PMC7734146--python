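"""Adaptive exponential integrate-and-fire (AEIF) single-neuron dynamics.

The AEIF neuron couples a leaky membrane with an exponential
spike-initiation term, a subthreshold adaptation current ``w`` and a
dimensionless synaptic trace ``s``::

    C_m dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T) / Delta_T)
                - w + I_const + I_syn
    tau_w dw/dt = a (V - E_L) - w
    tau_s ds/dt = -s

A spike is detected whenever ``V > V_thres``; the state is then reset::

    V -> V_r,   w -> w + b,   s -> s + 1

The trace is normalized: each spike increments it by exactly one, and
the synaptic conductance of an edge is the product of the edge-class
conductance (nS) with the delayed presynaptic trace.  This keeps the six
edge-class conductances independent of one another even though every
neuron carries a single trace variable.

Units throughout: mV, pA, nS, ms (so conductance * voltage = pA and
capacitance / conductance = ms without conversion factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NeuronParams",
    "NeuronState",
    "aeif_derivatives",
    "apply_threshold_reset",
    "EXP_ARG_MAX",
]

#: Cap on the exponential argument (V - V_T) / Delta_T.  With the default
#: V_thres = -40 mV the cap is never active below threshold; it only
#: prevents overflow during the fast upswing between crossing and reset.
EXP_ARG_MAX = 50.0


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one AEIF neuron.

    Defaults are the excitatory cortical-neuron values used throughout
    the network studies (regular-spiking cell with spike-frequency
    adaptation).  Inhibitory (fast-spiking) neurons use ``a = 0`` nS and
    ``b = 0`` pA.

    Parameters
    ----------
    C_m : float
        Membrane capacitance, pF.
    g_L : float
        Leak conductance, nS.
    E_L : float
        Leak reversal potential, mV.
    Delta_T : float
        Slope factor of the exponential term, mV.
    V_T : float
        Exponential threshold potential, mV.
    tau_w : float
        Adaptation time constant, ms.
    tau_s : float
        Synaptic-trace decay time constant, ms.
    V_r : float
        Post-spike reset potential, mV.
    I_const : float
        Constant input current, pA.
    V_thres : float
        Spike-detection cutoff, mV.  Must lie above ``V_T`` so that the
        exponential upswing can develop before the reset fires.
    a : float
        Subthreshold adaptation coupling, nS.
    b : float
        Spike-triggered adaptation increment, pA.
    """

    C_m: float = 200.0
    g_L: float = 12.0
    E_L: float = -70.0
    Delta_T: float = 2.0
    V_T: float = -50.0
    tau_w: float = 300.0
    tau_s: float = 2.728
    V_r: float = -58.0
    I_const: float = 270.0
    V_thres: float = -40.0
    a: float = 2.0
    b: float = 70.0

    def __post_init__(self) -> None:
        for name in ("C_m", "g_L", "Delta_T", "tau_w", "tau_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not self.V_r < self.V_thres:
            raise ValueError(f"V_r ({self.V_r}) must lie below V_thres ({self.V_thres})")
        if not self.V_T < self.V_thres:
            raise ValueError(f"V_T ({self.V_T}) must lie below V_thres ({self.V_thres})")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state (V mV, w pA, dimensionless trace s >= 0)."""

    V: float
    w: float
    s: float = 0.0


def aeif_derivatives(
    state: NeuronState, params: NeuronParams, I_syn: float = 0.0
) -> tuple[float, float, float]:
    """Right-hand side of the AEIF equations.

    Parameters
    ----------
    state : NeuronState
        Current (V, w, s).
    params : NeuronParams
        Neuron constants.
    I_syn : float
        Total synaptic current arriving at the neuron, pA.

    Returns
    -------
    (dV/dt, dw/dt, ds/dt) in mV/ms, pA/ms and 1/ms.

    Raises
    ------
    ValueError
        If any state component or ``I_syn`` is non-finite.
    """
    V, w, s = state.V, state.w, state.s
    if not (math.isfinite(V) and math.isfinite(w) and math.isfinite(s) and math.isfinite(I_syn)):
        raise ValueError(f"non-finite neuron state: V={V}, w={w}, s={s}, I_syn={I_syn}")
    p = params
    arg = min((V - p.V_T) / p.Delta_T, EXP_ARG_MAX)
    dV = (-p.g_L * (V - p.E_L) + p.g_L * p.Delta_T * math.exp(arg) - w + p.I_const + I_syn) / p.C_m
    dw = (p.a * (V - p.E_L) - w) / p.tau_w
    ds = -s / p.tau_s
    return dV, dw, ds


def apply_threshold_reset(
    state: NeuronState, params: NeuronParams
) -> tuple[NeuronState, bool]:
    """Detect a threshold crossing and apply the reset rules.

    If ``V > V_thres`` the neuron spiked: V is reset to ``V_r``, the
    adaptation current is incremented by ``b`` and the synaptic trace by
    one.  Otherwise the state is returned unchanged.  Because
    ``V_r < V_thres`` the operation is idempotent: a second application
    immediately after a reset is a no-op.
    """
    if state.V > params.V_thres:
        return NeuronState(V=params.V_r, w=state.w + params.b, s=state.s + 1.0), True
    return state, False
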