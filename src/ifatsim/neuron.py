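"""Two-compartment conductance-based integrate-and-fire neuron.

The neuron emulated here has a *distal* and a *proximal* compartment, each a
leaky RC membrane carrying two first-order conductance synapses, coupled by a
configurable conductance.  A spike is generated when the proximal membrane
voltage crosses threshold; the proximal voltage is then reset while the distal
compartment and all synaptic conductances are untouched.

Synaptic strength arrives as an 8-bit code split into a 4-bit mantissa ``W``
(pulse width) and a 4-bit exponent ``A`` (pulse amplitude); one input event
steps the addressed synapse's conductance by

    dG = g0 * (1 + W/16) * 2**A

which spans more than three decades of dynamic range across the 256 codes.
The drive pulse itself is collapsed into this instantaneous step; between
events conductances decay exponentially with their synaptic time constants
and the membrane voltages follow the piecewise-linear compartment dynamics.

All quantities are SI internally (volts, siemens, farads, seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "StrengthCode",
    "SynapseParams",
    "CompartmentParams",
    "NeuronParams",
    "NeuronState",
    "decode_strength",
    "conductance_step",
    "decay_conductances",
    "apply_synaptic_event",
    "integrate_step",
    "fire_and_reset",
]

#: Synapse indices 0 and 1 live on the distal compartment, 2 and 3 proximal.
DISTAL_SYNAPSES = (0, 1)
PROXIMAL_SYNAPSES = (2, 3)


@dataclass(frozen=True)
class StrengthCode:
    """8-bit synaptic strength: 4-bit mantissa ``W`` + 4-bit exponent ``A``.

    ``byte = 16*A + W``; W is the pulse-width mantissa (the four LSBs) and A
    the pulse-amplitude exponent (the four MSBs).
    """

    W: int
    A: int

    def __post_init__(self) -> None:
        if not (0 <= self.W <= 15 and 0 <= self.A <= 15):
            raise ValueError(f"W and A must be 4-bit values, got W={self.W}, A={self.A}")

    @property
    def byte(self) -> int:
        return 16 * self.A + self.W


def decode_strength(byte: int) -> StrengthCode:
    """Split an 8-bit strength code into mantissa (LSBs) and exponent (MSBs)."""
    byte = int(byte)
    if not 0 <= byte <= 255:
        raise ValueError(f"strength byte out of range [0, 255]: {byte}")
    return StrengthCode(W=byte % 16, A=byte // 16)


def conductance_step(code: StrengthCode, g0: float) -> float:
    """Conductance increment dG = g0 * (1 + W/16) * 2**A for one input event.

    ``g0`` is the conductance-step quantum (siemens) that folds the physical
    pulse prefactor into a single constant.
    """
    if g0 <= 0:
        raise ValueError(f"g0 must be positive, got {g0}")
    return g0 * (1.0 + code.W / 16.0) * float(2 ** code.A)


@dataclass(frozen=True)
class SynapseParams:
    """One first-order conductance synapse.

    E_rev sets the synapse type: above threshold it is excitatory, at or near
    the leak potential it is shunting/inhibitory.
    """

    syn_index: int          # 0,1 distal; 2,3 proximal
    E_rev: float            # reversal potential, V
    tau_syn: float          # conductance decay time constant, s
    g0: float               # conductance-step quantum, S

    def __post_init__(self) -> None:
        if not 0 <= self.syn_index <= 3:
            raise ValueError(f"syn_index must be 0-3, got {self.syn_index}")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.g0 <= 0:
            raise ValueError("g0 must be positive")


@dataclass(frozen=True)
class CompartmentParams:
    C_mem: float            # membrane capacitance, F
    G_leak: float           # leak conductance, S
    E_leak: float           # leak reversal potential, V

    def __post_init__(self) -> None:
        if self.C_mem <= 0:
            raise ValueError("C_mem must be positive")
        if self.G_leak < 0:
            raise ValueError("G_leak must be non-negative")


def _default_synapses() -> tuple[SynapseParams, ...]:
    # 0: distal excitatory, 1: distal shunting, 2: proximal excitatory,
    # 3: proximal shunting.  Shunting reversal sits at the leak potential.
    return (
        SynapseParams(0, 1.0, 5e-3, 1e-12),
        SynapseParams(1, 0.0, 5e-3, 1e-12),
        SynapseParams(2, 1.0, 5e-3, 1e-12),
        SynapseParams(3, 0.0, 5e-3, 1e-12),
    )


@dataclass(frozen=True)
class NeuronParams:
    """Full parameter set of one two-compartment neuron.

    Defaults give a 20 ms membrane (1 pF / 50 pS), unit excitatory reversal,
    0.5 V threshold with reset to rest, and a 100 us refractory dead time
    modelling the axon-hillock reset; at maximal synaptic strength this makes
    the neuron emit exactly one spike per input event up to 10 kHz, the
    regime where the response gain saturates at one.
    """

    distal: CompartmentParams = CompartmentParams(1e-12, 50e-12, 0.0)
    proximal: CompartmentParams = CompartmentParams(1e-12, 50e-12, 0.0)
    G_comp: float = 0.5e-9          # inter-compartment coupling, S
    V_thresh: float = 0.5           # firing threshold, V
    V_reset: float = 0.0            # post-spike proximal voltage, V
    t_refr: float = 100e-6          # refractory period, s
    synapses: tuple[SynapseParams, ...] = field(default_factory=_default_synapses)

    def __post_init__(self) -> None:
        if self.G_comp < 0:
            raise ValueError("G_comp must be non-negative")
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must be below V_thresh")
        if self.t_refr < 0:
            raise ValueError("t_refr must be non-negative")
        if len(self.synapses) != 4:
            raise ValueError("a neuron has exactly four synapses")
        for i, s in enumerate(self.synapses):
            if s.syn_index != i:
                raise ValueError("synapses must be ordered by syn_index 0-3")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state: two voltages, four conductances, bookkeeping times."""

    V_mem0: float = 0.0             # distal voltage, V
    V_mem1: float = 0.0             # proximal voltage, V
    G_syn: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    t_last: float = 0.0             # time of last state update, s
    t_refr_until: float = 0.0       # end of refractory lockout, s

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.G_syn):
            raise ValueError("conductances must be non-negative")
        if not (math.isfinite(self.V_mem0) and math.isfinite(self.V_mem1)):
            raise ValueError("voltages must be finite")


def decay_conductances(state: NeuronState, dt: float, params: NeuronParams) -> NeuronState:
    """Analytic exponential decay of all four synaptic conductances over ``dt``."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if dt == 0.0:
        return state
    g = tuple(
        gj * math.exp(-dt / params.synapses[j].tau_syn)
        for j, gj in enumerate(state.G_syn)
    )
    return replace(state, G_syn=g, t_last=state.t_last + dt)


def apply_synaptic_event(
    state: NeuronState, syn_index: int, byte: int, params: NeuronParams
) -> NeuronState:
    """Instantaneous conductance step on one synapse from an 8-bit strength code."""
    if not 0 <= syn_index <= 3:
        raise ValueError(f"syn_index must be 0-3, got {syn_index}")
    dg = conductance_step(decode_strength(byte), params.synapses[syn_index].g0)
    g = list(state.G_syn)
    g[syn_index] += dg
    return replace(state, G_syn=tuple(g))


def integrate_step(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Advance both compartment voltages one exponential-Euler step of ``dt``.

    Conductances and the opposite compartment's voltage are frozen at their
    start-of-step values, so each compartment relaxes exponentially toward its
    instantaneous equilibrium.  The update is a convex combination of the old
    voltage and that equilibrium, which keeps voltages inside the convex hull
    of the reversal potentials, leak potentials, and initial values.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    syn = params.synapses
    g = state.G_syn

    # distal (compartment 0): synapses 0,1 + leak + coupling toward V_mem1
    num0 = (
        g[0] * syn[0].E_rev
        + g[1] * syn[1].E_rev
        + params.distal.G_leak * params.distal.E_leak
        + params.G_comp * state.V_mem1
    )
    den0 = g[0] + g[1] + params.distal.G_leak + params.G_comp
    # proximal (compartment 1): synapses 2,3 + leak + coupling toward V_mem0
    num1 = (
        g[2] * syn[2].E_rev
        + g[3] * syn[3].E_rev
        + params.proximal.G_leak * params.proximal.E_leak
        + params.G_comp * state.V_mem0
    )
    den1 = g[2] + g[3] + params.proximal.G_leak + params.G_comp

    if den0 > 0:
        v_inf0 = num0 / den0
        a0 = math.exp(-den0 * dt / params.distal.C_mem)
        v0 = v_inf0 + (state.V_mem0 - v_inf0) * a0
    else:
        v0 = state.V_mem0
    if den1 > 0:
        v_inf1 = num1 / den1
        a1 = math.exp(-den1 * dt / params.proximal.C_mem)
        v1 = v_inf1 + (state.V_mem1 - v_inf1) * a1
    else:
        v1 = state.V_mem1

    return replace(state, V_mem0=v0, V_mem1=v1, t_last=state.t_last + dt)


# Tolerance on refractory-lockout comparisons: substep times accumulate
# O(1e-16) float error per addition and the lockout boundary must not slip
# by a whole substep because of it.
_REFR_EPS = 1e-12


def fire_and_reset(
    state: NeuronState, params: NeuronParams, t: float
) -> tuple[NeuronState, float | None]:
    """Threshold test at time ``t``; on a spike, reset the proximal voltage.

    Returns ``(new_state, spike_time)`` with ``spike_time is None`` when no
    spike was emitted (subthreshold or refractory lockout).
    """
    if state.V_mem1 >= params.V_thresh and t >= state.t_refr_until - _REFR_EPS:
        new = replace(state, V_mem1=params.V_reset, t_refr_until=t + params.t_refr)
        return new, t
    return state, None
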