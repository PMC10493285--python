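"""Event-driven network simulation.

The engine combines the neuron dynamics with the AER fabric: external input
events and routed recurrent events sit in a priority queue; between events
an active neuron's conductances decay analytically and its membrane
voltages advance in substeps no longer than ``dt``.  Within a substep the
conductances are frozen at their midpoint values and the resulting linear
two-compartment system is propagated by its closed-form solution, so
threshold-crossing (spike) times are resolved to much better than ``dt``.
Fired spikes are fanned out through the routing table and re-enqueued, so
virtual wiring and recurrence come for free.

Neuron ids are global within a quadrant: ``id = core * 2048 + neuron``.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aer import InputEvent, NEURONS_PER_CORE, RoutingTable, route_spike
from .neuron import NeuronParams, NeuronState, apply_synaptic_event

__all__ = [
    "SpikeTrain",
    "SimulationResult",
    "gen_spike_train",
    "run_simulation",
    "measure_activation",
    "events_from_train",
]

DEFAULT_DT = 10e-6        # spike-time resolution of the engine, s
DEFAULT_BURN_IN = 0.1     # transient discarded in rate measurements, s
PROBE_INTERVAL = 1e-4     # voltage/conductance trace sampling interval, s

# A neuron is put to sleep once its synaptic drive and its distance from the
# leak equilibrium are both negligible on the scale of the dynamics.
_G_SLEEP = 1e-15          # S
_V_SLEEP = 1e-6           # V

# Slack on time comparisons: substep boundaries accumulate float error and a
# refractory expiry must not slip past a boundary because of it.
_T_EPS = 1e-12            # s


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one source."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)


def gen_spike_train(
    kind: str, rate: float, duration: float, seed: int | np.random.Generator = 0
) -> SpikeTrain:
    """Seeded spike-train generator.

    ``regular`` trains are equally spaced at 1/rate starting at 1/rate;
    ``poisson`` trains have i.i.d. exponential inter-spike intervals with
    mean 1/rate (a homogeneous Poisson process), reproducible under a fixed
    seed.  A zero rate yields an empty train.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if rate == 0:
        return SpikeTrain(np.empty(0), label=kind)
    if kind == "regular":
        n = int(math.floor(rate * duration + 1e-9))
        times = np.arange(1, n + 1) / rate
    elif kind == "poisson":
        rng = np.random.default_rng(seed)
        # draw in chunks until past the duration
        times = np.empty(0)
        t_end = 0.0
        while t_end <= duration:
            chunk = rng.exponential(1.0 / rate, size=max(16, int(rate * duration * 0.5) + 16))
            times = np.concatenate([times, chunk])
            t_end = times.sum() if len(times) else 0.0
            if len(times) > 1e8:  # pragma: no cover - pathological rates
                raise RuntimeError("spike train generation runaway")
        times = np.cumsum(times)
        times = times[times <= duration]
    else:
        raise ValueError(f"unknown spike train kind: {kind!r}")
    return SpikeTrain(times, label=kind)


def events_from_train(
    train: SpikeTrain, core: int, neuron: int, syn_type: int, strength: int
) -> list[InputEvent]:
    """Address every spike of a train to one synapse as input events."""
    return [InputEvent(float(t), core, neuron, syn_type, strength) for t in train.times]


@dataclass
class SimulationResult:
    """Output spikes and optional probe traces of one run."""

    spikes: list[tuple[int, float]]                   # (global neuron id, time)
    traces: dict[int, np.ndarray] = field(default_factory=dict)
    duration: float = 0.0

    def spike_times(self, neuron_id: int) -> np.ndarray:
        return np.asarray([t for n, t in self.spikes if n == neuron_id])

    def rate(self, neuron_id: int, t_start: float = 0.0, t_stop: float | None = None) -> float:
        """Mean firing rate of one neuron over (t_start, t_stop]."""
        t_stop = self.duration if t_stop is None else t_stop
        times = self.spike_times(neuron_id)
        n = int(np.sum((times > t_start) & (times <= t_stop)))
        return n / (t_stop - t_start)


class _FrozenPropagator:
    """Closed-form solution of the two-compartment system over one substep.

    With conductances frozen the system is linear time-invariant,
    ``dV/dt = A V + b`` with a 2x2 compartmental matrix whose eigenvalues
    are real and non-positive, so the voltages are sums of at most two
    exponentials around the steady state.  This gives exact substep
    voltages and lets the proximal threshold crossing be located to
    floating-point precision by monotone-segment bisection.
    """

    __slots__ = ("mode", "vi0", "vi1", "k0", "k1", "v0_0", "v1_0",
                 "vss0", "vss1", "l1", "l2", "c1_0", "c2_0", "c1_1", "c2_1",
                 "lam", "w0", "w1", "d0_1", "d1_1")

    def __init__(self, p: NeuronParams, g: Sequence[float], v0: float, v1: float):
        syn = p.synapses
        C0, C1, gc = p.distal.C_mem, p.proximal.C_mem, p.G_comp
        b0 = g[0] * syn[0].E_rev + g[1] * syn[1].E_rev + p.distal.G_leak * p.distal.E_leak
        d0 = g[0] + g[1] + p.distal.G_leak + gc
        b1 = g[2] * syn[2].E_rev + g[3] * syn[3].E_rev + p.proximal.G_leak * p.proximal.E_leak
        d1 = g[2] + g[3] + p.proximal.G_leak + gc
        self.v0_0, self.v1_0 = v0, v1
        if gc == 0.0:
            self.mode = "decoupled"
            self.k0 = d0 / C0
            self.k1 = d1 / C1
            self.vi0 = b0 / d0 if d0 > 0 else v0
            self.vi1 = b1 / d1 if d1 > 0 else v1
            return
        a00, a01 = -d0 / C0, gc / C0
        a10, a11 = gc / C1, -d1 / C1
        det = a00 * a11 - a01 * a10
        r0, r1 = b0 / C0, b1 / C1
        if det != 0.0:
            self.vss0 = (-a11 * r0 + a01 * r1) / det
            self.vss1 = (a10 * r0 - a00 * r1) / det
        else:   # no leak path anywhere: pure charge sharing
            self.vss0, self.vss1 = v0, v1
        tr = a00 + a11
        s = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
        w0, w1 = v0 - self.vss0, v1 - self.vss1
        if s > 1e-9 * abs(tr):
            self.mode = "coupled"
            l1, l2 = 0.5 * (tr + s), 0.5 * (tr - s)
            inv = 1.0 / (l1 - l2)
            self.c1_0 = ((a00 - l2) * w0 + a01 * w1) * inv
            self.c2_0 = w0 - self.c1_0
            self.c1_1 = (a10 * w0 + (a11 - l2) * w1) * inv
            self.c2_1 = w1 - self.c1_1
            self.l1, self.l2 = l1, l2
        else:   # (near-)repeated eigenvalue: e^{At} = e^{lt}(I + (A-lI)t)
            self.mode = "degenerate"
            lam = 0.5 * tr
            self.lam = lam
            self.w0, self.w1 = w0, w1
            self.d0_1 = (a00 - lam) * w0 + a01 * w1   # d/dt coefficient, v0
            self.d1_1 = a10 * w0 + (a11 - lam) * w1   # d/dt coefficient, v1

    def eval(self, t: float) -> tuple[float, float]:
        if self.mode == "decoupled":
            v0 = self.vi0 + (self.v0_0 - self.vi0) * math.exp(-self.k0 * t)
            v1 = self.vi1 + (self.v1_0 - self.vi1) * math.exp(-self.k1 * t)
            return v0, v1
        if self.mode == "coupled":
            e1, e2 = math.exp(self.l1 * t), math.exp(self.l2 * t)
            return (self.vss0 + self.c1_0 * e1 + self.c2_0 * e2,
                    self.vss1 + self.c1_1 * e1 + self.c2_1 * e2)
        e = math.exp(self.lam * t)
        return (self.vss0 + e * (self.w0 + self.d0_1 * t),
                self.vss1 + e * (self.w1 + self.d1_1 * t))

    def _v1(self, t: float) -> float:
        return self.eval(t)[1]

    def _extremum(self, lo: float, hi: float) -> float | None:
        """Time of the (single) interior extremum of v1, if inside (lo, hi)."""
        if self.mode == "decoupled":
            return None
        if self.mode == "coupled":
            a, b = self.c1_1 * self.l1, self.c2_1 * self.l2
            if a == 0.0 or b == 0.0 or (a > 0) == (b > 0):
                return None
            t = math.log(-b / a) / (self.l1 - self.l2)
        else:
            if self.lam == 0.0 or self.d1_1 == 0.0:
                return None
            t = -(self.lam * self.w1 + self.d1_1) / (self.lam * self.d1_1)
        return t if lo < t < hi else None

    def first_crossing(self, theta: float, rem: float, t_lo: float = 0.0) -> float | None:
        """Earliest t in [t_lo, rem] where v1 reaches ``theta`` from below.

        Returns the crossing time (0 if already at/above threshold at
        ``t_lo``) or None when the threshold is not reached in the window.
        """
        v_lo = self._v1(t_lo) if t_lo > 0.0 else self.v1_0
        if v_lo >= theta:
            return t_lo
        bounds = [t_lo]
        t_ext = self._extremum(t_lo, rem)
        if t_ext is not None:
            bounds.append(t_ext)
        bounds.append(rem)
        for a, b in zip(bounds, bounds[1:]):
            va, vb = self._v1(a), self._v1(b)
            if va < theta <= vb:
                for _ in range(60):       # monotone-segment bisection
                    m = 0.5 * (a + b)
                    if self._v1(m) >= theta:
                        b = m
                    else:
                        a = m
                return b
            if vb >= theta:               # non-monotone edge case
                return b
        return None


class _Neuron:
    """Mutable per-neuron bookkeeping inside the engine."""

    __slots__ = ("state", "params", "next_wake", "eq0", "eq1")

    def __init__(self, params: NeuronParams, t: float):
        self.state = NeuronState(
            V_mem0=_leak_eq(params)[0], V_mem1=_leak_eq(params)[1], t_last=t
        )
        self.params = params
        self.next_wake: float | None = None
        self.eq0, self.eq1 = _leak_eq(params)


def _leak_eq(params: NeuronParams) -> tuple[float, float]:
    """Leak-only steady state of the coupled two-compartment system."""
    gl0, gl1, gc = params.distal.G_leak, params.proximal.G_leak, params.G_comp
    e0, e1 = params.distal.E_leak, params.proximal.E_leak
    # (gl0+gc) V0 - gc V1 = gl0 e0 ; -gc V0 + (gl1+gc) V1 = gl1 e1
    det = (gl0 + gc) * (gl1 + gc) - gc * gc
    if det == 0:
        return e0, e1
    v0 = ((gl1 + gc) * gl0 * e0 + gc * gl1 * e1) / det
    v1 = ((gl0 + gc) * gl1 * e1 + gc * gl0 * e0) / det
    return v0, v1


def run_simulation(
    params: NeuronParams | Mapping[int, NeuronParams],
    table: RoutingTable | None,
    external: Sequence[InputEvent],
    duration: float,
    dt: float = DEFAULT_DT,
    *,
    axonal_delay: float = 0.0,
    probes: Sequence[int] = (),
    probe_interval: float = PROBE_INTERVAL,
    mismatch=None,
) -> SimulationResult:
    """Run the event-driven engine for ``duration`` seconds.

    ``params`` is either one parameter set shared by all neurons or a mapping
    from global neuron id to parameters.  ``mismatch``, when given, must
    expose ``conductance_step(neuron_id, byte, g0) -> float`` and replaces
    the ideal PWAM conductance step per neuron (used for calibration
    studies).  The run is deterministic for fixed inputs.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    table = table if table is not None else RoutingTable()

    ext = list(external)
    ts = [e.t for e in ext]
    if any(t1 < t0 for t0, t1 in zip(ts, ts[1:])):
        raise ValueError("external events must be time-sorted")
    n_late = sum(1 for e in ext if e.t > duration)
    if n_late:
        warnings.warn(f"ignoring {n_late} external events beyond duration")
        ext = [e for e in ext if e.t <= duration]

    neurons: dict[int, _Neuron] = {}

    def get(nid: int) -> _Neuron:
        nrn = neurons.get(nid)
        if nrn is None:
            p = params[nid] if isinstance(params, Mapping) else params
            nrn = _Neuron(p, 0.0)
            neurons[nid] = nrn
        return nrn

    spikes: list[tuple[int, float]] = []
    trace_buf: dict[int, list[tuple]] = {nid: [] for nid in probes}
    next_sample: dict[int, float] = {nid: 0.0 for nid in probes}

    # Heap entries: (t, seq, kind, payload). kind 0 = external/routed input
    # event, kind 1 = wake (continue stepping an active neuron).
    heap: list = []
    seq = 0
    for e in ext:
        heap.append((e.t, seq, 0, e))
        seq += 1
    heapq.heapify(heap)

    def sample(nid: int, nrn: _Neuron, t: float) -> None:
        while nid in next_sample and t >= next_sample[nid] - 1e-12:
            s = nrn.state
            trace_buf[nid].append(
                (next_sample[nid], s.V_mem0, s.V_mem1, *s.G_syn)
            )
            next_sample[nid] += probe_interval

    def emit(nid: int, t_fire: float) -> None:
        nonlocal seq
        spikes.append((nid, t_fire))
        for ev in route_spike(table, nid, t_fire, axonal_delay):
            if ev.t <= duration:
                heapq.heappush(heap, (ev.t, seq, 0, ev))
                seq += 1

    def substep(nid: int, nrn: _Neuron, t_start: float, t_end: float) -> None:
        """One substep with midpoint-frozen conductances and exact voltages.

        Conductances are evaluated at the substep midpoint (second-order
        accurate for the exponentially decaying drive) and frozen; the
        resulting two-compartment system is linear time-invariant, so both
        voltages are propagated by its closed-form solution and the proximal
        threshold-crossing time is located exactly (within the scheme).  A
        neuron held above threshold by the refractory lockout fires exactly
        at lockout expiry.
        """
        p = nrn.params
        st = nrn.state
        h = t_end - t_start
        g_mid = [gj * math.exp(-0.5 * h / p.synapses[j].tau_syn)
                 for j, gj in enumerate(st.G_syn)]
        v0, v1 = st.V_mem0, st.V_mem1
        refr = st.t_refr_until
        t_cur = t_start
        while True:
            prop = _FrozenPropagator(p, g_mid, v0, v1)
            rem = t_end - t_cur
            t_cross = prop.first_crossing(p.V_thresh, rem)
            if t_cross is None:
                v0, v1 = prop.eval(rem)
                break
            t_fire = t_cur + t_cross
            if refr > t_fire:
                # locked out at the crossing: fire at expiry if still above
                # threshold there, otherwise look for the next crossing
                if refr > t_end + _T_EPS:
                    v0, v1 = prop.eval(rem)
                    break
                v_at = prop.eval(refr - t_cur)[1]
                if v_at >= p.V_thresh - 1e-15:
                    t_fire = refr
                else:
                    later = prop.first_crossing(p.V_thresh, rem,
                                                t_lo=refr - t_cur)
                    if later is None:
                        v0, v1 = prop.eval(rem)
                        break
                    t_fire = t_cur + later
            if t_fire > t_end + _T_EPS:
                v0, v1 = prop.eval(rem)
                break
            emit(nid, t_fire)
            v0 = prop.eval(t_fire - t_cur)[0]
            v1 = p.V_reset
            refr = t_fire + p.t_refr
            t_cur = t_fire
        nrn.state = NeuronState(v0, v1, tuple(
            gj * math.exp(-h / p.synapses[j].tau_syn) for j, gj in enumerate(st.G_syn)
        ), t_end, refr)

    def advance(nid: int, nrn: _Neuron, t: float) -> None:
        """Step neuron from its t_last to t, firing and routing on the way."""
        t0 = nrn.state.t_last
        if t <= t0 + 1e-15:
            return
        n_steps = max(1, int(math.ceil((t - t0) / dt - 1e-9)))
        h = (t - t0) / n_steps
        for k in range(n_steps):
            t_sub = t if k == n_steps - 1 else t0 + (k + 1) * h
            substep(nid, nrn, t0 + k * h, t_sub)
            if nid in next_sample:
                sample(nid, nrn, t_sub)

    def active(nrn: _Neuron) -> bool:
        s = nrn.state
        return (
            max(s.G_syn) > _G_SLEEP
            or abs(s.V_mem0 - nrn.eq0) > _V_SLEEP
            or abs(s.V_mem1 - nrn.eq1) > _V_SLEEP
            or s.t_refr_until > s.t_last
        )

    def ensure_wake(nid: int, nrn: _Neuron, t: float) -> None:
        nonlocal seq
        tw = t + dt
        if tw <= duration + dt and (nrn.next_wake is None or tw < nrn.next_wake - 1e-15):
            nrn.next_wake = tw
            heapq.heappush(heap, (tw, seq, 1, nid))
            seq += 1

    # probed neurons stay on the sampling grid even when idle
    for nid in probes:
        nrn = get(nid)
        sample(nid, nrn, 0.0)
        ensure_wake(nid, nrn, 0.0)

    while heap:
        t, _, kind, payload = heapq.heappop(heap)
        if t > duration + 1e-12:
            break
        if kind == 0:
            e: InputEvent = payload
            nid = e.core * NEURONS_PER_CORE + e.neuron
            nrn = get(nid)
            advance(nid, nrn, t)
            if mismatch is not None:
                g0 = nrn.params.synapses[e.syn_type].g0
                dg = mismatch.conductance_step(nid, e.strength, g0)
                g = list(nrn.state.G_syn)
                g[e.syn_type] += dg
                nrn.state = NeuronState(
                    nrn.state.V_mem0, nrn.state.V_mem1, tuple(g),
                    nrn.state.t_last, nrn.state.t_refr_until,
                )
            else:
                nrn.state = apply_synaptic_event(nrn.state, e.syn_type, e.strength, nrn.params)
            ensure_wake(nid, nrn, t)
        else:
            nid = payload
            nrn = neurons[nid]
            if nrn.next_wake is not None and t >= nrn.next_wake - 1e-15:
                nrn.next_wake = None
            advance(nid, nrn, t)
            if active(nrn) or nid in next_sample:
                ensure_wake(nid, nrn, t)

    # settle every touched neuron to the end of the run
    for nid, nrn in neurons.items():
        advance(nid, nrn, duration)

    traces = {
        nid: np.asarray(buf, dtype=float) for nid, buf in trace_buf.items()
    }
    return SimulationResult(spikes=spikes, traces=traces, duration=duration)


def measure_activation(
    params: NeuronParams,
    kind: str,
    rates: Sequence[float],
    strength: int,
    duration: float = 1.0,
    seed: int = 0,
    *,
    syn_index: int = 2,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
) -> list[tuple[float, float]]:
    """Measure the activation function: output rate vs input rate.

    One single-neuron simulation per input rate; spikes are counted over the
    window ``(burn_in, burn_in + duration]`` to discard the onset transient,
    and the output rate is that count divided by ``duration``.
    """
    out: list[tuple[float, float]] = []
    total = burn_in + duration
    for i, f_in in enumerate(rates):
        train = gen_spike_train(kind, f_in, total, seed=seed + i)
        events = events_from_train(train, core=0, neuron=0, syn_type=syn_index,
                                   strength=strength)
        res = run_simulation(params, None, events, total, dt=dt)
        out.append((float(f_in), res.rate(0, t_start=burn_in, t_stop=total)))
    return out
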