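"""Independent brute-force oracles used only by the tests.

These deliberately re-derive behaviour through different algorithms than the
package: a dense fixed-step integrator for the neuron network (no event
queue, no analytic inter-event shortcuts beyond the per-step update) and a
time-quantized state machine for the pipeline front end.
"""

from __future__ import annotations

import math

import numpy as np


def dense_network_sim(params_of, table, external, duration, h, axonal_delay=0.0):
    """Fixed-step network simulation at step ``h``; returns [(nid, t), ...].

    Every neuron is stepped on the same dense global grid; events are applied
    at the first grid point at/after their timestamp; spikes fan out through
    the routing table immediately (plus delay) and are applied on the grid.
    """
    n_steps = int(round(duration / h))
    # pending[k] = list of (nid, syn, byte) applied at step k
    pending: dict[int, list] = {}

    def schedule(t, core, neuron, syn, byte):
        k = int(math.ceil(t / h - 1e-9))
        pending.setdefault(k, []).append((core * 2048 + neuron, syn, byte))

    for e in external:
        schedule(e.t, e.core, e.neuron, e.syn_type, e.strength)

    nids = set(core * 2048 + neuron for (core, neuron) in (
        (e.core, e.neuron) for e in external))
    for pre, entries in table.items():
        nids.add(pre)
        for en in entries:
            nids.add(en.core * 2048 + en.neuron)
    nids = sorted(nids)

    state = {}
    for nid in nids:
        p = params_of(nid)
        state[nid] = {
            "p": p, "v0": 0.0, "v1": 0.0, "g": [0.0, 0.0, 0.0, 0.0],
            "refr": 0.0,
        }

    spikes = []
    for k in range(n_steps + 1):
        t = k * h
        for (nid, syn, byte) in pending.get(k, ()):
            p = state[nid]["p"]
            W, A = byte % 16, byte // 16
            state[nid]["g"][syn] += p.synapses[syn].g0 * (1 + W / 16) * 2 ** A
        if k == n_steps:
            break
        t_next = (k + 1) * h
        for nid in nids:
            s = state[nid]
            p = s["p"]
            g = s["g"]
            gm = [g[j] * math.exp(-0.5 * h / p.synapses[j].tau_syn)
                  for j in range(4)]   # midpoint conductances
            num0 = (gm[0] * p.synapses[0].E_rev + gm[1] * p.synapses[1].E_rev
                    + p.distal.G_leak * p.distal.E_leak + p.G_comp * s["v1"])
            den0 = gm[0] + gm[1] + p.distal.G_leak + p.G_comp
            num1 = (gm[2] * p.synapses[2].E_rev + gm[3] * p.synapses[3].E_rev
                    + p.proximal.G_leak * p.proximal.E_leak + p.G_comp * s["v0"])
            den1 = gm[2] + gm[3] + p.proximal.G_leak + p.G_comp
            v0, v1 = s["v0"], s["v1"]
            if den0 > 0:
                vi = num0 / den0
                v0 = vi + (v0 - vi) * math.exp(-den0 * h / p.distal.C_mem)
            if den1 > 0:
                vi = num1 / den1
                v1_prev = v1
                v1 = vi + (v1 - vi) * math.exp(-den1 * h / p.proximal.C_mem)
                # threshold crossing resolved by linear interpolation inside
                # the step; a neuron held up by the lockout fires at expiry
                if v1 >= p.V_thresh or v1_prev >= p.V_thresh:
                    if v1_prev >= p.V_thresh:
                        t_cross = t
                    else:
                        frac = (p.V_thresh - v1_prev) / (v1 - v1_prev)
                        t_cross = t + frac * h
                    t_fire = max(t_cross, s["refr"])
                    if t_fire <= t_next + 1e-15:
                        spikes.append((nid, t_fire))
                        s["refr"] = t_fire + p.t_refr
                        # integrate the post-reset remainder of the step
                        rem = t_next - t_fire
                        v1 = vi + (p.V_reset - vi) * math.exp(
                            -den1 * rem / p.proximal.C_mem)
                        for en in table.fan_out(nid):
                            if t_fire + axonal_delay <= duration:
                                schedule(t_fire + axonal_delay, en.core,
                                         en.neuron, en.syn_type, en.strength)
            s["v0"], s["v1"] = v0, v1
            for j in range(4):
                g[j] *= math.exp(-h / p.synapses[j].tau_syn)
    return spikes


def quantized_pipeline_sim(events, T_latency, dt_pulse_base, row_count, tick):
    """Time-quantized front-end + row-lock state machine.

    Advances a clock in ``tick`` quanta.  The head-of-line event starts its
    handshake only when the front end is idle and its row is free; the
    handshake lasts T_latency, then the pulse occupies the row.  Returns
    (service_start, pulse_end) arrays.  For exactness the tick must divide
    T_latency, the possible pulse widths (multiples of dt_pulse_base/16) and
    every arrival time.
    """
    n = len(events)
    starts = np.full(n, np.nan)
    ends = np.full(n, np.nan)
    row_busy_until = np.zeros(row_count)
    head = 0
    k = 0
    frontend_busy_until = 0.0
    while head < n:
        t = k * tick
        e = events[head]
        width = dt_pulse_base * (1 + (e.strength % 16) / 16)
        if (e.t <= t + 1e-15 and frontend_busy_until <= t + 1e-15
                and row_busy_until[e.row] <= t + 1e-15):
            starts[head] = t
            frontend_busy_until = t + T_latency
            row_busy_until[e.row] = t + T_latency + width
            ends[head] = t + T_latency + width
            head += 1
        else:
            k += 1
    return starts, ends
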