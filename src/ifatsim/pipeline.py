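"""Two-tier micro-pipeline service model of one 2k-neuron core.

The front end admits input address events serially: each handshake takes
``T_latency``, and an event addressed to a row whose pulse-width/amplitude
(PWAM) circuit is still busy is not acknowledged until the row frees — the
blocked head-of-line event stalls everything behind it (in-order,
non-preemptive).  Once delivered, an event occupies its row's PWAM circuit
for the pulse width ``dt_pulse_base * (1 + W/16)`` set by its 4-bit mantissa.

Under a saturated single-row workload every event waits out the previous
pulse, giving a service period of ``T_latency + pulse_width`` and hence a
throughput of ``1 / (T_latency + T_wait)``; interleaving events over many
rows hides the pulse occupancy behind the handshakes and the throughput
climbs toward ``1 / T_latency``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aer import InputEvent, ROWS_PER_CORE

__all__ = ["TimingParams", "ServiceTrace", "pulse_width", "schedule_deliveries",
           "throughput_estimate"]


@dataclass(frozen=True)
class TimingParams:
    """Handshake latency and PWAM pulse-width base of the pipeline model.

    Hardware values are free parameters here; the defaults (50 ns handshake,
    10 us base pulse) put the two tiers on the scales where row interleaving
    visibly matters.
    """

    T_latency: float = 50e-9        # per-event handshake latency, s
    dt_pulse_base: float = 10e-6    # pulse width at W = 0, s
    row_count: int = ROWS_PER_CORE

    def __post_init__(self) -> None:
        if self.T_latency <= 0:
            raise ValueError("T_latency must be positive")
        if self.dt_pulse_base < 0:
            raise ValueError("dt_pulse_base must be non-negative")


def pulse_width(W: int, p: TimingParams) -> float:
    """PWAM pulse width dt = dt_pulse_base * (1 + W/16) for mantissa ``W``."""
    if not 0 <= int(W) <= 15:
        raise ValueError(f"mantissa W out of range [0, 15]: {W}")
    return p.dt_pulse_base * (1.0 + int(W) / 16.0)


@dataclass
class ServiceTrace:
    """Per-event service record of one scheduled stream (parallel arrays)."""

    arrival: np.ndarray        # event arrival at the front end, s
    row: np.ndarray            # target row
    service_start: np.ndarray  # handshake start (front end begins serving), s
    pulse_start: np.ndarray    # delivery to the row's PWAM circuit, s
    service_end: np.ndarray    # end of the row pulse, s

    def __len__(self) -> int:
        return len(self.arrival)


def schedule_deliveries(events: list[InputEvent], p: TimingParams) -> ServiceTrace:
    """Serve a time-sorted event stream through the two-tier pipeline.

    For each event in order: the handshake starts once the front end is free
    *and* the target row's PWAM circuit is idle (the unacknowledged event
    blocks the front end); it completes ``T_latency`` later, and the pulse
    then occupies the row for its PWAM width.
    """
    ts = [e.t for e in events]
    if any(t1 < t0 for t0, t1 in zip(ts, ts[1:])):
        raise ValueError("event stream must be time-sorted")

    n = len(events)
    arrival = np.asarray(ts, dtype=float)
    rows = np.fromiter((e.row for e in events), dtype=np.int64, count=n)
    start = np.empty(n)
    pstart = np.empty(n)
    end = np.empty(n)

    row_free = np.zeros(p.row_count, dtype=float)
    frontend_free = 0.0
    for i, e in enumerate(events):
        if e.row >= p.row_count:
            raise ValueError(f"row {e.row} exceeds row_count {p.row_count}")
        width = pulse_width(e.strength % 16, p)
        s = max(arrival[i], frontend_free, row_free[e.row])
        d = s + p.T_latency            # handshake complete, pulse begins
        start[i] = s
        pstart[i] = d
        end[i] = d + width
        frontend_free = d
        row_free[e.row] = end[i]

    return ServiceTrace(arrival=arrival, row=rows, service_start=start,
                        pulse_start=pstart, service_end=end)


def throughput_estimate(trace: ServiceTrace) -> float:
    """Served events per second: N / (last service end - first arrival)."""
    if len(trace) == 0:
        raise ValueError("cannot estimate throughput of an empty trace")
    span = float(trace.service_end[-1] - trace.arrival[0])
    return len(trace) / span
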