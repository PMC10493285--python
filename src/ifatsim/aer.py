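"""Address-event representation (AER) fabric of one quadrant.

Spikes travel as address events: an input synaptic event is a 24-bit word
(3-bit destination core, 11-bit neuron address, 2-bit synapse type, 8-bit
strength); an output spike is a 14-bit word built by prepending one core bit
per merger stage to the 11-bit in-core neuron address.  Virtual wiring is a
routing table held outside the array that fans a presynaptic spike out into
input events for its postsynaptic targets.

The chip carries 4 independent quadrants x 8 cores x 2048 neurons
(64 rows x 32 columns per core) = 65,536 neurons, each with two compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "N_QUADRANTS",
    "CORES_PER_QUADRANT",
    "NEURONS_PER_CORE",
    "ROWS_PER_CORE",
    "COLS_PER_CORE",
    "TOTAL_NEURONS",
    "TOTAL_COMPARTMENTS",
    "INPUT_WORD_BITS",
    "OUTPUT_WORD_BITS",
    "InputEvent",
    "OutputEvent",
    "RoutingEntry",
    "RoutingTable",
    "pack_input_event",
    "unpack_input_event",
    "pack_output_event",
    "unpack_output_event",
    "route_spike",
    "split_to_cores",
    "arbitrate_merge",
]

N_QUADRANTS = 4
CORES_PER_QUADRANT = 8
NEURONS_PER_CORE = 2048
ROWS_PER_CORE = 64
COLS_PER_CORE = 32
TOTAL_NEURONS = N_QUADRANTS * CORES_PER_QUADRANT * NEURONS_PER_CORE   # 65,536
TOTAL_COMPARTMENTS = 2 * TOTAL_NEURONS                                # 131,072
INPUT_WORD_BITS = 24
OUTPUT_WORD_BITS = 14


@dataclass(frozen=True, order=True)
class InputEvent:
    """A timed, addressed synaptic stimulus carrying an 8-bit strength code."""

    t: float            # seconds
    core: int           # 0-7
    neuron: int         # 0-2047; row = neuron // 32, col = neuron % 32
    syn_type: int       # 0-3
    strength: int       # 0-255

    def __post_init__(self) -> None:
        _check_fields(self.core, self.neuron, self.syn_type, self.strength)

    @property
    def row(self) -> int:
        return self.neuron // COLS_PER_CORE

    @property
    def col(self) -> int:
        return self.neuron % COLS_PER_CORE


@dataclass(frozen=True, order=True)
class OutputEvent:
    """A fired spike on the quadrant output bus: 14-bit address (3 core + 11 neuron)."""

    t: float
    address: int

    def __post_init__(self) -> None:
        if not 0 <= self.address < 2 ** OUTPUT_WORD_BITS:
            raise ValueError(f"output address out of 14-bit range: {self.address}")

    @property
    def core(self) -> int:
        return self.address >> 11

    @property
    def neuron(self) -> int:
        return self.address & 0x7FF


@dataclass(frozen=True)
class RoutingEntry:
    core: int
    neuron: int
    syn_type: int
    strength: int

    def __post_init__(self) -> None:
        _check_fields(self.core, self.neuron, self.syn_type, self.strength)


def _check_fields(core: int, neuron: int, syn_type: int, strength: int) -> None:
    if not 0 <= core < CORES_PER_QUADRANT:
        raise ValueError(f"core out of range [0, 7]: {core}")
    if not 0 <= neuron < NEURONS_PER_CORE:
        raise ValueError(f"neuron out of range [0, 2047]: {neuron}")
    if not 0 <= syn_type <= 3:
        raise ValueError(f"syn_type out of range [0, 3]: {syn_type}")
    if not 0 <= strength <= 255:
        raise ValueError(f"strength out of range [0, 255]: {strength}")


class RoutingTable:
    """Virtual wiring: presynaptic global neuron id -> ordered fan-out entries."""

    def __init__(self, table: Mapping[int, Sequence[RoutingEntry]] | None = None):
        self._table: dict[int, list[RoutingEntry]] = {}
        if table:
            for pre_id, entries in table.items():
                self._table[int(pre_id)] = list(entries)

    def add(self, pre_id: int, entry: RoutingEntry) -> None:
        self._table.setdefault(int(pre_id), []).append(entry)

    def fan_out(self, pre_id: int) -> list[RoutingEntry]:
        return list(self._table.get(pre_id, []))

    def items(self):
        return self._table.items()

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, pre_id: int) -> bool:
        return pre_id in self._table

    def __eq__(self, other) -> bool:
        return isinstance(other, RoutingTable) and self._table == other._table


# ---------------------------------------------------------------------------
# Event word codecs
# ---------------------------------------------------------------------------
# 24-bit input word layout (MSB first, mirroring the splitter's MSB-per-stage
# decode): core [23:21] | neuron [20:10] | syn_type [9:8] | strength [7:0].

def pack_input_event(e: InputEvent) -> int:
    """Pack an input event into its 24-bit bus word (timestamp not included)."""
    return (e.core << 21) | (e.neuron << 10) | (e.syn_type << 8) | e.strength


def unpack_input_event(word: int, t: float = 0.0) -> InputEvent:
    """Inverse of :func:`pack_input_event`."""
    word = int(word)
    if not 0 <= word < 2 ** INPUT_WORD_BITS:
        raise ValueError(f"input word out of 24-bit range: {word}")
    return InputEvent(
        t=t,
        core=(word >> 21) & 0x7,
        neuron=(word >> 10) & 0x7FF,
        syn_type=(word >> 8) & 0x3,
        strength=word & 0xFF,
    )


def pack_output_event(core: int, neuron: int) -> int:
    """14-bit output address: three merger-stage core bits above the 11-bit neuron."""
    if not 0 <= core < CORES_PER_QUADRANT:
        raise ValueError(f"core out of range [0, 7]: {core}")
    if not 0 <= neuron < NEURONS_PER_CORE:
        raise ValueError(f"neuron out of range [0, 2047]: {neuron}")
    return (core << 11) | neuron


def unpack_output_event(address: int) -> tuple[int, int]:
    if not 0 <= address < 2 ** OUTPUT_WORD_BITS:
        raise ValueError(f"output address out of 14-bit range: {address}")
    return address >> 11, address & 0x7FF


# ---------------------------------------------------------------------------
# Routing and splitter/merger behaviour
# ---------------------------------------------------------------------------

def route_spike(
    table: RoutingTable, presyn_id: int, t: float, axonal_delay: float = 0.0
) -> list[InputEvent]:
    """Fan a presynaptic spike at time ``t`` out through the routing table.

    Returns one input event per fan-out entry, in table order, stamped
    ``t + axonal_delay``.  An absent presynaptic id yields an empty list.
    """
    return [
        InputEvent(t + axonal_delay, en.core, en.neuron, en.syn_type, en.strength)
        for en in table.fan_out(presyn_id)
    ]


def split_to_cores(events: Iterable[InputEvent]) -> list[list[InputEvent]]:
    """Deliver each input event to the core named in its word's top three bits.

    Models the three-stage binary-tree splitter: one address MSB is decoded
    per stage, so the word reaches exactly the core in bits [23:21].
    """
    streams: list[list[InputEvent]] = [[] for _ in range(CORES_PER_QUADRANT)]
    for e in events:
        core = (pack_input_event(e) >> 21) & 0x7
        streams[core].append(e)
    return streams


def arbitrate_merge(streams: Sequence[Sequence[OutputEvent]]) -> list[OutputEvent]:
    """Three-stage binary-tree merge of the 8 per-core output streams.

    Each two-way merge keeps global time order for distinct timestamps and
    resolves equal timestamps deterministically in favour of the lower port
    index; one address MSB is prepended per stage.  No event is lost or
    duplicated.  Events must arrive with 11-bit in-core neuron addresses; the
    result carries full 14-bit quadrant addresses.
    """
    if len(streams) != CORES_PER_QUADRANT:
        raise ValueError(f"expected {CORES_PER_QUADRANT} per-core streams")
    staged: list[list[OutputEvent]] = []
    for core, stream in enumerate(streams):
        ts = [e.t for e in stream]
        if any(t1 < t0 for t0, t1 in zip(ts, ts[1:])):
            raise ValueError(f"stream for core {core} is not time-sorted")
        for e in stream:
            if e.address >= NEURONS_PER_CORE:
                raise ValueError(
                    "per-core streams must carry 11-bit neuron addresses"
                )
        staged.append(list(stream))

    for stage in range(3):  # 8 -> 4 -> 2 -> 1
        merged: list[list[OutputEvent]] = []
        for lo, hi in zip(staged[0::2], staged[1::2]):
            merged.append(_merge_two(lo, hi, bit_pos=11 + stage))
        staged = merged
    return staged[0]


def _merge_two(
    a: list[OutputEvent], b: list[OutputEvent], bit_pos: int
) -> list[OutputEvent]:
    """One arbiter stage: two-way time merge, port 0 wins ties, MSB prepended.

    ``bit_pos`` is where the selected-port bit lands: events grow from 11-bit
    in-core addresses to the 14-bit quadrant address over the three stages.
    """
    out: list[OutputEvent] = []
    i = j = 0
    while i < len(a) or j < len(b):
        take_a = j >= len(b) or (i < len(a) and a[i].t <= b[j].t)
        if take_a:
            e, bit = a[i], 0
            i += 1
        else:
            e, bit = b[j], 1
            j += 1
        out.append(replace(e, address=e.address | (bit << bit_pos)))
    return out
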