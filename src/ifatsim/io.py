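"""Event-stream, routing-table and image file formats.

Event streams exist in two interconvertible dialects with microsecond time
resolution: a CSV with header ``t_us,core,neuron,syn_type,strength`` and a
packed binary file of little-endian records — a 32-bit unsigned timestamp in
microseconds followed by a 32-bit word whose low 24 bits are the packed
input-event bus word (high byte zero).  Routing tables are CSV with header
``pre_id,core,neuron,syn_type,strength``; fan-out order is file order.
Grayscale images go through PGM (raw P5 or plain P2) and PNG.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .aer import InputEvent, RoutingEntry, RoutingTable, pack_input_event, unpack_input_event

__all__ = [
    "read_events", "write_events", "read_routing", "write_routing",
    "read_image", "write_image",
]

_EVENT_COLUMNS = ["t_us", "core", "neuron", "syn_type", "strength"]
_ROUTING_COLUMNS = ["pre_id", "core", "neuron", "syn_type", "strength"]


def _is_binary(path: Path) -> bool:
    return path.suffix.lower() in (".bin", ".aer", ".dat")


def write_events(events: Sequence[InputEvent], path: str | Path) -> None:
    """Write an event stream; dialect chosen by extension (.csv vs .bin)."""
    path = Path(path)
    t_us = np.array([round(e.t * 1e6) for e in events], dtype=np.uint64)
    if np.any(np.diff(t_us.astype(np.int64)) < 0):
        raise ValueError("events must be time-sorted")
    if _is_binary(path):
        words = np.array([pack_input_event(e) for e in events], dtype=np.uint32)
        rec = np.empty(2 * len(events), dtype="<u4")
        rec[0::2] = t_us.astype("<u4")
        rec[1::2] = words
        rec.tofile(path)
    else:
        df = pd.DataFrame(
            {
                "t_us": t_us,
                "core": [e.core for e in events],
                "neuron": [e.neuron for e in events],
                "syn_type": [e.syn_type for e in events],
                "strength": [e.strength for e in events],
            }
        )
        df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[InputEvent]:
    """Read an event stream (CSV or packed binary) into time-sorted events."""
    path = Path(path)
    if _is_binary(path):
        rec = np.fromfile(path, dtype="<u4")
        if len(rec) % 2:
            raise ValueError(f"{path}: truncated binary event record")
        events = []
        for t_us, word in zip(rec[0::2], rec[1::2]):
            if word >> 24:
                raise ValueError(f"{path}: high byte of event word must be zero")
            events.append(unpack_input_event(int(word), t=float(t_us) / 1e6))
    else:
        df = pd.read_csv(path)
        if list(df.columns) != _EVENT_COLUMNS:
            raise ValueError(
                f"{path}: expected header {','.join(_EVENT_COLUMNS)}, got "
                f"{','.join(map(str, df.columns))}"
            )
        events = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                events.append(
                    InputEvent(float(row.t_us) / 1e6, int(row.core), int(row.neuron),
                               int(row.syn_type), int(row.strength))
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{i}: malformed event row: {exc}") from exc
    ts = [e.t for e in events]
    if any(t1 < t0 for t0, t1 in zip(ts, ts[1:])):
        raise ValueError(f"{path}: event times are not sorted")
    return events


def write_routing(table: RoutingTable, path: str | Path) -> None:
    rows = []
    for pre_id, entries in table.items():
        for e in entries:
            rows.append((pre_id, e.core, e.neuron, e.syn_type, e.strength))
    pd.DataFrame(rows, columns=_ROUTING_COLUMNS).to_csv(path, index=False)


def read_routing(path: str | Path) -> RoutingTable:
    df = pd.read_csv(path)
    if list(df.columns) != _ROUTING_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_ROUTING_COLUMNS)}, got "
            f"{','.join(map(str, df.columns))}"
        )
    table = RoutingTable()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            table.add(int(row.pre_id),
                      RoutingEntry(int(row.core), int(row.neuron),
                                   int(row.syn_type), int(row.strength)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed routing row: {exc}") from exc
    return table


def write_image(arr: np.ndarray, path: str | Path, plain: bool = False) -> None:
    """Write an 8-bit grayscale image as PGM (raw P5, or plain P2) or PNG."""
    path = Path(path)
    a = np.asarray(arr)
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a), 0, 255).astype(np.uint8)
    if path.suffix.lower() == ".pgm" and plain:
        lines = [f"P2\n{a.shape[1]} {a.shape[0]}\n255\n"]
        lines += [" ".join(str(v) for v in row) + "\n" for row in a]
        path.write_text("".join(lines))
    else:
        Image.fromarray(a, mode="L").save(path)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
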