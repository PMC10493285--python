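"""Structured configuration with unit-suffixed values.

The config document is YAML with five sections — ``neuron``, ``mismatch``,
``timing``, ``sim`` and ``encoders`` — whose scalar values may carry SI unit
suffixes ("50 pS", "20 ms", "0.5 V").  Values are stored SI internally.
Unknown sections or keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .neuron import CompartmentParams, NeuronParams, SynapseParams
from .pipeline import TimingParams

__all__ = ["SimConfig", "parse_quantity", "load_config"]

_PREFIX = {
    "f": 1e-15, "p": 1e-12, "n": 1e-9, "u": 1e-6, "µ": 1e-6,
    "m": 1e-3, "": 1.0, "k": 1e3, "M": 1e6, "G": 1e9,
}
_UNITS = ("Hz", "V", "S", "s", "F")
_QTY_RE = re.compile(
    r"^\s*([-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)\s*([fpnuµmkMG]?)(Hz|V|S|s|F)\s*$"
)


def parse_quantity(value) -> float:
    """Parse a number or a unit-suffixed string ("50 pS") into SI units."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if not m:
            raise ValueError(f"cannot parse quantity: {value!r}")
        return float(m.group(1)) * _PREFIX[m.group(2)]
    raise ValueError(f"cannot parse quantity: {value!r}")


_NEURON_KEYS = {
    "C_mem", "G_leak", "E_leak", "G_comp", "V_thresh", "V_reset", "t_refr",
    "E_rev_exc", "E_rev_inh", "tau_syn", "g0",
}
_MISMATCH_KEYS = {"mu_offset", "sigma_offset", "mu_slope", "sigma_slope", "seed"}
_TIMING_KEYS = {"T_latency", "dt_pulse_base", "row_count"}
_SIM_KEYS = {"dt", "duration", "probes", "probe_interval"}
_ENCODER_KEYS = {"rate_unit", "w_nom"}


@dataclass
class SimConfig:
    """Validated configuration; all quantities SI."""

    neuron: dict = field(default_factory=dict)
    mismatch: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    encoders: dict = field(default_factory=dict)
    config_hash: str = ""

    def neuron_params(self) -> NeuronParams:
        n = self.neuron
        comp = CompartmentParams(
            C_mem=n.get("C_mem", 1e-12),
            G_leak=n.get("G_leak", 50e-12),
            E_leak=n.get("E_leak", 0.0),
        )
        e_exc = n.get("E_rev_exc", 1.0)
        e_inh = n.get("E_rev_inh", 0.0)
        tau = n.get("tau_syn", 5e-3)
        g0 = n.get("g0", 1e-12)
        return NeuronParams(
            distal=comp,
            proximal=comp,
            G_comp=n.get("G_comp", 0.5e-9),
            V_thresh=n.get("V_thresh", 0.5),
            V_reset=n.get("V_reset", 0.0),
            t_refr=n.get("t_refr", 100e-6),
            synapses=(
                SynapseParams(0, e_exc, tau, g0),
                SynapseParams(1, e_inh, tau, g0),
                SynapseParams(2, e_exc, tau, g0),
                SynapseParams(3, e_inh, tau, g0),
            ),
        )

    def timing_params(self) -> TimingParams:
        t = self.timing
        return TimingParams(
            T_latency=t.get("T_latency", 50e-9),
            dt_pulse_base=t.get("dt_pulse_base", 10e-6),
            row_count=int(t.get("row_count", 64)),
        )


def load_config(path: str | Path) -> SimConfig:
    """Load, unit-parse and validate a YAML config document."""
    raw = Path(path).read_text()
    doc = yaml.safe_load(raw) or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    allowed = {
        "neuron": _NEURON_KEYS,
        "mismatch": _MISMATCH_KEYS,
        "timing": _TIMING_KEYS,
        "sim": _SIM_KEYS,
        "encoders": _ENCODER_KEYS,
    }
    unknown = set(doc) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = SimConfig(config_hash=hashlib.sha256(raw.encode()).hexdigest()[:16])
    for section, keys in allowed.items():
        sec = doc.get(section) or {}
        if not isinstance(sec, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(sec) - keys
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
        parsed = {}
        for k, v in sec.items():
            if k in ("probes",):
                parsed[k] = [int(x) for x in (v or [])]
            elif k in ("seed", "row_count", "w_nom"):
                parsed[k] = int(v)
            else:
                parsed[k] = parse_quantity(v)
        setattr(cfg, section, parsed)
    return cfg
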