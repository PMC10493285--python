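"""Mean-rate linear/ReLU approximation of the neuron.

On time scales of many spikes, a conductance synapse driven by spike trains
at frequencies ``f_n`` with weight codes ``w_n`` behaves like a constant
drive proportional to the weight-normalized effective rate
``f_eff = sum_n f_n * w_n / w_nom``.  The output rate is then a rectified
linear function of the net excitatory-minus-inhibitory effective drive:

    f_out = [ G_wnom * (f_ext_eff - f_inh_eff) ]+

where ``G_wnom`` is the dimensionless gain-scaling factor at the nominal
weight ``w_nom`` (default 80).  The model is exact under its own reduction:
exchanging a set of inputs for a single input at their effective rate leaves
the output unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["RateModelParams", "EffectiveInput", "effective_rate", "relu_rate",
           "fit_gain"]

DEFAULT_W_NOM = 80


@dataclass(frozen=True)
class RateModelParams:
    w_nom: int = DEFAULT_W_NOM      # nominal digital weight code
    G_wnom: float = 1.0             # gain-scaling factor at w_nom

    def __post_init__(self) -> None:
        if self.w_nom <= 0:
            raise ValueError("w_nom must be positive")
        if self.G_wnom < 0:
            raise ValueError("G_wnom must be non-negative")


@dataclass(frozen=True)
class EffectiveInput:
    """Weight-normalized excitatory and inhibitory drive, Hz."""

    f_ext_eff: float = 0.0
    f_inh_eff: float = 0.0

    def __post_init__(self) -> None:
        if self.f_ext_eff < 0 or self.f_inh_eff < 0:
            raise ValueError("effective rates must be non-negative")


def effective_rate(
    rates: Sequence[float], weights: Sequence[float], w_nom: int = DEFAULT_W_NOM
) -> float:
    """Weight-normalized effective input rate: sum_n f_n * w_n / w_nom."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.shape != weights.shape:
        raise ValueError("rates and weights must have equal length")
    if w_nom <= 0:
        raise ValueError("w_nom must be positive")
    if rates.size == 0:
        return 0.0
    return float(np.sum(rates * weights) / w_nom)


def relu_rate(inp: EffectiveInput, p: RateModelParams) -> float:
    """Rectified-linear output rate for a given effective drive."""
    return max(0.0, p.G_wnom * (inp.f_ext_eff - inp.f_inh_eff))


def fit_gain(
    drives: Sequence[float],
    rates: Sequence[float],
    w_nom: int = DEFAULT_W_NOM,
    f_max: float | None = None,
) -> RateModelParams:
    """Least-squares gain through the origin on rectified (drive, rate) pairs.

    ``drives`` are net effective input rates and ``rates`` the simulated or
    measured output rates.  Pairs with non-positive drive are excluded
    (rectified region carries no gain information); when ``f_max`` is given,
    pairs at or above half of it are treated as gain-one saturation and
    excluded from the linear fit.
    """
    d = np.asarray(drives, dtype=float)
    r = np.asarray(rates, dtype=float)
    if d.shape != r.shape:
        raise ValueError("drives and rates must have equal length")
    mask = d > 0
    if f_max is not None:
        mask &= r < 0.5 * f_max
    if mask.sum() < 1 or not np.any(d[mask] != 0):
        raise ValueError("no usable pairs in the linear regime")
    g = float(np.sum(d[mask] * r[mask]) / np.sum(d[mask] ** 2))
    return RateModelParams(w_nom=w_nom, G_wnom=max(0.0, g))
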