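"""Per-neuron mismatch modelling and single-point digital offset calibration.

Fabrication mismatch (mainly threshold-voltage spread in the axon-hillock
comparator) shows up as a per-neuron horizontal *offset* of the response
curve along the digital-weight axis, and as a per-neuron *slope* of
log10(output rate) per weight code in the log-linear regime.  Both are
modelled as independent normal draws; the ideal PWAM code law gives a slope
of log10(2)/16 ~ 0.0188 decades per code.

Calibration measures each neuron's weight-sweep response at fixed input
rate, reads the offset off the curve as the code where the response gain
crosses a criterion (0.1 by default), and stores an integer per-neuron
weight correction that re-centres all curves on the population mean.  The
corrections are applied externally, by pre-distorting routing-table
strengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aer import RoutingEntry, RoutingTable

__all__ = [
    "IDEAL_SLOPE",
    "SLOPE_FLOOR",
    "MismatchModel",
    "ResponseCurve",
    "CalibrationTable",
    "CalibrationError",
    "sample_mismatch",
    "synthesize_response_curve",
    "estimate_offset",
    "estimate_slope",
    "calibrate",
    "apply_calibration",
    "run_mismatch_experiment",
]

#: Slope of the ideal PWAM law dG ~ 2**(code/16): log10(2)/16 decades/code.
IDEAL_SLOPE = math.log10(2.0) / 16.0

#: Lower truncation of sampled slopes, decades/code.  About a tenth of the
#: ideal law; keeps every neuron's log-linear regime inside the 0-255 sweep.
SLOPE_FLOOR = 0.002

#: Digital weight at which the nominal (mismatch-free) neuron's gain crosses
#: the calibration criterion; ties the offset scale to the nominal weight.
NOMINAL_OFFSET_CODE = 80.0

DEFAULT_GAIN_CRITERION = 0.1


class CalibrationError(RuntimeError):
    """A response curve that cannot be calibrated (no criterion crossing or
    too few points in the log-linear regime)."""


@dataclass(frozen=True)
class MismatchModel:
    """Per-neuron offset (weight codes) and slope (decades/code) draws.

    In simulation a neuron's PWAM conductance step becomes
    ``dG(w) = g0 * 10**(slope * (w - offset))`` — the smooth log-linear
    envelope of the code law, shifted by the neuron's offset and tilted to
    its slope.  With ``slope = IDEAL_SLOPE`` and zero offset this reduces to
    ``g0 * 2**(w/16)``.
    """

    offset_w: np.ndarray
    slope_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.offset_w) != len(self.slope_s):
            raise ValueError("offset_w and slope_s must have equal length")
        if np.any(self.slope_s <= 0):
            raise ValueError("slopes must be positive")

    def __len__(self) -> int:
        return len(self.offset_w)

    def conductance_step(self, neuron_id: int, byte: int, g0: float) -> float:
        w_eff = byte - float(self.offset_w[neuron_id])
        return g0 * 10.0 ** (float(self.slope_s[neuron_id]) * w_eff)


def sample_mismatch(
    n: int,
    mu_off: float = 0.0,
    sigma_off: float = 8.0,
    mu_slope: float = 0.0185,
    sigma_slope: float = 0.0068,
    seed: int | np.random.Generator = 0,
) -> MismatchModel:
    """Draw ``n`` independent per-neuron mismatch realizations.

    Slopes are rejection-sampled into ``[max(mu - 3 sigma, SLOPE_FLOOR),
    mu + 3 sigma]``: a plain 3-sigma window would admit non-physical
    non-positive slopes at the default parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma_off < 0 or sigma_slope < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(mu_off, sigma_off, size=n)
    if sigma_slope == 0:
        if mu_slope <= 0:
            raise ValueError("mu_slope must be positive")
        return MismatchModel(offset_w=offsets, slope_s=np.full(n, mu_slope))
    lo = max(mu_slope - 3.0 * sigma_slope, SLOPE_FLOOR)
    hi = mu_slope + 3.0 * sigma_slope
    if hi <= lo:
        raise ValueError("slope distribution entirely below the positivity floor")
    slopes = rng.normal(mu_slope, sigma_slope, size=n)
    bad = (slopes < lo) | (slopes > hi)
    while np.any(bad):
        slopes[bad] = rng.normal(mu_slope, sigma_slope, size=int(bad.sum()))
        bad = (slopes < lo) | (slopes > hi)
    return MismatchModel(offset_w=offsets, slope_s=slopes)


@dataclass(frozen=True)
class ResponseCurve:
    """Output rate versus digital weight code at a fixed input rate."""

    codes: np.ndarray
    rates: np.ndarray
    input_rate: float

    def __post_init__(self) -> None:
        c = np.asarray(self.codes, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if len(c) != len(r):
            raise ValueError("codes and rates must have equal length")
        if np.any(np.diff(c) <= 0):
            raise ValueError("codes must be strictly increasing")
        object.__setattr__(self, "codes", c)
        object.__setattr__(self, "rates", r)


def synthesize_response_curve(
    offset_w: float,
    slope_s: float,
    input_rate: float = 10_000.0,
    codes: np.ndarray | None = None,
    duration: float = 1.0,
    rng: np.random.Generator | int = 0,
    gain_criterion: float = DEFAULT_GAIN_CRITERION,
) -> ResponseCurve:
    """Rate-model shortcut for one neuron's weight-sweep response.

    The mean response follows the mismatch model's log-linear law — the rate
    crosses ``gain_criterion * input_rate`` at code ``NOMINAL_OFFSET_CODE +
    offset_w`` and climbs ``slope_s`` decades per code until it saturates at
    gain one — and the measured rate is a Poisson spike count over
    ``duration`` at that mean, exactly as a counting measurement would see.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    codes = np.arange(256) if codes is None else np.asarray(codes)
    mean = _mean_response(np.asarray(codes, dtype=float)[None, :],
                          np.array([offset_w]), np.array([slope_s]),
                          input_rate, gain_criterion)[0]
    counts = rng.poisson(mean * duration)
    return ResponseCurve(codes=codes, rates=counts / duration, input_rate=input_rate)


def _mean_response(codes, offsets, slopes, input_rate, gain_criterion):
    """Mean rate surface (n_neurons, n_codes) of the log-linear regime model."""
    crossing = NOMINAL_OFFSET_CODE + offsets[:, None]
    log_rate = np.log10(gain_criterion * input_rate) + slopes[:, None] * (codes - crossing)
    return np.minimum(10.0 ** log_rate, input_rate)


def estimate_offset(
    curve: ResponseCurve, gain_criterion: float = DEFAULT_GAIN_CRITERION
) -> float:
    """Digital weight (fractional) where the response gain crosses the criterion.

    Linear interpolation in (code, log10 rate) at ``rate = gain_criterion *
    input_rate``; the curve must span the crossing.
    """
    target = gain_criterion * curve.input_rate
    above = curve.rates >= target
    if not above.any() or above[0]:
        raise CalibrationError("response curve does not span the criterion crossing")
    i = int(np.argmax(above))            # first code at/above the criterion
    r_lo, r_hi = curve.rates[i - 1], curve.rates[i]
    c_lo, c_hi = curve.codes[i - 1], curve.codes[i]
    if r_lo <= 0:
        return float(c_hi)
    frac = (math.log10(target) - math.log10(r_lo)) / (math.log10(r_hi) - math.log10(r_lo))
    return float(c_lo + frac * (c_hi - c_lo))


def estimate_slope(
    curve: ResponseCurve,
    gain_criterion: float = DEFAULT_GAIN_CRITERION,
    min_points: int = 4,
) -> float:
    """Least-squares slope of log10(rate) vs code over the log-linear regime.

    The regime is taken as rates between twice the offset-criterion rate and
    half the input rate — comfortably above the threshold knee and below
    gain-one saturation.
    """
    lo = 2.0 * gain_criterion * curve.input_rate
    hi = 0.5 * curve.input_rate
    mask = (curve.rates >= lo) & (curve.rates <= hi)
    if int(mask.sum()) < min_points:
        raise CalibrationError(
            f"only {int(mask.sum())} points in the linear regime (need {min_points})"
        )
    slope, _ = np.polyfit(curve.codes[mask], np.log10(curve.rates[mask]), 1)
    return float(slope)


@dataclass(frozen=True)
class CalibrationTable:
    """Integer per-neuron weight corrections re-centring curves on the mean.

    ``corrections[i] = round(mean(offsets) - offset_i)`` measures how far
    neuron i's crossing sits below (positive) or above (negative) the
    population mean; pre-distorting a routed strength *removes* that excess
    sensitivity, so the transmitted code is ``byte - correction`` clamped to
    the 8-bit range.
    """

    corrections: np.ndarray

    def corrected_strength(self, neuron_id: int, byte: int) -> int:
        return int(np.clip(byte - self.corrections[neuron_id], 0, 255))


def calibrate(offsets: np.ndarray) -> CalibrationTable:
    """Single-point offset calibration: align every curve to the mean offset."""
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    corr = np.rint(offsets.mean() - offsets).astype(int)
    return CalibrationTable(corrections=corr)


def apply_calibration(
    table: RoutingTable, cal: CalibrationTable, neuron_id_of=lambda e: e.core * 2048 + e.neuron
) -> RoutingTable:
    """Pre-distort routing-table strengths by the per-target corrections."""
    out = RoutingTable()
    for pre_id, entries in table.items():
        for e in entries:
            s = cal.corrected_strength(neuron_id_of(e), e.strength)
            out.add(pre_id, RoutingEntry(e.core, e.neuron, e.syn_type, s))
    return out


def run_mismatch_experiment(
    n: int = 2048,
    seed: int = 0,
    input_rate: float = 10_000.0,
    duration: float = 1.0,
    mu_off: float = 0.0,
    sigma_off: float = 8.0,
    mu_slope: float = 0.0185,
    sigma_slope: float = 0.0068,
    gain_criterion: float = DEFAULT_GAIN_CRITERION,
    codes: np.ndarray | None = None,
) -> dict:
    """Full mismatch-recovery experiment on a simulated core.

    Draws per-neuron mismatch, synthesizes each neuron's 0-255 weight sweep
    (Poisson counting at ``input_rate`` for ``duration`` per code), and
    estimates every neuron's offset and slope from its measured curve.
    Returns the mismatch model, the per-neuron estimates (NaN where a curve
    was uncalibratable), and the sample statistics of the slope estimates.
    """
    rng = np.random.default_rng(seed)
    model = sample_mismatch(n, mu_off, sigma_off, mu_slope, sigma_slope, seed=rng)
    codes = np.arange(256, dtype=float) if codes is None else np.asarray(codes, float)
    mean = _mean_response(codes[None, :], model.offset_w, model.slope_s,
                          input_rate, gain_criterion)
    rates = rng.poisson(mean * duration) / duration

    offset_est = np.full(n, np.nan)
    slope_est = np.full(n, np.nan)
    for i in range(n):
        curve = ResponseCurve(codes=codes, rates=rates[i], input_rate=input_rate)
        try:
            offset_est[i] = estimate_offset(curve, gain_criterion)
            slope_est[i] = estimate_slope(curve, gain_criterion)
        except CalibrationError:
            continue
    ok = np.isfinite(slope_est)
    return {
        "model": model,
        "offset_est": offset_est,
        "slope_est": slope_est,
        "n_flagged": int((~ok).sum()),
        "slope_mean": float(np.mean(slope_est[ok])),
        "slope_std": float(np.std(slope_est[ok], ddof=1)),
        "offset_std": float(np.std(offset_est[np.isfinite(offset_est)], ddof=1)),
    }
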