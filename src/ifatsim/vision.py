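"""Orientation tuning and boundary detection through IFAT neurons.

A 15x15 stimulus patch is encoded pixel-by-pixel into input spike rates
(6-bit intensity codes, 0 = darkest to 63 = brightest), and a 15x15 signed
kernel (an oriented Gabor patch) into per-pixel synaptic weight codes:
positive values drive the excitatory synapse, negative values the inhibitory
synapse of a single target neuron.  The projected output rate realizes the
rectified weighted sum

    f_out = [ sum_ij f_in(i,j) * w(i,j) ]+   (gain-scaled)

either through the mean-rate ReLU model or by actually wiring all 225
Poisson trains to one neuron in the event-driven engine.  Sweeping bar
stimuli over orientation yields tuning curves peaked at the kernel
orientation; sliding the window over an image yields oriented boundary maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neuron import CompartmentParams, NeuronParams, SynapseParams
from .rate_model import RateModelParams, EffectiveInput, relu_rate, DEFAULT_W_NOM
from .simulation import DEFAULT_BURN_IN, DEFAULT_DT, gen_spike_train, run_simulation
from .aer import InputEvent

__all__ = [
    "PATCH_SIZE",
    "RATE_UNIT",
    "TuningCurve",
    "demo_neuron_params",
    "gabor_patch",
    "bar_stimulus",
    "encode_stimulus",
    "encode_kernel",
    "project_patch",
    "tuning_curve",
    "detect_boundaries",
    "synthetic_boundary_image",
]

PATCH_SIZE = 15

#: Hz per intensity code unit; code 63 maps to ~2 kHz, the top of the
#: excitatory/inhibitory input-frequency range of the rate-model surface.
RATE_UNIT = 31.25


def demo_neuron_params(g0: float = 3.3e-15, tau_syn: float = 2e-3) -> NeuronParams:
    """Neuron profile used by the vision demos.

    The projection neuron is programmed into the current-driven regime where
    the rectified-linear reduction is faithful: symmetric excitatory and
    inhibitory reversal potentials at +-1 V with a threshold of only 0.1 V,
    so g*(E - V) ~ g*E and excitatory/inhibitory unit drives are equal and
    opposite; a small leak and a decoupled distal compartment keep the
    rectification threshold low; and a scaled-down conductance quantum keeps
    the 225-pixel summed drive linear.  The short synaptic time constant
    leaves enough Poisson conductance fluctuation to smooth the knee of the
    rectifier, as noisy input does in the measured activation functions.
    """
    return NeuronParams(
        distal=CompartmentParams(1e-12, 2e-12, 0.0),
        proximal=CompartmentParams(1e-12, 2e-12, 0.0),
        G_comp=0.0,
        V_thresh=0.01,
        V_reset=0.0,
        t_refr=10e-6,
        synapses=(
            SynapseParams(0, 1.0, tau_syn, g0),
            SynapseParams(1, -1.0, tau_syn, g0),
            SynapseParams(2, 1.0, tau_syn, g0),
            SynapseParams(3, -1.0, tau_syn, g0),
        ),
    )


def gabor_patch(
    theta: float,
    size: int = PATCH_SIZE,
    wavelength: float = 10.0,
    sigma: float = 4.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Zero-mean oriented Gabor kernel on a ``size`` x ``size`` grid.

    ``theta`` (degrees) is the orientation of the carrier wave vector; with
    even phase the kernel is symmetric under 180-degree rotation.  The DC
    component is subtracted so a uniform stimulus projects to zero.
    """
    if size % 2 == 0:
        raise ValueError("size must be odd")
    c = size // 2
    y, x = np.mgrid[-c: c + 1, -c: c + 1].astype(float)
    th = math.radians(theta)
    # stripes run along theta: the carrier varies perpendicular to the
    # orientation, so a bar at angle theta drives the kernel maximally
    perp = -x * math.sin(th) + y * math.cos(th)
    g = np.exp(-(x ** 2 + y ** 2) / (2.0 * sigma ** 2)) * np.cos(
        2.0 * math.pi * perp / wavelength + phase
    )
    return g - g.mean()


def bar_stimulus(theta: float, size: int = PATCH_SIZE, width: float = 3.0) -> np.ndarray:
    """Anti-aliased bright bar through the centre at angle ``theta`` (degrees).

    The bar is a rotated rectangle of length ``size`` and the given width on
    a dark background, intensities 0-255; its total intensity is therefore
    approximately orientation-invariant.
    """
    if width < 1:
        raise ValueError("width must be >= 1 pixel")
    c = size // 2
    y, x = np.mgrid[-c: c + 1, -c: c + 1].astype(float)
    th = math.radians(theta)
    u = x * math.cos(th) + y * math.sin(th)        # along the bar
    d = np.abs(-x * math.sin(th) + y * math.cos(th))  # across the bar
    across = np.clip(0.5 + (width / 2.0 - d), 0.0, 1.0)
    along = np.clip(0.5 + (size / 2.0 - np.abs(u)), 0.0, 1.0)
    return 255.0 * across * along


def encode_stimulus(
    patch: np.ndarray, rate_unit: float = RATE_UNIT, max_intensity: float | None = None
) -> np.ndarray:
    """Per-pixel input rates: 6-bit intensity code (0-63) times ``rate_unit``.

    ``max_intensity`` fixes the intensity mapped to code 63; by default the
    patch's own maximum (an all-zero stimulus encodes to all-zero rates).
    """
    patch = np.asarray(patch, dtype=float)
    if np.any(patch < 0):
        raise ValueError("stimulus intensities must be non-negative")
    top = float(patch.max()) if max_intensity is None else float(max_intensity)
    if top <= 0:
        return np.zeros_like(patch)
    codes = np.rint(63.0 * patch / top)
    return codes * rate_unit


def encode_kernel(patch: np.ndarray, w_nom: int = DEFAULT_W_NOM) -> np.ndarray:
    """Per-pixel signed weight codes for a (zero-mean) kernel.

    Magnitudes are scaled so the kernel's peak maps to twice the nominal
    weight (w_nom as mid-scale), clipped to the 8-bit code range; the sign
    selects the excitatory (+) or inhibitory (-) synapse.
    """
    patch = np.asarray(patch, dtype=float)
    top = float(np.abs(patch).max())
    if top <= 0:
        return np.zeros(patch.shape, dtype=int)
    codes = np.rint(np.abs(patch) / top * 2 * w_nom)
    codes = np.clip(codes, 0, 255).astype(int)
    return (np.sign(patch) * codes).astype(int)


def _linear_weight_to_byte(w: int, w_nom: int) -> int:
    """Digital strength byte realizing a *linear* synaptic weight ``w``.

    The PWAM code law is exponential (dG ~ 2**(byte/16)), so a weight that
    must scale conductance linearly is programmed through the logarithm of
    its magnitude, anchored so that ``w = w_nom`` transmits byte ``w_nom``.
    """
    byte = round(w_nom + 16.0 * math.log2(w / w_nom))
    return int(np.clip(byte, 0, 255))


def _effective_drive(rates: np.ndarray, weights: np.ndarray, w_nom: int) -> EffectiveInput:
    pos = weights > 0
    neg = weights < 0
    f_ext = float(np.sum(rates[pos] * weights[pos]) / w_nom)
    f_inh = float(np.sum(rates[neg] * -weights[neg]) / w_nom)
    return EffectiveInput(f_ext_eff=f_ext, f_inh_eff=f_inh)


def project_patch(
    rates: np.ndarray,
    weights: np.ndarray,
    mode: str = "rate_model",
    *,
    rm_params: RateModelParams | None = None,
    neuron_params: NeuronParams | None = None,
    duration: float = 1.0,
    burn_in: float = DEFAULT_BURN_IN,
    seed: int | np.random.SeedSequence = 0,
    dt: float = DEFAULT_DT,
) -> float:
    """Project one encoded stimulus through one encoded kernel; returns Hz.

    ``rate_model`` computes the rectified weighted sum directly;
    ``event_sim`` wires one Poisson train per active pixel to the target
    neuron's proximal excitatory/inhibitory synapse and measures the output
    rate over ``duration`` after a ``burn_in`` transient.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights)
    if rates.shape != weights.shape:
        raise ValueError("stimulus and kernel shapes must match")
    rm_params = rm_params or RateModelParams()

    if mode == "rate_model":
        return relu_rate(_effective_drive(rates, weights, rm_params.w_nom), rm_params)
    if mode != "event_sim":
        raise ValueError(f"unknown projection mode: {mode!r}")

    params = neuron_params or demo_neuron_params()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    active = np.argwhere((rates > 0) & (weights != 0))
    children = ss.spawn(len(active))
    total = burn_in + duration
    events: list[InputEvent] = []
    for (idx, (i, j)) in enumerate(active):
        w = int(weights[i, j])
        syn = 2 if w > 0 else 3
        strength = _linear_weight_to_byte(abs(w), rm_params.w_nom)
        train = gen_spike_train("poisson", float(rates[i, j]), total,
                                seed=np.random.default_rng(children[idx]))
        events.extend(
            InputEvent(float(t), 0, 0, syn, strength) for t in train.times
        )
    events.sort(key=lambda e: e.t)
    res = run_simulation(params, None, events, total, dt=dt)
    return res.rate(0, t_start=burn_in, t_stop=total)


@dataclass(frozen=True)
class TuningCurve:
    """Mean +- std of the projected rate per stimulus angle."""

    angles: np.ndarray       # degrees
    mean_rate: np.ndarray    # Hz
    std_rate: np.ndarray     # Hz

    def __post_init__(self) -> None:
        if not (len(self.angles) == len(self.mean_rate) == len(self.std_rate)):
            raise ValueError("angles, mean and std must have equal length")
        if np.any(self.std_rate < 0):
            raise ValueError("std must be non-negative")

    def peak_angle(self) -> float:
        return float(self.angles[int(np.argmax(self.mean_rate))])


def tuning_curve(
    kernel_theta: float,
    angles: np.ndarray | None = None,
    trials: int = 30,
    trial_duration: float = 1.0,
    seed: int = 0,
    mode: str = "event_sim",
    *,
    bar_width: float = 3.0,
    neuron_params: NeuronParams | None = None,
    rm_params: RateModelParams | None = None,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
) -> TuningCurve:
    """Orientation tuning curve of a Gabor kernel at ``kernel_theta`` degrees.

    Bar stimuli sweep 0-180 degrees in 5-degree steps by default; each data
    point is the mean (and std) of ``trials`` independent Poisson projection
    measurements of ``trial_duration`` each.
    """
    angles = np.arange(0.0, 181.0, 5.0) if angles is None else np.asarray(angles, float)
    kernel = encode_kernel(gabor_patch(kernel_theta))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(angles) * trials)
    means = np.empty(len(angles))
    stds = np.empty(len(angles))
    for ai, theta in enumerate(angles):
        stim = encode_stimulus(bar_stimulus(theta, width=bar_width))
        vals = np.empty(trials)
        for k in range(trials):
            vals[k] = project_patch(
                stim, kernel, mode,
                rm_params=rm_params, neuron_params=neuron_params,
                duration=trial_duration, burn_in=burn_in,
                seed=children[ai * trials + k], dt=dt,
            )
        means[ai] = vals.mean()
        stds[ai] = vals.std(ddof=1) if trials > 1 else 0.0
    return TuningCurve(angles=angles, mean_rate=means, std_rate=stds)


def detect_boundaries(
    image: np.ndarray,
    kernels: list[np.ndarray] | None = None,
    mode: str = "rate_model",
    *,
    rm_params: RateModelParams | None = None,
    neuron_params: NeuronParams | None = None,
    duration: float = 0.2,
    burn_in: float = DEFAULT_BURN_IN,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    normalize: bool = True,
) -> list[np.ndarray]:
    """Oriented boundary maps of a grayscale image.

    Slides a 15x15 window (stride 1, valid region) over the image and
    projects every patch through each oriented kernel; a 113x75 input yields
    99x61 maps.  ``kernels`` defaults to four Gabor patches at 0, 45, 90 and
    135 degrees.  With ``normalize`` the maps are jointly scaled to 0-255
    for writing as images; otherwise raw rates (Hz) are returned.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < PATCH_SIZE:
        raise ValueError(f"image must be 2-D and at least {PATCH_SIZE}x{PATCH_SIZE}")
    if kernels is None:
        kernels = [gabor_patch(th) for th in (0.0, 45.0, 90.0, 135.0)]
    rm_params = rm_params or RateModelParams()

    top = image.max() if image.max() > 0 else 1.0
    rate_img = encode_stimulus(image, max_intensity=top)
    weight_sets = [encode_kernel(k, rm_params.w_nom) for k in kernels]

    h = image.shape[0] - PATCH_SIZE + 1
    w = image.shape[1] - PATCH_SIZE + 1
    maps: list[np.ndarray] = []
    if mode == "rate_model":
        windows = np.lib.stride_tricks.sliding_window_view(
            rate_img, (PATCH_SIZE, PATCH_SIZE)
        )
        for wts in weight_sets:
            drive = np.einsum("ijkl,kl->ij", windows, wts.astype(float)) / rm_params.w_nom
            maps.append(np.maximum(0.0, rm_params.G_wnom * drive))
    elif mode == "event_sim":
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(h * w * len(weight_sets))
        for ki, wts in enumerate(weight_sets):
            out = np.empty((h, w))
            for i in range(h):
                for j in range(w):
                    out[i, j] = project_patch(
                        rate_img[i: i + PATCH_SIZE, j: j + PATCH_SIZE], wts,
                        "event_sim",
                        neuron_params=neuron_params, duration=duration,
                        burn_in=burn_in,
                        seed=children[(ki * h + i) * w + j], dt=dt,
                    )
            maps.append(out)
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    if normalize:
        peak = max(float(m.max()) for m in maps)
        if peak > 0:
            maps = [m * (255.0 / peak) for m in maps]
    return maps


def synthetic_boundary_image(height: int = 75, width: int = 113, seed: int = 0) -> np.ndarray:
    """Synthetic grayscale test scene with oriented edges (stand-in for a
    photographic input): a bright rectangle and a diagonal stripe on a dark
    background, uint8."""
    img = np.zeros((height, width), dtype=float)
    img[height // 5: height // 2, width // 6: width // 2] = 220.0
    y, x = np.mgrid[0:height, 0:width].astype(float)
    stripe = np.abs((x - 0.6 * width) - (y - 0.2 * height)) < max(3, height // 12)
    img[stripe] = np.maximum(img[stripe], 170.0)
    rng = np.random.default_rng(seed)
    img += rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
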