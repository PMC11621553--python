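"""Synthetic nuclear-calcium fluorescence traces, cohorts and image stacks.

The trace generator emulates an NR-GECO1-like intensiometric readout sampled
every 5 s for 10-15 min:

    F(t) = f0 * exp(-t / bleach_tau) * (1 + sum_k A_k * g(t - t_k)) + eps

where ``g`` is a stereotyped spike shape (linear rise over ``rise_samples``
samples to the apex, then exponential decay with time constant
``decay_tau``), spike apices ``t_k`` fall on the sampling grid, and
``eps ~ N(0, noise_sigma * f0)`` is additive detector noise.  Negative
intensities are clipped to zero, as a detector would.

Spike timing is a renewal process with a hard refractory gap: each
inter-spike interval is ``refractory + Exp(lam)`` with ``lam`` chosen so the
mean event rate equals ``spike_rate`` per 600 s exactly (the refractory dead
time is compensated, so the realised spike count matches
``spike_rate * duration / 600`` up to sampling error).

Everything is reproducible bit-for-bit from the integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError
from .imaging import ImageStack, ROIMask
from .traces import FluorescenceTrace


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a single simulated trace.

    Attributes
    ----------
    baseline_f0 : float
        Baseline fluorescence at t=0 (arbitrary units, > 0).
    bleach_tau : float
        Photobleaching time constant in seconds; ``inf`` disables bleaching.
    spike_amplitude : float
        Relative spike amplitude A >= 0: peak fractional increase over the
        local (bleached) baseline.
    decay_tau : float
        Spike exponential decay constant in seconds.
    rise_samples : int
        Samples of linear rise to the apex (>= 0; 0 = instantaneous).
    spike_rate : float
        Expected number of spikes per 600 s (>= 0).
    refractory : float
        Minimum gap between consecutive spike apices, seconds (>= 0).
    noise_sigma : float
        Gaussian noise SD as a fraction of ``baseline_f0`` (>= 0).
    duration : float
        Acquisition span in seconds (>= 7 * dt so an SNR point exists).
    dt : float
        Sampling interval in seconds (default 5).
    seed : int
        Seed of the trace's random stream.
    """

    baseline_f0: float = 100.0
    bleach_tau: float = math.inf
    spike_amplitude: float = 0.6
    decay_tau: float = 10.0
    rise_samples: int = 1
    spike_rate: float = 8.0
    refractory: float = 20.0
    noise_sigma: float = 0.02
    duration: float = 600.0
    dt: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.baseline_f0 <= 0:
            raise InvalidParameterError(f"baseline_f0 must be positive, got {self.baseline_f0}")
        if self.duration < 7 * self.dt:
            raise InvalidParameterError(
                f"duration {self.duration} s < 7*dt = {7 * self.dt} s: no SNR point would exist"
            )
        if self.spike_rate < 0 or self.refractory < 0:
            raise InvalidParameterError("spike_rate and refractory must be >= 0")
        if self.noise_sigma < 0 or self.spike_amplitude < 0:
            raise InvalidParameterError("noise_sigma and spike_amplitude must be >= 0")
        if self.decay_tau <= 0 or self.bleach_tau <= 0:
            raise InvalidParameterError("decay_tau and bleach_tau must be positive")
        if self.rise_samples < 0:
            raise InvalidParameterError("rise_samples must be >= 0")
        rate_per_s = self.spike_rate / 600.0
        if rate_per_s * self.refractory >= 1:
            raise InvalidParameterError(
                "spike_rate and refractory are incompatible: the refractory dead "
                "time alone exceeds the requested mean inter-spike interval"
            )


@dataclass
class GroundTruth:
    """Generator-side truth for one trace: apex times, amplitudes, clean trace."""

    spike_times: list[float]
    per_spike_amplitude: list[float]
    clean_trace: np.ndarray


@dataclass(frozen=True)
class CohortSpec:
    """A labelled cohort of nuclei with per-nucleus parameter variability.

    ``fraction_spiking`` of the nuclei receive a positive spike rate drawn
    from N(spike_rate_mean, spike_rate_sd) (clipped at a small positive
    floor); the remainder are generated with spike_rate = 0.  Per-nucleus
    amplitudes are drawn from N(amplitude_mean, amplitude_sd), clipped at 0.
    """

    group_label: str
    n_nuclei: int
    fraction_spiking: float = 0.9
    spike_rate_mean: float = 8.0
    spike_rate_sd: float = 1.0
    amplitude_mean: float = 0.6
    amplitude_sd: float = 0.05
    base: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 1:
            raise InvalidParameterError("n_nuclei must be >= 1")
        if not 0.0 <= self.fraction_spiking <= 1.0:
            raise InvalidParameterError("fraction_spiking must lie in [0, 1]")
        if self.spike_rate_sd < 0 or self.amplitude_sd < 0:
            raise InvalidParameterError("distribution SDs must be >= 0")
        if self.spike_rate_mean < 0 or self.amplitude_mean < 0:
            raise InvalidParameterError("distribution means must be >= 0")


def _draw_spike_indices(params: SimulationParams, rng: np.random.Generator) -> list[int]:
    """Apex sample indices of the dead-time-compensated renewal process."""
    n = int(math.floor(params.duration / params.dt)) + 1
    rate_per_s = params.spike_rate / 600.0
    if rate_per_s == 0:
        return []
    lam = rate_per_s / (1.0 - rate_per_s * params.refractory)
    min_gap = int(math.ceil(params.refractory / params.dt - 1e-9))
    indices: list[int] = []
    t = rng.exponential(1.0 / lam)
    while t <= params.duration:
        i = int(round(t / params.dt))
        if indices and i - indices[-1] < min_gap:
            i = indices[-1] + min_gap  # snapping shrank the gap below the floor
        if i <= n - 1 and (not indices or i > indices[-1]):
            indices.append(i)
        t += params.refractory + rng.exponential(1.0 / lam)
    return indices


def _spike_shape(n: int, apex: int, params: SimulationParams) -> np.ndarray:
    """Unit-amplitude spike waveform g on the sample grid, apex value 1."""
    g = np.zeros(n)
    r = params.rise_samples
    if r > 0:
        lo = max(0, apex - r)
        k = np.arange(lo, apex + 1)
        g[lo : apex + 1] = 1.0 - (apex - k) / r
    else:
        g[apex] = 1.0
    post = np.arange(apex + 1, n)
    if post.size:
        g[post] = np.exp(-(post - apex) * params.dt / params.decay_tau)
    return g


def simulate_trace(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    nucleus_id: str = "sim-0",
    group: str = "",
    stage: str = "",
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Generate one fluorescence trace and its ground truth.

    The trace has ``floor(duration/dt) + 1`` samples; spike apices are snapped
    to the sampling grid so the clean trace attains
    ``f0 * exp(-t_apex/bleach_tau) * (1 + A)`` exactly at each isolated apex.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(math.floor(params.duration / params.dt)) + 1
    t = np.arange(n) * params.dt
    apex_indices = _draw_spike_indices(params, rng)
    envelope = np.ones(n)
    for a in apex_indices:
        envelope += params.spike_amplitude * _spike_shape(n, a, params)
    bleach = np.exp(-t / params.bleach_tau) if math.isfinite(params.bleach_tau) else 1.0
    clean = params.baseline_f0 * bleach * envelope
    values = clean + rng.normal(0.0, params.noise_sigma * params.baseline_f0, size=n)
    np.clip(values, 0.0, None, out=values)
    trace = FluorescenceTrace(
        nucleus_id=nucleus_id, values=values, dt=params.dt, group=group, stage=stage
    )
    truth = GroundTruth(
        spike_times=[a * params.dt for a in apex_indices],
        per_spike_amplitude=[params.spike_amplitude] * len(apex_indices),
        clean_trace=clean,
    )
    return trace, truth


def simulate_cohort(spec: CohortSpec) -> list[tuple[FluorescenceTrace, GroundTruth]]:
    """Generate a cohort of nuclei under a shared parameter distribution.

    Exactly ``round(n_nuclei * fraction_spiking)`` nuclei receive a positive
    spike rate; the rest are generated with spike_rate = 0.  Per-nucleus
    parameters and noise derive reproducibly from ``spec.seed``.
    """
    spec.validate()
    spec.base.validate()
    rng = np.random.default_rng(spec.seed)
    n_spiking = int(round(spec.n_nuclei * spec.fraction_spiking))
    out = []
    for i in range(spec.n_nuclei):
        child = np.random.default_rng(rng.integers(0, 2**31))
        if i < n_spiking:
            rate = max(float(child.normal(spec.spike_rate_mean, spec.spike_rate_sd)), 0.1)
        else:
            rate = 0.0
        amp = max(float(child.normal(spec.amplitude_mean, spec.amplitude_sd)), 0.0)
        params = replace(spec.base, spike_rate=rate, spike_amplitude=amp)
        trace, truth = simulate_trace(
            params,
            rng=child,
            nucleus_id=f"{spec.group_label}-{i:03d}",
            group=spec.group_label,
        )
        out.append((trace, truth))
    return out


def simulate_stack(
    shape: tuple[int, int, int],
    background: float,
    foreground_regions: Sequence[tuple[np.ndarray, float | Sequence[float]]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    axis: str = "z",
) -> tuple[ImageStack, list[ROIMask]]:
    """Build a toy grayscale stack with known foreground regions.

    Parameters
    ----------
    shape : (n_slices, y, x)
        Stack shape; the leading axis is ``z`` or ``t`` per ``axis``.
    background : float
        Background intensity of every pixel.
    foreground_regions : sequence of (mask, intensities)
        ``mask`` is a boolean (y, x) array; ``intensities`` is a scalar or a
        per-slice sequence of length ``n_slices``.  Regions must not overlap.
    noise_sigma : float
        SD of additive Gaussian noise (intensity units).
    seed : int
        Noise seed; output is deterministic under (arguments, seed).

    Returns
    -------
    (ImageStack, list of ROIMask)
        The returned masks are the exact foreground ground truth.
    """
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise InvalidParameterError(f"shape must be 3 positive integers, got {shape}")
    if axis not in ("z", "t"):
        raise InvalidParameterError(f"leading axis must be 'z' or 't', got {axis!r}")
    n_slices, ny, nx = shape
    occupancy = np.zeros((ny, nx), dtype=bool)
    data = np.full(shape, float(background))
    masks: list[ROIMask] = []
    for mask, intens in foreground_regions:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise InvalidParameterError(
                f"foreground mask shape {mask.shape} does not match slice shape {(ny, nx)}"
            )
        if np.any(occupancy & mask):
            raise InvalidParameterError("foreground regions overlap")
        occupancy |= mask
        if np.ndim(intens) == 0:
            per_slice = np.full(n_slices, float(intens))
        else:
            per_slice = np.asarray(intens, dtype=float).ravel()
            if per_slice.size != n_slices:
                raise InvalidParameterError(
                    f"per-slice intensities must have length {n_slices}"
                )
        for k in range(n_slices):
            data[k][mask] = per_slice[k]
        masks.append(ROIMask(mask=mask.copy(), provenance="supplied"))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=shape)
        np.clip(data, 0.0, None, out=data)
    return ImageStack(data=data, axis=axis), masks
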