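"""Per-nucleus calcium-spiking metrics from fluorescence time series.

A nuclear calcium transient reported by an intensiometric sensor such as
NR-GECO1 appears as a sharp rise of the nuclear fluorescence ``F_t`` followed
by an exponential return to baseline.  The quantification implemented here
contrasts each time point with a *local* baseline

    B_t = (F_{t-15s} + F_{t-10s} + F_{t+10s} + F_{t+15s}) / 4

and expresses the excursion as a signal-to-noise ratio,

    SNR_t = (F_t - B_t) / B_t        (relative mode, default)
    SNR_t =  F_t - B_t               (absolute mode)

Because the window is symmetric, any affine trend (including the linear part
of slow photobleaching) is annihilated exactly.  Peaks are maximal runs of
consecutive samples with SNR >= theta (default 0.3); a nucleus is summarised
by its peak count, spiking frequency rescaled to a 10-minute window, and
amplitude defined as the mean of its peak (apex) SNR values.  A nucleus is
classified as *spiking* when its frequency exceeds 2 peaks per 10 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptySeriesError,
    InvalidParameterError,
    UndefinedSNRError,
    UnsupportedBatchError,
    UnsupportedSamplingError,
)

#: SNR threshold defining individual peaks.
DEFAULT_THETA = 0.3
#: Baseline window offsets, in seconds, on each side of the evaluated sample.
BASELINE_OFFSETS_S = (10.0, 15.0)
#: Reference window for frequency normalisation (peaks per 600 s).
FREQUENCY_WINDOW_S = 600.0
#: A nucleus is "spiking" when frequency (peaks per 600 s) strictly exceeds this.
SPIKING_FREQUENCY_CUTOFF = 2.0


@dataclass
class FluorescenceTrace:
    """One nucleus's fluorescence intensity time series at fixed sampling.

    Parameters
    ----------
    nucleus_id : str
        Identifier of the nucleus / region of interest.
    values : array-like of float
        Mean ROI fluorescence per frame, arbitrary units, finite and >= 0.
    dt : float, default 5.0
        Sampling interval in seconds.
    group, stage : str
        Free-text labels (e.g. genotype, and "RHE" / "IT" / cortex stage).
    """

    nucleus_id: str
    values: np.ndarray
    dt: float = 5.0
    group: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidParameterError("trace values must be a non-empty 1-D series")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("trace values must be finite")
        if np.any(self.values < 0):
            raise InvalidParameterError("trace values must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Observation span (N-1)*dt in seconds."""
        return (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class SNRSeries:
    """Baseline-subtracted signal derived from a trace.

    ``values[i]`` is the SNR at trace sample ``offset + i``; the first and
    last ``offset`` samples of the trace have no complete baseline window and
    carry no SNR value.
    """

    values: np.ndarray
    offset: int
    mode: str = "relative"
    theta: float = DEFAULT_THETA
    dt: float = 5.0

    def __len__(self) -> int:
        return int(self.values.size)

    def sample_index(self, i: int) -> int:
        """Map an index into :attr:`values` to the trace sample index."""
        return self.offset + i


@dataclass(frozen=True)
class Peak:
    """A maximal supra-threshold run of SNR samples.

    Indices refer to trace samples.  ``apex_index`` is the argmax of the SNR
    within the run (earliest sample on ties).
    """

    run_start: int
    run_end: int
    apex_index: int
    apex_snr: float


@dataclass
class NucleusSummary:
    """The per-nucleus readout: peak count, frequency, amplitude, spiking flag."""

    nucleus_id: str
    n_peaks: int
    duration_s: float
    frequency: float
    mean_peak_snr: Optional[float]
    spiking: bool
    group: str = ""
    stage: str = ""


def _baseline_offsets_in_samples(dt: float) -> tuple[int, int]:
    """Convert the ±10 s / ±15 s baseline offsets to sample counts."""
    offsets = []
    for off_s in BASELINE_OFFSETS_S:
        k = off_s / dt
        k_round = round(k)
        if not np.isclose(k, k_round, rtol=0, atol=1e-9) or k_round < 1:
            raise UnsupportedSamplingError(
                f"dt={dt} s cannot express a {off_s} s baseline offset as a whole "
                "number of samples"
            )
        offsets.append(int(k_round))
    return offsets[0], offsets[1]


def compute_snr(trace: FluorescenceTrace, mode: str = "relative") -> SNRSeries:
    """Compute the SNR series of a fluorescence trace.

    Parameters
    ----------
    trace : FluorescenceTrace
    mode : {"relative", "absolute"}
        ``relative`` returns (F_t - B_t) / B_t (scale-free, matching the
        fixed unitless peak threshold); ``absolute`` returns F_t - B_t.

    Returns
    -------
    SNRSeries
        Defined for trace samples ``k15 .. N-1-k15`` where ``k15 = 15/dt``
        (indices 3 .. N-4 at 5 s sampling).

    Raises
    ------
    EmptySeriesError
        If the trace is too short for any baseline window (N < 2*k15 + 1).
    UnsupportedSamplingError
        If 10/dt or 15/dt is not a whole number.
    UndefinedSNRError
        If a baseline value is zero under relative mode.
    """
    if mode not in ("relative", "absolute"):
        raise InvalidParameterError(f"unknown SNR mode {mode!r}")
    k10, k15 = _baseline_offsets_in_samples(trace.dt)
    f = trace.values
    n = f.size
    if n < 2 * k15 + 1:
        raise EmptySeriesError(
            f"trace of {n} samples has no full baseline window (need >= {2 * k15 + 1})"
        )
    m = n - 2 * k15  # number of defined SNR samples
    centre = slice(k15, n - k15)
    baseline = (
        f[k15 - k15 : k15 - k15 + m]          # t - 15 s
        + f[k15 - k10 : k15 - k10 + m]        # t - 10 s
        + f[k15 + k10 : k15 + k10 + m]        # t + 10 s
        + f[k15 + k15 : k15 + k15 + m]        # t + 15 s
    ) / 4.0
    signal = f[centre]
    if mode == "absolute":
        values = signal - baseline
    else:
        zero = np.flatnonzero(baseline == 0)
        if zero.size:
            raise UndefinedSNRError(
                f"baseline is zero at trace sample {int(zero[0]) + k15}; "
                "relative SNR undefined"
            )
        values = (signal - baseline) / baseline
    return SNRSeries(values=values, offset=k15, mode=mode, dt=trace.dt)


def detect_peaks(snr: SNRSeries, theta: Optional[float] = None) -> list[Peak]:
    """Call peaks as maximal runs of consecutive samples with SNR >= theta.

    Distinct peaks are separated by at least one sub-threshold sample.  Within
    each run the apex is the maximum, resolved to the earliest index on ties.
    An SNR series with no supra-threshold sample yields an empty list.
    """
    if theta is None:
        theta = snr.theta
    v = snr.values
    if v.size == 0:
        return []
    above = v >= theta
    peaks: list[Peak] = []
    # Run boundaries from the diff of the boolean mask.
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        run = v[start:stop]
        apex_local = int(np.argmax(run))  # argmax returns earliest max
        peaks.append(
            Peak(
                run_start=snr.sample_index(int(start)),
                run_end=snr.sample_index(int(stop) - 1),
                apex_index=snr.sample_index(int(start) + apex_local),
                apex_snr=float(run[apex_local]),
            )
        )
    return peaks


def summarize_nucleus(trace: FluorescenceTrace, peaks: Sequence[Peak]) -> NucleusSummary:
    """Summarise a nucleus from its detected peaks.

    Frequency is the peak count rescaled to a 600 s window using the
    observation span (N-1)*dt; amplitude (mean apex SNR) is absent when no
    peak was detected; the spiking flag is ``frequency > 2`` (strict).
    Non-spiking nuclei are retained so that they enter frequency statistics.
    """
    n_peaks = len(peaks)
    duration = trace.duration_s
    frequency = n_peaks * FREQUENCY_WINDOW_S / duration
    mean_peak_snr = float(np.mean([p.apex_snr for p in peaks])) if n_peaks else None
    return NucleusSummary(
        nucleus_id=trace.nucleus_id,
        n_peaks=n_peaks,
        duration_s=duration,
        frequency=frequency,
        mean_peak_snr=mean_peak_snr,
        spiking=frequency > SPIKING_FREQUENCY_CUTOFF,
        group=trace.group,
        stage=trace.stage,
    )


def analyze_trace(
    trace: FluorescenceTrace, mode: str = "relative", theta: float = DEFAULT_THETA
) -> NucleusSummary:
    """SNR -> peaks -> summary convenience for a single trace."""
    snr = compute_snr(trace, mode=mode)
    return summarize_nucleus(trace, detect_peaks(snr, theta=theta))


_SUMMARY_COLUMNS = [
    "group",
    "nucleus_id",
    "stage",
    "n_peaks",
    "duration_s",
    "frequency",
    "mean_peak_snr",
    "spiking",
]


def batch_summaries(
    traces: Iterable[FluorescenceTrace],
    mode: str = "relative",
    theta: float = DEFAULT_THETA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise a collection of traces.

    Returns
    -------
    (frequency_table, amplitude_table) : tuple of pandas.DataFrame
        The frequency table has one row per nucleus (zero-peak nuclei
        included, so the frequency n exceeds the amplitude n); the amplitude
        table keeps only nuclei with at least one detected peak, for which
        the mean peak SNR is defined.  Rows are ordered by (group,
        nucleus_id).

    Raises
    ------
    UnsupportedBatchError
        If traces do not share a sampling interval.
    """
    traces = list(traces)
    if traces:
        dts = {t.dt for t in traces}
        if len(dts) > 1:
            raise UnsupportedBatchError(f"mixed sampling intervals in batch: {sorted(dts)}")
    rows = []
    for t in traces:
        s = analyze_trace(t, mode=mode, theta=theta)
        rows.append(
            {
                "group": s.group,
                "nucleus_id": s.nucleus_id,
                "stage": s.stage,
                "n_peaks": s.n_peaks,
                "duration_s": s.duration_s,
                "frequency": s.frequency,
                "mean_peak_snr": s.mean_peak_snr,
                "spiking": s.spiking,
            }
        )
    freq = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    freq = freq.sort_values(["group", "nucleus_id"], kind="stable").reset_index(drop=True)
    amp = freq[freq["mean_peak_snr"].notna()].reset_index(drop=True)
    return freq, amp
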