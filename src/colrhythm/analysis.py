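"""Measurement layer: rates, irregularity, synchrony, spectra, latencies.

Population rates are computed on a 1 ms grid with a 200 ms sliding window
by default (truncated normalization at the edges). Spectra are Welch
estimates of the mean-subtracted population rate (2 s Hann segments, 50%
overlap by default) with the peak taken over the 5-100 Hz band, covering
the beta and gamma ranges of interest. Spike-train irregularity is the
coefficient of variation of inter-spike intervals; population synchrony
is the Golomb membrane-potential measure chi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dynamics import SpikeRecord
from .groups import GroupId


class AnalysisError(ValueError):
    """Signaled when a measure is undefined for the given data."""


@dataclass
class RateTrace:
    """Population mean firing rate (Hz) on a uniform ms grid."""

    group: GroupId | None
    times: np.ndarray  # ms
    rate: np.ndarray  # Hz, per-neuron population mean

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rate):
            raise ValueError("times and rate must be aligned")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0

    def restrict(self, t_start: float, t_end: float) -> "RateTrace":
        m = (self.times >= t_start) & (self.times < t_end)
        return RateTrace(self.group, self.times[m], self.rate[m])


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray
    peak_frequency: float  # Hz, argmax within the search band
    peak_power: float


def population_rate(
    spikes: SpikeRecord,
    group: GroupId,
    window: float = 200.0,
    step: float = 1.0,
) -> RateTrace:
    """Sliding-window population rate of one group, Hz per neuron.

    rate(t) = count of group spikes in [t - window/2, t + window/2) /
    (window * group size); window edges beyond the record are truncated
    and the normalization shortened accordingly.
    """
    if window < step:
        raise AnalysisError("window must be at least the step size")
    n_in_group = len(spikes.neurons_of_group(group))
    if n_in_group == 0:
        raise AnalysisError(f"group {group} has no neurons")
    t, _ = spikes.for_group(group)
    t0, t1 = spikes.t_start, spikes.t_start + spikes.duration
    grid = np.arange(t0, t1 + step / 2, step)
    # spike counts per step bin, then windowed sum
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    counts, _ = np.histogram(t, bins=edges)
    half = window / 2.0
    lo = np.clip(grid - half, t0, t1)
    hi = np.clip(grid + half, t0, t1)
    csum = np.concatenate([[0.0], np.cumsum(counts)])

    def bin_of(x):
        return np.clip(((x - (t0 - step / 2)) / step).astype(int), 0, len(counts))

    window_counts = csum[bin_of(hi)] - csum[bin_of(lo)]
    eff_window = np.maximum(hi - lo, step)  # ms, truncated at edges
    rate = window_counts / (eff_window * 1e-3) / n_in_group
    return RateTrace(group=group, times=grid, rate=rate)


def isi_cv(spikes: SpikeRecord, group: GroupId, min_spikes: int = 3):
    """Coefficient of variation of inter-spike intervals, per unit.

    Units with fewer than ``min_spikes`` spikes are excluded; returns
    (per-unit CVs, number of excluded units).
    """
    trains = spikes.spike_trains()
    members = set(spikes.neurons_of_group(group).tolist())
    cvs = []
    excluded = 0
    for nid in sorted(members):
        st = trains.get(nid)
        if st is None or len(st) < min_spikes:
            excluded += 1
            continue
        isi = np.diff(st)
        m = isi.mean()
        cvs.append(float(isi.std() / m) if m > 0 else np.nan)
    return np.array(cvs), excluded


def synchrony_chi(v_traces: np.ndarray) -> float:
    """Golomb synchrony measure from sampled membrane potentials.

    ``v_traces`` has shape (n_samples, n_neurons). chi^2 is the temporal
    variance of the population-mean voltage divided by the mean
    single-trace temporal variance; chi is 1 for identical traces and
    falls off as 1/sqrt(N) for independent ones.
    """
    v = np.asarray(v_traces, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise AnalysisError("need at least two membrane traces on a common grid")
    var_each = v.var(axis=0)
    denom = var_each.mean()
    if denom <= 0:
        raise AnalysisError("synchrony undefined for constant traces")
    num = v.mean(axis=1).var()
    return float(np.sqrt(num / denom))


def power_spectrum(
    trace: RateTrace,
    t_start: float | None = None,
    t_end: float | None = None,
    band: tuple[float, float] = (5.0, 100.0),
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> SpectrumResult:
    """Welch power spectrum of the mean-subtracted population rate.

    The peak frequency is the argmax of the estimate restricted to
    ``band`` (Hz). Requires at least one second of signal.
    """
    r = trace
    if t_start is not None or t_end is not None:
        r = trace.restrict(
            trace.times[0] if t_start is None else t_start,
            trace.times[-1] + trace.step if t_end is None else t_end,
        )
    dt_s = r.step * 1e-3
    total_s = len(r.rate) * dt_s
    if total_s < 1.0:
        raise AnalysisError("need at least 1 s of rate signal for a spectrum")
    fs = 1.0 / dt_s
    x = r.rate - r.rate.mean()
    nperseg = min(int(round(segment_s * fs)), len(x))
    f, p = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend=False,
    )
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise AnalysisError("frequency band empty at this resolution")
    k = np.argmax(p[in_band])
    return SpectrumResult(
        frequencies=f,
        power=p,
        peak_frequency=float(f[in_band][k]),
        peak_power=float(p[in_band][k]),
    )


def activation_latency(
    trace: RateTrace,
    stim_onset: float,
    baseline_window: float = 200.0,
) -> float:
    """Time (ms after onset) at which the rate first reaches half of its
    evoked maximum above baseline, linearly interpolated between grid
    points. Raises if no evoked increase is detectable."""
    t, r = trace.times, trace.rate
    base_mask = (t >= stim_onset - baseline_window) & (t < stim_onset)
    if base_mask.sum() < 2:
        raise AnalysisError("insufficient baseline before stimulus onset")
    baseline = r[base_mask].mean()
    base_sd = r[base_mask].std()
    after = t >= stim_onset
    if not np.any(after):
        raise AnalysisError("trace does not cover the stimulus onset")
    peak = r[after].max()
    if peak <= baseline + 3 * base_sd or peak <= baseline:
        raise AnalysisError("no evoked rate increase above baseline")
    half = baseline + 0.5 * (peak - baseline)
    ta, ra = t[after], r[after]
    above = np.nonzero(ra >= half)[0]
    k = above[0]
    if k == 0:
        return float(ta[0] - stim_onset)
    # linear interpolation between the bracketing grid points
    t_cross = ta[k - 1] + (half - ra[k - 1]) / (ra[k] - ra[k - 1]) * (ta[k] - ta[k - 1])
    return float(t_cross - stim_onset)


def rate_cross_correlation(
    trace_a: RateTrace, trace_b: RateTrace, max_lag: float = 100.0
):
    """Normalized cross-correlation of two rate traces over +-max_lag ms.

    Returns (lags_ms, correlogram, peak_value, peak_lag); positive peak
    lag means trace_b follows trace_a.
    """
    if len(trace_a.times) != len(trace_b.times) or trace_a.step != trace_b.step:
        raise AnalysisError("traces must share one time grid")
    a = trace_a.rate - trace_a.rate.mean()
    b = trace_b.rate - trace_b.rate.mean()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise AnalysisError("cross-correlation undefined for constant traces")
    n = len(a)
    max_k = int(round(max_lag / trace_a.step))
    max_k = min(max_k, n - 1)
    full = signal.correlate(b, a, mode="full") / (n * sa * sb)
    mid = n - 1
    sel = slice(mid - max_k, mid + max_k + 1)
    lags = np.arange(-max_k, max_k + 1) * trace_a.step
    cc = full[sel]
    k = int(np.argmax(np.abs(cc)))
    return lags, cc, float(cc[k]), float(lags[k])
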