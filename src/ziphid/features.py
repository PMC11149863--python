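"""Per-click metrics and per-cluster summary features.

Three feature families drive classification: spectral shape (peak frequency,
center frequency, mean cluster spectrum), waveform envelope and duration, and
clicking rate (the inter-click-interval distribution and its mode). Cluster
summaries average the min-max-normalized dB spectra and envelopes of member
clicks and histogram the ICIs up to 0.8 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .detector import ClickDetection, energy_bounds, smoothed_energy

__all__ = [
    "ClickMetrics",
    "ClusterSummary",
    "click_metrics",
    "ici_distribution",
    "cluster_summary",
    "norm01",
    "smoothed_envelope",
    "resample_envelope",
    "ICI_MAX_S",
    "ICI_BIN_S",
    "ENVELOPE_POINTS",
]

#: ICI histogram support (0, 0.8] s at 0.01-s bins — 80 bins
ICI_MAX_S = 0.8
ICI_BIN_S = 0.01
ICI_BINS = int(round(ICI_MAX_S / ICI_BIN_S))
#: fixed resampled length for envelope summaries
ENVELOPE_POINTS = 200
#: analysis band (kHz) for peak / center frequency
ANALYSIS_BAND_KHZ = (5.0, 100.0)
# sweep-rate estimator frames: 40 samples, 75% overlap
SWEEP_FRAME = 40
SWEEP_HOP = 10
SWEEP_NFFT = 256


def norm01(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant series maps to all zeros.
    Idempotent on series already spanning [0, 1]."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def smoothed_envelope(snippet: np.ndarray, width: int = 5) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal with a short moving-average
    smoothing."""
    env = np.abs(signal.hilbert(np.asarray(snippet, dtype=float)))
    if env.size >= width:
        env = np.convolve(env, np.ones(width) / width, mode="same")
    return env


def resample_envelope(env: np.ndarray, n: int = ENVELOPE_POINTS) -> np.ndarray:
    """Linear resampling of an envelope onto a fixed number of points."""
    env = np.asarray(env, dtype=float)
    if env.size == n:
        return env.copy()
    if env.size == 1:
        return np.full(n, env[0])
    src = np.linspace(0.0, 1.0, env.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, env)


@dataclass
class ClickMetrics:
    """Scalar descriptors of one click.

    ``peak_freq`` / ``center_freq`` in kHz within the analysis band,
    ``duration`` in microseconds, ``sweep_rate`` in kHz/ms (NaN when the
    snippet is too short for the frame-track estimator), ``envelope``
    normalized to [0, 1] at sample resolution.
    """

    peak_freq: float
    center_freq: float
    duration: float
    sweep_rate: float
    envelope: np.ndarray
    rl_pp: float
    sample_rate: float


def _sweep_rate(snippet: np.ndarray, sample_rate: float) -> float:
    """Least-squares slope (kHz/ms) of the per-frame spectral-argmax track."""
    x = np.asarray(snippet, dtype=float)
    if x.size < SWEEP_FRAME + SWEEP_HOP:
        return float("nan")
    starts = np.arange(0, x.size - SWEEP_FRAME + 1, SWEEP_HOP)
    if starts.size < 2:
        return float("nan")
    win = signal.windows.hann(SWEEP_FRAME, sym=False)
    frames = np.stack([x[s : s + SWEEP_FRAME] for s in starts]) * win
    spec = np.abs(np.fft.rfft(frames, n=SWEEP_NFFT, axis=1))
    freqs_khz = np.fft.rfftfreq(SWEEP_NFFT, d=1.0 / sample_rate) / 1e3
    track = freqs_khz[np.argmax(spec, axis=1)]
    t_ms = (starts + SWEEP_FRAME / 2.0) / sample_rate * 1e3
    slope, _ = np.polyfit(t_ms, track, 1)
    return float(slope)


def click_metrics(detection: ClickDetection, sample_rate: float | None = None) -> ClickMetrics:
    """Compute :class:`ClickMetrics` for a detection.

    Peak frequency is the spectral argmax and center frequency the linear-power
    spectral centroid, both within the 5-100 kHz analysis band. Duration comes
    from the detection's start/end times (the 70th-percentile energy bounds);
    for bare snippets without times it is re-derived from the energy bounds.
    """
    fs = sample_rate or detection.sample_rate
    spec_db = np.asarray(detection.spectrum, dtype=float)
    nfft = 2 * (spec_db.size - 1)
    freqs_khz = np.fft.rfftfreq(nfft, d=1.0 / fs) / 1e3
    band = (freqs_khz >= ANALYSIS_BAND_KHZ[0]) & (freqs_khz <= ANALYSIS_BAND_KHZ[1])
    fb = freqs_khz[band]
    sb = spec_db[band]
    peak = float(fb[np.argmax(sb)])
    power = 10 ** (sb / 10.0)
    center = float(np.sum(fb * power) / np.sum(power))

    if detection.end_time > detection.start_time:
        duration = (detection.end_time - detection.start_time) * 1e6
    else:
        s, e = energy_bounds(smoothed_energy(detection.snippet))
        duration = (e - s) / fs * 1e6

    env = detection.envelope
    if env is None or np.size(env) == 0:
        env = smoothed_envelope(detection.snippet)
    return ClickMetrics(
        peak_freq=peak,
        center_freq=center,
        duration=float(duration),
        sweep_rate=_sweep_rate(detection.snippet, fs),
        envelope=norm01(env),
        rl_pp=detection.rl_pp,
        sample_rate=fs,
    )


def ici_distribution(click_times: np.ndarray) -> tuple[np.ndarray, float]:
    """Inter-click-interval histogram over (0, 0.8] s and its modal value.

    Successive differences above 0.8 s (gaps between click trains, missed
    detections) are discarded. With fewer than two valid gaps the histogram is
    all zeros and the modal ICI is NaN (undefined). Input must be sorted
    ascending.
    """
    times = np.asarray(click_times, dtype=float)
    gaps = np.diff(times)
    if np.any(gaps < 0):
        raise ValueError("click times must be sorted ascending")
    valid = gaps[(gaps > 0) & (gaps <= ICI_MAX_S)]
    edges = np.linspace(0.0, ICI_MAX_S, ICI_BINS + 1)
    if valid.size < 2:
        return np.zeros(ICI_BINS), float("nan")
    hist, _ = np.histogram(valid, bins=edges)
    hist = hist.astype(float)
    hist /= hist.sum()
    mode = float(edges[np.argmax(hist)] + ICI_BIN_S / 2.0)
    return hist, mode


@dataclass
class ClusterSummary:
    """Summary features of a set of clicks within one time bin.

    ``mean_spectrum`` and ``mean_envelope`` are averages of per-click
    [0, 1]-normalized series (dB spectra; resampled smoothed envelopes);
    ``ici_distribution`` is a normalized histogram over (0, 0.8] s and
    ``modal_ici`` the center of its maximal bin (NaN when undefined).
    """

    mean_spectrum: np.ndarray
    mean_envelope: np.ndarray
    ici_distribution: np.ndarray
    modal_ici: float
    n_clicks: int
    freqs_khz: np.ndarray = field(default=None, repr=False)


def summary_from_arrays(
    spectra_db: np.ndarray,
    envelopes: np.ndarray,
    times: np.ndarray,
    freqs_khz: np.ndarray | None = None,
) -> ClusterSummary:
    """Build a :class:`ClusterSummary` from stacked per-click arrays
    (rows = clicks). Envelope rows must already be at the fixed resampled
    length."""
    spectra_db = np.atleast_2d(np.asarray(spectra_db, dtype=float))
    envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
    norm_spec = np.stack([norm01(row) for row in spectra_db])
    norm_env = np.stack([norm01(row) for row in envelopes])
    hist, mode = ici_distribution(np.sort(np.asarray(times, dtype=float)))
    return ClusterSummary(
        mean_spectrum=norm_spec.mean(axis=0),
        mean_envelope=norm_env.mean(axis=0),
        ici_distribution=hist,
        modal_ici=mode,
        n_clicks=spectra_db.shape[0],
        freqs_khz=freqs_khz,
    )


def cluster_summary(members: list[ClickDetection]) -> ClusterSummary:
    """Summary features over member clicks (order-independent).

    Each click's dB spectrum is min-max normalized before averaging; envelopes
    are resampled to a fixed length and likewise normalized; the ICI
    distribution is computed from the member start times.
    """
    if not members:
        raise ValueError("cluster_summary requires at least one member click")
    spectra = np.stack([m.spectrum for m in members])
    envelopes = np.stack([resample_envelope(m.envelope) for m in members])
    times = np.array([m.start_time for m in members])
    fs = members[0].sample_rate
    nfft = 2 * (spectra.shape[1] - 1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs) / 1e3
    return summary_from_arrays(spectra, envelopes, times, freqs_khz=freqs)
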