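"""Speech auditory-motor synchrony measurement.

The synchrony between a perceived syllable stream and concurrently produced
(whispered) speech is quantified by the phase-locking value (PLV) between
the two amplitude envelopes.  Envelopes are resampled to 100 Hz, band-pass
filtered around the syllable rate (3.5-5.5 Hz), and their instantaneous
phases extracted with the Hilbert transform.  The PLV over a window of T
samples is

    PLV = (1/T) | sum_t exp(i (theta1(t) - theta2(t))) |

computed in 5-s windows overlapping by 2 s (hop 3 s) and averaged across
complete windows, giving one value per stimulus block.

Participants are classified as high or low synchronizers by 1-D two-means
clustering of PLVs (optionally of a larger reference pool); the decision
threshold is the midpoint between the two cluster centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

ANALYSIS_RATE_HZ = 100.0
BAND_HZ = (3.5, 5.5)
WINDOW_S = 5.0
OVERLAP_S = 2.0
MIN_DURATION_S = 5.0


@dataclass(frozen=True)
class EnvelopeSignal:
    """Nonnegative amplitude envelope at a known sampling rate."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, float)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(x)):
            raise ValueError("envelope contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(np.asarray(self.samples)) / self.rate_hz


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped instantaneous phase in (-pi, pi] at the analysis rate."""

    theta: np.ndarray
    rate_hz: float = ANALYSIS_RATE_HZ

    def __post_init__(self) -> None:
        if len(np.asarray(self.theta)) == 0:
            raise ValueError("empty phase series")


@dataclass(frozen=True)
class PLVResult:
    window_plvs: np.ndarray
    mean_plv: float
    window_s: float = WINDOW_S
    overlap_s: float = OVERLAP_S
    t_per_window: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.window_plvs, float)
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("PLV outside [0, 1]")


@dataclass(frozen=True)
class Classification:
    threshold: float
    labels: tuple[str, ...]  # "high" / "low" per participant
    cluster_centers: tuple[float, float]


def _resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase rational resampling (antialiased, no phase distortion)."""
    if rate_in == rate_out:
        return x
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(10_000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def extract_phase(
    envelope: EnvelopeSignal,
    band_hz: tuple[float, float] = BAND_HZ,
    rate_hz: float = ANALYSIS_RATE_HZ,
) -> PhaseSeries:
    """Resample to 100 Hz, band-pass 3.5-5.5 Hz (zero phase), Hilbert phase.

    The band-pass is a 4th-order Butterworth applied forward-backward so that
    filtering adds no phase lag to the PLV.
    """
    if envelope.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"envelope too short ({envelope.duration_s:.2f} s); "
            f"minimum duration is {MIN_DURATION_S:.0f} s"
        )
    x = np.asarray(envelope.samples, float)
    x = _resample_to(x, envelope.rate_hz, rate_hz)
    x = x - np.mean(x)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=rate_hz, output="sos")
    x = signal.sosfiltfilt(sos, x)
    theta = np.angle(signal.hilbert(x))
    return PhaseSeries(theta=theta, rate_hz=rate_hz)


def _window_slices(n: int, rate: float, window_s: float, hop_s: float) -> list[slice]:
    t = int(round(window_s * rate))
    hop = int(round(hop_s * rate))
    if t <= 0 or hop <= 0:
        raise ValueError("window and hop must be positive")
    out = []
    start = 0
    while start + t <= n:
        out.append(slice(start, start + t))
        start += hop
    return out


def compute_plv(
    theta1: PhaseSeries,
    theta2: PhaseSeries,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
    hop_s: float | None = None,
) -> PLVResult:
    """Windowed phase-locking value between two phase series.

    Windows of ``window_s`` advance by ``window_s - overlap_s`` (the default
    reading of "5 s windows with 2 s overlap"); pass ``hop_s`` to override.
    Trailing partial windows are discarded; the mean is over complete windows.
    """
    t1 = np.asarray(theta1.theta, float)
    t2 = np.asarray(theta2.theta, float)
    if len(t1) != len(t2) or theta1.rate_hz != theta2.rate_hz:
        raise ValueError("phase series must share length and rate")
    if hop_s is None:
        hop_s = window_s - overlap_s
    slices = _window_slices(len(t1), theta1.rate_hz, window_s, hop_s)
    if not slices:
        raise ValueError("signal shorter than one analysis window")
    d = t1 - t2
    plvs = np.array([np.abs(np.mean(np.exp(1j * d[s]))) for s in slices])
    return PLVResult(
        window_plvs=plvs,
        mean_plv=float(np.mean(plvs)),
        window_s=window_s,
        overlap_s=window_s - hop_s,
        t_per_window=slices[0].stop - slices[0].start,
    )


def _erb_space(low_hz: float, high_hz: float, n: int) -> np.ndarray:
    # Glasberg & Moore ERB-rate scale
    ear_q, min_bw = 9.26449, 24.7
    lo = np.log(low_hz / ear_q + min_bw)
    hi = np.log(high_hz / ear_q + min_bw)
    return ear_q * (np.exp(np.linspace(lo, hi, n)) - min_bw / ear_q) - 0.0


def cochlear_envelope(
    waveform: np.ndarray,
    rate_hz: float,
    n_channels: int = 64,
    low_hz: float = 100.0,
    high_hz: float = 4000.0,
    summary: str = "mean",
) -> EnvelopeSignal:
    """Broadband envelope from a gammatone-style filterbank.

    The waveform is passed through ``n_channels`` ERB-spaced gammatone filters
    (100-4000 Hz), the magnitude envelope taken per channel (analytic signal),
    and channels averaged (or summed).
    """
    x = np.asarray(waveform, float)
    if x.size == 0:
        raise ValueError("empty audio")
    if rate_hz < 8000:
        raise ValueError("audio sampling rate must be at least 8 kHz")
    cfs = _erb_space(low_hz, min(high_hz, rate_hz / 2 * 0.95), n_channels)
    env = np.zeros_like(x)
    for cf in cfs:
        b, a = signal.gammatone(cf, "iir", fs=rate_hz)
        y = signal.lfilter(b, a, x)
        env += np.abs(signal.hilbert(y))
    if summary == "mean":
        env /= n_channels
    elif summary != "sum":
        raise ValueError("summary must be 'mean' or 'sum'")
    return EnvelopeSignal(samples=env, rate_hz=rate_hz)


def _two_means_1d(values: np.ndarray) -> tuple[float, float]:
    """Globally optimal 1-D two-means (squared Euclidean).

    In one dimension the optimal 2-clustering is a split of the sorted data,
    so scanning all n-1 split points (prefix sums) finds the exact k-means
    optimum deterministically — Lloyd iterations can stall in local optima
    even from extreme-point initialization.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    i = np.arange(1, n)  # split: v[:i] | v[i:]
    mean_lo = csum[:-1] / i
    mean_hi = (total - csum[:-1]) / (n - i)
    csq = np.cumsum(v**2)
    sse = (csq[:-1] - i * mean_lo**2) + (csq[-1] - csq[:-1] - (n - i) * mean_hi**2)
    best = int(np.argmin(sse))
    return float(mean_lo[best]), float(mean_hi[best])


def classify_synchronizers(
    plvs: np.ndarray,
    reference_plvs: np.ndarray | None = None,
) -> Classification:
    """High/low split by 1-D two-means on the PLV pool.

    The clustering runs on ``reference_plvs`` when provided (e.g. a larger
    normative pool), otherwise on ``plvs`` themselves; the threshold is the
    midpoint of the two cluster centers, and each participant is labeled
    high iff their PLV exceeds it (ties -> low).
    """
    plvs = np.asarray(plvs, float)
    pool = np.asarray(reference_plvs, float) if reference_plvs is not None else plvs
    if len(pool) < 4:
        raise ValueError("need at least 4 PLVs to cluster")
    if np.ptp(pool) == 0:
        raise ValueError("degenerate clustering: constant PLV pool")
    c_lo, c_hi = _two_means_1d(pool)
    threshold = (c_lo + c_hi) / 2.0
    labels = tuple("high" if p > threshold else "low" for p in plvs)
    return Classification(
        threshold=float(threshold),
        labels=labels,
        cluster_centers=(c_lo, c_hi),
    )


def plv_table(
    results: dict[str, PLVResult], block: str = "sss"
) -> pd.DataFrame:
    """Tidy per-window PLV table (participant, block, window, plv, mean_plv)."""
    rows = []
    for pid, res in results.items():
        for w, v in enumerate(np.asarray(res.window_plvs)):
            rows.append(
                {
                    "participant": pid,
                    "block": block,
                    "window": w,
                    "plv": float(v),
                    "mean_plv": res.mean_plv,
                }
            )
    return pd.DataFrame(rows)
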