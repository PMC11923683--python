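"""Input/output signal metrics for stimulus-response voltage recordings.

Everything here operates on :class:`Signal`, a uniformly sampled real-valued
series (volts or normalized audio amplitude).  The module covers the metrics
used to characterise how a proteinoid sample transforms a driving stimulus:
signal-to-noise ratio, Welch power spectral density, cross-correlation,
pointwise error metrics (RMSE/MAE/PSNR/Pearson), power at selected
frequencies, empirical frequency and impulse response, bispectrum (quadratic
phase coupling), short-time spectrogram and a paired t-test between the two
sample sequences.

Conventions
-----------
* "noise" is always ``output - input``.
* Positive cross-correlation lag means the output is delayed relative to the
  input.
* PSNR uses the input peak as reference: ``20*log10(max|input| / RMSE)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats


__all__ = [
    "Signal",
    "Spectrum",
    "CrossCorrelation",
    "FrequencyResponse",
    "Bispectrum",
    "MetricsReport",
    "snr_db",
    "welch_psd",
    "cross_correlation",
    "error_metrics",
    "power_at_frequencies",
    "frequency_response",
    "impulse_response",
    "bispectrum",
    "spectrogram",
    "paired_ttest",
    "metrics_report",
]


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : array-like
        Sample values (V, or dimensionless for normalized audio).
    sample_rate : float
        Sampling frequency in Hz.
    t0 : float, optional
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None) -> "Signal":
        """Read a two-column (time_s|index, value) CSV.

        If the first column is a time axis the sample rate is inferred from
        the median spacing; for an index column ``sample_rate`` must be given.
        """
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
        axis = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1].to_numpy(dtype=float)
        name = str(df.columns[0]).lower()
        if name.startswith("time"):
            dt = float(np.median(np.diff(axis)))
            if dt <= 0:
                raise ValueError(f"{path}: non-increasing time axis")
            return cls(values, sample_rate=1.0 / dt, t0=float(axis[0]))
        if sample_rate is None:
            raise ValueError("sample_rate required for index-based CSV")
        return cls(values, sample_rate=sample_rate)

    def to_csv(self, path) -> None:
        """Write the series as a ``time_s,value`` CSV."""
        pd.DataFrame({"time_s": self.times, "value": self.samples}).to_csv(
            path, index=False
        )


@dataclass
class Spectrum:
    """One-sided power spectral density estimate (units^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        """Integral of the PSD over frequency (~ signal variance)."""
        return float(np.trapezoid(self.power, self.frequencies))


@dataclass
class CrossCorrelation:
    """Full discrete cross-correlation of two signals."""

    lags: np.ndarray          # seconds
    values: np.ndarray
    normalized: bool

    @property
    def max_value(self) -> float:
        return float(self.values[np.argmax(np.abs(self.values))])

    @property
    def lag_at_max(self) -> float:
        """Lag (s) of the extremum; positive = output delayed vs input."""
        return float(self.lags[np.argmax(np.abs(self.values))])


@dataclass
class FrequencyResponse:
    """Empirical transfer estimate H(f) = S_xy / S_xx on a uniform grid."""

    frequencies: np.ndarray
    H: np.ndarray             # complex

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.H)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.H)


@dataclass
class Bispectrum:
    """Segment-averaged direct bispectrum magnitude over (f1, f2)."""

    frequencies: np.ndarray   # axis shared by f1 and f2
    magnitude: np.ndarray     # shape (nf, nf); entries with f1+f2 > Nyquist are 0

    def peak(self) -> tuple[float, float, float]:
        """Return (f1, f2, |B|) at the bispectral maximum."""
        i, j = np.unravel_index(np.argmax(self.magnitude), self.magnitude.shape)
        return (
            float(self.frequencies[i]),
            float(self.frequencies[j]),
            float(self.magnitude[i, j]),
        )


@dataclass
class MetricsReport:
    """All scalar input/output comparison metrics in one record."""

    mean_in: float
    sd_in: float
    mean_out: float
    sd_out: float
    snr_db: float
    rmse: float
    mae: float
    psnr_db: float
    pearson_r: float
    max_xcorr: float
    lag_at_max: float
    ttest_p: float
    power_at_freqs: dict[float, tuple[float, float]] = field(default_factory=dict)
    sample_rate: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "mean_in": self.mean_in,
            "sd_in": self.sd_in,
            "mean_out": self.mean_out,
            "sd_out": self.sd_out,
            "snr_db": self.snr_db,
            "rmse": self.rmse,
            "mae": self.mae,
            "psnr_db": self.psnr_db,
            "pearson_r": self.pearson_r,
            "max_xcorr": self.max_xcorr,
            "lag_at_max_s": self.lag_at_max,
            "ttest_p": self.ttest_p,
            "sample_rate_hz": self.sample_rate,
        }
        if self.power_at_freqs:
            d["power_at_frequencies"] = {
                f"{f:g}": {"input": pin, "output": pout}
                for f, (pin, pout) in self.power_at_freqs.items()
            }
        return d


# ---------------------------------------------------------------------------
# helpers


def _check_pair(x: Signal, y: Signal) -> None:
    if len(x) != len(y):
        raise ValueError(f"signal lengths differ: {len(x)} vs {len(y)}")
    if not math.isclose(x.sample_rate, y.sample_rate, rel_tol=1e-9):
        raise ValueError("signals must share a sample rate")


def default_nperseg(n: int) -> int:
    """Welch default segment: min(1024, n//4) rounded down to a power of two."""
    target = min(1024, max(n // 4, 2))
    return 1 << (target.bit_length() - 1)


# ---------------------------------------------------------------------------
# metrics


def snr_db(input: Signal, output: Signal) -> float:
    """Signal-to-noise ratio in dB.

    Signal power is the mean square of the input; noise is ``output - input``.
    Identical signals yield ``inf`` (zero noise power).
    """
    _check_pair(input, output)
    p_signal = float(np.mean(input.samples**2))
    p_noise = float(np.mean((output.samples - input.samples) ** 2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * math.log10(p_signal / p_noise)


def welch_psd(
    x: Signal,
    segment_length: int | None = None,
    overlap: int | None = None,
    window: str = "hann",
    detrend: str | bool = "constant",
) -> Spectrum:
    """Welch averaged-periodogram PSD (density scaling, one-sided)."""
    n = len(x)
    if segment_length is None:
        segment_length = default_nperseg(n)
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds signal length {n}")
    f, p = sps.welch(
        x.samples,
        fs=x.sample_rate,
        window=window,
        nperseg=segment_length,
        noverlap=overlap,
        detrend=detrend,
        scaling="density",
    )
    return Spectrum(f, p)


def cross_correlation(
    x: Signal, y: Signal, normalize: bool = True
) -> CrossCorrelation:
    """Full discrete cross-correlation of input x and output y.

    With ``normalize=True`` both signals are mean-removed and the result is
    divided by ``sqrt(sum(x^2) * sum(y^2))`` (coefficient normalization), so
    values lie in [-1, 1].  Positive lag means y is delayed relative to x.
    """
    _check_pair(x, y)
    a = x.samples.astype(float)
    b = y.samples.astype(float)
    if normalize:
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt(float(np.sum(a**2)) * float(np.sum(b**2)))
        if denom == 0.0:
            raise ValueError("cannot normalize: a signal has zero energy")
    # c[k] = sum_n b[n] a[n-k]; peak at k=d when b[n] = a[n-d]
    c = sps.correlate(b, a, mode="full")
    if normalize:
        c = c / denom
    lags = sps.correlation_lags(len(b), len(a), mode="full") / x.sample_rate
    return CrossCorrelation(lags=lags, values=c, normalized=normalize)


def error_metrics(input: Signal, output: Signal) -> tuple[float, float, float, float]:
    """Return (rmse, mae, psnr_db, pearson_r) for an input/output pair."""
    _check_pair(input, output)
    diff = output.samples - input.samples
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    peak = float(np.max(np.abs(input.samples)))
    if rmse == 0.0:
        psnr = float("inf")
    elif peak == 0.0:
        psnr = float("-inf")
    else:
        psnr = 20.0 * math.log10(peak / rmse)
    if np.std(input.samples) == 0.0 or np.std(output.samples) == 0.0:
        raise ValueError("Pearson correlation undefined for constant signal")
    r = float(stats.pearsonr(input.samples, output.samples).statistic)
    return rmse, mae, psnr, r


def power_at_frequencies(
    x: Signal, freqs, segment_length: int | None = None, **welch_kwargs
) -> np.ndarray:
    """Welch PSD evaluated at the nearest bin to each requested frequency."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyq = x.sample_rate / 2.0
    if np.any(freqs >= nyq):
        raise ValueError(f"requested frequency at or above Nyquist ({nyq} Hz)")
    spec = welch_psd(x, segment_length=segment_length, **welch_kwargs)
    idx = np.array([np.argmin(np.abs(spec.frequencies - f)) for f in freqs])
    return spec.power[idx]


def frequency_response(
    input: Signal,
    output: Signal,
    regularization: float = 1e-10,
    segment_length: int | None = None,
    overlap: int | None = None,
    window: str = "hann",
    detrend: str | bool = "constant",
) -> FrequencyResponse:
    """Empirical transfer function H(f) = S_xy(f) / S_xx(f).

    ``regularization`` adds ``eps * max(S_xx)`` to the denominator to keep the
    estimate finite where the input carries no power.
    """
    _check_pair(input, output)
    n = len(input)
    if segment_length is None:
        segment_length = default_nperseg(n)
    f, sxy = sps.csd(
        input.samples,
        output.samples,
        fs=input.sample_rate,
        window=window,
        nperseg=segment_length,
        noverlap=overlap,
        detrend=detrend,
    )
    _, sxx = sps.welch(
        input.samples,
        fs=input.sample_rate,
        window=window,
        nperseg=segment_length,
        noverlap=overlap,
        detrend=detrend,
    )
    H = sxy / (sxx + regularization * np.max(sxx))
    return FrequencyResponse(frequencies=f, H=H)


def impulse_response(H: FrequencyResponse | np.ndarray) -> np.ndarray:
    """Real time-domain kernel h from a one-sided transfer estimate.

    The grid must be uniform from 0 to Nyquist; the Hermitian extension is
    implicit in the inverse real FFT.
    """
    Hc = H.H if isinstance(H, FrequencyResponse) else np.asarray(H)
    if Hc.ndim != 1 or Hc.size < 2:
        raise ValueError("H must be a 1-D array on a uniform frequency grid")
    return np.fft.irfft(Hc, n=2 * (Hc.size - 1))


def bispectrum(
    x: Signal, segment_length: int, window: str | None = "hann"
) -> Bispectrum:
    """Direct (FFT-based) bispectrum estimate averaged over segments.

    B(f1, f2) = mean over segments of X(f1) X(f2) conj(X(f1+f2)); the returned
    magnitude is zero where f1 + f2 exceeds Nyquist.  Detects quadratic phase
    coupling: three tones at f1, f2, f1+f2 with locked phases produce a peak
    at (f1, f2) that vanishes when the phases are independent.
    """
    n = len(x)
    if n < 4 * segment_length:
        raise ValueError("signal must be at least 4 segments long")
    n_seg = n // segment_length
    segs = x.samples[: n_seg * segment_length].reshape(n_seg, segment_length)
    segs = segs - segs.mean(axis=1, keepdims=True)
    if window is not None:
        segs = segs * sps.get_window(window, segment_length)
    X = np.fft.fft(segs, axis=1)
    half = segment_length // 2
    acc = np.zeros((half, half), dtype=complex)
    i = np.arange(half)
    sum_idx = i[:, None] + i[None, :]
    valid = sum_idx <= half
    for s in range(n_seg):
        Xs = X[s]
        prod = Xs[:half, None] * Xs[None, :half]
        conj_term = np.where(valid, np.conj(Xs[np.minimum(sum_idx, half)]), 0.0)
        acc += prod * conj_term
    mag = np.abs(acc) / n_seg
    mag[~valid] = 0.0
    freqs = np.fft.fftfreq(segment_length, d=1.0 / x.sample_rate)[:half]
    return Bispectrum(frequencies=freqs, magnitude=mag)


def spectrogram(
    x: Signal, window_length: int, hop: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-windowed short-time Fourier magnitude.

    Returns (frequencies Hz, segment times s, magnitude[f, t]).
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    if window_length > len(x):
        raise ValueError("window longer than signal")
    win = sps.get_window("hann", window_length)
    stft = sps.ShortTimeFFT(win, hop=hop, fs=x.sample_rate, scale_to="magnitude")
    S = stft.stft(x.samples)
    t = stft.t(len(x))
    return stft.f, t, np.abs(S)


def paired_ttest(input: Signal, output: Signal) -> float:
    """Two-sided paired t-test p-value over the sample pairs.

    Degenerate cases: identical signals give p = 1; a nonzero constant
    difference (zero variance) gives p = 0.
    """
    _check_pair(input, output)
    if len(input) < 3:
        raise ValueError("need at least 3 sample pairs")
    d = output.samples - input.samples
    if np.std(d) == 0.0:
        return 1.0 if np.all(d == 0.0) else 0.0
    return float(stats.ttest_rel(output.samples, input.samples).pvalue)


def metrics_report(
    input: Signal, output: Signal, fib_freqs=(144.0, 233.0, 377.0, 610.0, 987.0)
) -> MetricsReport:
    """Compute the full comparison table for an input/output recording pair."""
    _check_pair(input, output)
    rmse, mae, psnr, r = error_metrics(input, output)
    xc = cross_correlation(input, output, normalize=True)
    powers: dict[float, tuple[float, float]] = {}
    usable = [f for f in fib_freqs if f < input.sample_rate / 2.0]
    if usable:
        pin = power_at_frequencies(input, usable)
        pout = power_at_frequencies(output, usable)
        powers = {float(f): (float(a), float(b)) for f, a, b in zip(usable, pin, pout)}
    return MetricsReport(
        mean_in=float(np.mean(input.samples)),
        sd_in=float(np.std(input.samples, ddof=1)),
        mean_out=float(np.mean(output.samples)),
        sd_out=float(np.std(output.samples, ddof=1)),
        snr_db=snr_db(input, output),
        rmse=rmse,
        mae=mae,
        psnr_db=psnr,
        pearson_r=r,
        max_xcorr=xc.max_value,
        lag_at_max=xc.lag_at_max,
        ttest_p=paired_ttest(input, output),
        power_at_freqs=powers,
        sample_rate=input.sample_rate,
    )
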