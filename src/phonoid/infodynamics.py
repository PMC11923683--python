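"""Histogram-based information measures for stimulus/response pairs.

Plug-in (maximum-likelihood) estimators built on equal-width histogram
binning: Shannon entropy, mutual information, transfer entropy with a
configurable history length, magnitude-squared coherence, the Shannon
capacity bound log2(1 + SNR), transfer efficiency, and band-limited variants
of MI/TE obtained by zero-phase Butterworth filtering before estimation.

All information quantities are in bits.  Plug-in estimates carry a positive
bias of roughly (n_bins - 1)**2 / (2 N ln 2) for MI under independence; an
optional Miller-Madow correction is available where that matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_metrics import Signal, default_nperseg

__all__ = [
    "InfoReport",
    "entropy_bits",
    "mutual_information",
    "channel_capacity_bound",
    "efficiency",
    "transfer_entropy",
    "band_limited_measure",
    "coherence",
    "normalized_mi_per_band",
    "info_report",
]

DEFAULT_BINS = 16


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index (0..n_bins-1) over the data range.

    A constant array maps to a single occupied bin.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros(x.size, dtype=np.intp)
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def _freedman_diaconis_bins(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return DEFAULT_BINS
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    span = float(np.max(x) - np.min(x))
    return max(1, int(math.ceil(span / width)))


def _resolve_bins(x: np.ndarray, n_bins) -> int:
    if n_bins == "fd":
        return _freedman_diaconis_bins(x)
    n = int(n_bins)
    if n < 1:
        raise ValueError("n_bins must be >= 1")
    return n


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-np.sum(p * np.log2(p)))


def entropy_bits(x, n_bins=DEFAULT_BINS) -> float:
    """Plug-in Shannon entropy of the equal-width binning of x, in bits."""
    x = np.asarray(x, dtype=float).ravel()
    nb = _resolve_bins(x, n_bins)
    counts = np.bincount(_bin_indices(x, nb), minlength=nb)
    return _entropy_from_counts(counts)


def mutual_information(
    x, y, n_bins=DEFAULT_BINS, miller_madow: bool = False
) -> float:
    """Plug-in mutual information I(X;Y) in bits from a 2-D histogram.

    Symmetric in (x, y) and nonnegative.  A constant input occupies one bin
    and yields 0 by convention.  ``miller_madow=True`` subtracts the
    first-order bias (m_occupied - 1) / (2 N ln 2) from each entropy term.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    nb = _resolve_bins(x, n_bins)
    if x.size < nb:
        raise ValueError("need at least n_bins samples")
    bx = _bin_indices(x, nb)
    by = _bin_indices(y, nb)
    joint = np.bincount(bx * nb + by, minlength=nb * nb).reshape(nb, nb)
    n = x.size
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    hxy = _entropy_from_counts(joint.ravel())
    if miller_madow:
        ln2 = math.log(2.0)
        hx += (np.count_nonzero(joint.sum(axis=1)) - 1) / (2.0 * n * ln2)
        hy += (np.count_nonzero(joint.sum(axis=0)) - 1) / (2.0 * n * ln2)
        hxy += (np.count_nonzero(joint) - 1) / (2.0 * n * ln2)
    return max(0.0, hx + hy - hxy)


def channel_capacity_bound(snr: float, scale: str = "db") -> float:
    """Shannon bound I_max = log2(1 + SNR_linear) in bits.

    ``scale`` is ``'db'`` (default) or ``'linear'``, stating how ``snr`` is
    given.
    """
    if scale == "db":
        snr_linear = 10.0 ** (snr / 10.0)
    elif scale == "linear":
        snr_linear = snr
    else:
        raise ValueError("scale must be 'db' or 'linear'")
    if snr_linear <= -1.0:
        raise ValueError("linear SNR must exceed -1")
    return math.log2(1.0 + snr_linear)


def efficiency(mi_bits: float, mi_max_bits: float) -> float:
    """Transfer efficiency eta = 100 * I / I_max, in percent."""
    if mi_max_bits <= 0:
        raise ValueError("mi_max_bits must be positive")
    return 100.0 * mi_bits / mi_max_bits


def transfer_entropy(x, y, n_bins=DEFAULT_BINS, history: int = 1) -> float:
    """Plug-in transfer entropy T_{X->Y} in bits.

    T_{X->Y} = sum p(y+, Y, X) log2[ p(y+ | Y, X) / p(y+ | Y) ] where Y and X
    are the ``history``-step pasts of y and x and y+ is the next y sample.
    Histogram-binned with equal-width bins per series; nonnegative up to
    estimator noise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if history < 1:
        raise ValueError("history must be >= 1")
    n = x.size
    if n < history + 2:
        raise ValueError("series too short for the requested history")
    nb = _resolve_bins(np.concatenate([x, y]), n_bins)
    bx = _bin_indices(x, nb)
    by = _bin_indices(y, nb)

    # encode the k-step pasts as base-nb integers
    k = history
    m = n - k  # number of (past, next) tuples
    ypast = np.zeros(m - 0, dtype=np.int64)
    xpast = np.zeros(m - 0, dtype=np.int64)
    for j in range(k):
        ypast = ypast * nb + by[j : j + m]
        xpast = xpast * nb + bx[j : j + m]
    ynext = by[k:].astype(np.int64)
    ypast = ypast[: ynext.size]
    xpast = xpast[: ynext.size]

    nY = nb**k
    code_full = (ynext * nY + ypast) * nY + xpast
    cnt_full = np.bincount(code_full)
    cnt_yY = np.bincount(ynext * nY + ypast)
    cnt_YX = np.bincount(ypast * nY + xpast)
    cnt_Y = np.bincount(ypast)

    te = 0.0
    N = float(ynext.size)
    nz = np.nonzero(cnt_full)[0]
    for code in nz:
        c = cnt_full[code]
        xp = code % nY
        rest = code // nY
        yp = rest % nY
        yn = rest // nY
        te += (c / N) * math.log2(
            (c * cnt_Y[yp]) / (cnt_YX[yp * nY + xp] * cnt_yY[yn * nY + yp])
        )
    return max(0.0, te)


def _design_band_filter(band, fs: float, order: int = 4):
    """Zero-phase Butterworth SOS for a (f_lo, f_hi) band.

    ``f_lo <= 0`` gives a low-pass at f_hi; ``f_hi`` of None (or >= Nyquist)
    gives a high-pass at f_lo.
    """
    f_lo, f_hi = band
    nyq = fs / 2.0
    if f_hi is not None and f_hi <= (f_lo or 0):
        raise ValueError(f"empty band {band}")
    lo_ok = f_lo is not None and f_lo > 0
    hi_ok = f_hi is not None and f_hi < nyq
    if lo_ok and hi_ok:
        return sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    if lo_ok:
        if f_lo >= nyq:
            raise ValueError(f"band edge {f_lo} Hz at or above Nyquist {nyq} Hz")
        return sps.butter(order, f_lo, btype="highpass", fs=fs, output="sos")
    if hi_ok:
        return sps.butter(order, f_hi, btype="lowpass", fs=fs, output="sos")
    return None  # whole-spectrum band: no filtering


def band_filter(x: Signal, band, order: int = 4) -> Signal:
    """Zero-phase (forward-backward) Butterworth band filter of a Signal."""
    sos = _design_band_filter(band, x.sample_rate, order)
    if sos is None:
        return x
    return Signal(sps.sosfiltfilt(sos, x.samples), x.sample_rate, x.t0)


def band_limited_measure(
    x: Signal,
    y: Signal,
    band,
    measure: str = "mi",
    n_bins=DEFAULT_BINS,
    history: int = 1,
) -> float:
    """MI or TE (bits) after zero-phase band-pass filtering both signals."""
    if measure not in ("mi", "te"):
        raise ValueError("measure must be 'mi' or 'te'")
    xf = band_filter(x, band)
    yf = band_filter(y, band)
    if measure == "mi":
        return mutual_information(xf.samples, yf.samples, n_bins=n_bins)
    return transfer_entropy(xf.samples, yf.samples, n_bins=n_bins, history=history)


def coherence(
    x: Signal, y: Signal, segment_length: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence gamma^2(f) in [0, 1] via Welch.

    The default segment length guarantees at least 8 averaged segments (a
    single segment would give the degenerate gamma^2 == 1 and is an error).
    """
    if len(x) != len(y):
        raise ValueError("signals must have equal length")
    n = len(x)
    if segment_length is None:
        # largest power of two giving >= 8 segments at 50% overlap
        segment_length = 1 << max(1, int(math.floor(math.log2(n / 4.5))))
    n_segments = max(0, (n - segment_length) // max(segment_length // 2, 1) + 1)
    if n_segments < 2:
        raise ValueError(
            f"segment_length {segment_length} yields {n_segments} segment(s); "
            "coherence needs >= 2 (degenerate at 1)"
        )
    f, c = sps.coherence(
        x.samples, y.samples, fs=x.sample_rate, nperseg=segment_length
    )
    return f, c


def normalized_mi_per_band(
    x: Signal, y: Signal, bands, n_bins=DEFAULT_BINS
) -> list[float]:
    """I_norm(band) = I(X_f; Y_f) / H(X_f) for each frequency band.

    X_f, Y_f are the band-filtered signals; MI and the input marginal entropy
    come from the same histogram binning.  NaN flags a band where the
    filtered input is constant (H = 0).
    """
    out = []
    for band in bands:
        xf = band_filter(x, band)
        yf = band_filter(y, band)
        h = entropy_bits(xf.samples, n_bins=n_bins)
        if h == 0.0:
            out.append(float("nan"))
            continue
        out.append(mutual_information(xf.samples, yf.samples, n_bins=n_bins) / h)
    return out


@dataclass
class InfoReport:
    """Information-theoretic summary of one stimulus/response pair."""

    mi_bits: float
    mi_max_bits: float
    efficiency_percent: float
    te_bits_per_band: dict[str, float] = field(default_factory=dict)
    normalized_mi_per_band: dict[str, float] = field(default_factory=dict)
    coherence_freqs: np.ndarray | None = None
    coherence: np.ndarray | None = None
    n_bins: int = DEFAULT_BINS

    def to_dict(self) -> dict:
        d = {
            "mi_bits": self.mi_bits,
            "mi_max_bits": self.mi_max_bits,
            "efficiency_percent": self.efficiency_percent,
            "te_bits_per_band": self.te_bits_per_band,
            "normalized_mi_per_band": self.normalized_mi_per_band,
            "n_bins": self.n_bins,
        }
        if self.coherence is not None:
            d["coherence"] = {
                "frequencies_hz": np.asarray(self.coherence_freqs).tolist(),
                "gamma_squared": np.asarray(self.coherence).tolist(),
            }
        return d


def _band_label(band) -> str:
    lo, hi = band
    lo_s = f"{lo:g}" if lo else "0"
    return f"{lo_s}-{hi:g}Hz" if hi is not None else f">{lo:g}Hz"


def info_report(
    x: Signal,
    y: Signal,
    bands=((0.0, 10.0), (30.0, 50.0), (100.0, None)),
    n_bins=DEFAULT_BINS,
    include_coherence: bool = True,
) -> InfoReport:
    """Full information summary: MI, capacity bound, efficiency, banded TE,
    banded normalized MI and coherence."""
    from .signal_metrics import snr_db as _snr_db

    mi = mutual_information(x.samples, y.samples, n_bins=n_bins)
    snr = _snr_db(x, y)
    mi_max = channel_capacity_bound(snr, scale="db") if math.isfinite(snr) else float("inf")
    eta = efficiency(mi, mi_max) if math.isfinite(mi_max) and mi_max > 0 else float("nan")
    usable = [b for b in bands if (b[0] or 0) < x.sample_rate / 2.0]
    te = {
        _band_label(b): band_limited_measure(x, y, b, measure="te", n_bins=n_bins)
        for b in usable
    }
    nmi_vals = normalized_mi_per_band(x, y, usable, n_bins=n_bins)
    nmi = {_band_label(b): v for b, v in zip(usable, nmi_vals)}
    cf = cv = None
    if include_coherence:
        try:
            cf, cv = coherence(x, y)
        except ValueError:
            pass
    return InfoReport(
        mi_bits=mi,
        mi_max_bits=mi_max,
        efficiency_percent=eta,
        te_bits_per_band=te,
        normalized_mi_per_band=nmi,
        coherence_freqs=cf,
        coherence=cv,
        n_bins=n_bins if isinstance(n_bins, int) else DEFAULT_BINS,
    )
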