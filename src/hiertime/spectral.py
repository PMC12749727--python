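"""Timescale estimation from activity spectra.

The resting-state timescale of an area is read off the aperiodic component
of its power spectrum.  The PSD (Welch, 1-s Hamming windows, 0.5-s
overlap) is parameterized as a Lorentz function plus Gaussian peaks in
log-power:

    L(f) = A / (k + f^chi)

The bend ("knee") of L sits at f_knee = k^(1/chi) and corresponds to the
decay time constant tau = 1 / (2 pi f_knee).  For an Ornstein-Uhlenbeck
process the spectrum is exactly Lorentzian with chi = 2 and knee at
1/(2 pi tau), which is the calibration case for the estimator.

Post-stimulus timescales are instead fitted directly in the time domain as
r(t) = a exp(-t / tau_tilde) on the decay after the response peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "SpectralConfig",
    "SpectralFit",
    "ExpDecayFit",
    "welch_psd",
    "fit_aperiodic",
    "estimate_timescales",
    "fit_exp_decay",
]


@dataclass
class SpectralConfig:
    window_s: float = 1.0
    overlap_fraction: float = 0.5
    taper: str = "hamming"
    fit_range_hz: tuple[float, float] = (0.5, 80.0)
    max_peaks: int = 4
    peak_width_bounds_hz: tuple[float, float] = (0.5, 12.0)
    peak_threshold_sd: float = 2.5  # residual SDs above the aperiodic fit
    freq_weight_exp: float = 0.25  # residuals weighted by f^-exp: on a linear
    # frequency grid this rebalances leverage toward the knee region, which
    # holds few bins but all the timescale information

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.fit_range_hz[0] <= 0 or self.fit_range_hz[1] <= self.fit_range_hz[0]:
            raise ValueError("invalid fit range")


@dataclass
class SpectralFit:
    """Aperiodic (Lorentz) spectral parameterization A/(k + f^chi).

    ``f_knee`` and ``tau`` are derived, never stored: f_knee = k^(1/chi) Hz
    and tau = 1/(2 pi f_knee) seconds.  ``knee_defined`` is False when the
    fitted knee falls outside the fit range, in which case tau is
    unreliable and reported as None by the table-level estimators.
    """

    A: float
    k: float
    chi: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    fit_error: float = np.nan  # RMSE in log10 power
    fit_range_hz: tuple[float, float] = (0.5, 80.0)

    @property
    def f_knee(self) -> float:
        return self.k ** (1.0 / self.chi)

    @property
    def tau(self) -> float:
        return 1.0 / (2.0 * np.pi * self.f_knee)

    @property
    def knee_defined(self) -> bool:
        return self.fit_range_hz[0] <= self.f_knee <= self.fit_range_hz[1]


@dataclass
class ExpDecayFit:
    a: float
    tau_tilde: float  # ms
    window: tuple[float, float]
    fit_error: float

    def __post_init__(self) -> None:
        if self.tau_tilde <= 0:
            raise ValueError("tau_tilde must be positive")


def welch_psd(
    series: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD; multiple channels (rows) are averaged.

    Windows are ``window_s`` seconds long with ``overlap_fraction`` overlap
    and the configured taper (Hamming by default).
    """
    cfg = cfg or SpectralConfig()
    series = np.atleast_2d(np.asarray(series, dtype=float))
    nperseg = int(round(cfg.window_s * fs))
    if series.shape[1] < 2 * nperseg - int(nperseg * cfg.overlap_fraction):
        raise ValueError("series shorter than two Welch windows")
    noverlap = int(round(nperseg * cfg.overlap_fraction))
    freqs, psd = signal.welch(
        series, fs=fs, window=cfg.taper, nperseg=nperseg, noverlap=noverlap,
        axis=-1, detrend="constant",
    )
    return freqs, psd.mean(axis=0)


def _lorentz_log10(theta: np.ndarray, f: np.ndarray) -> np.ndarray:
    log10A, log10k, chi = theta
    return log10A - np.log10(10.0**log10k + f**chi)


def _gauss_log10(peaks: np.ndarray, f: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for ctr, height, width in peaks.reshape(-1, 3):
        out += height * np.exp(-0.5 * ((f - ctr) / width) ** 2)
    return out


def _fit_lorentz(
    f: np.ndarray, logp: np.ndarray, theta0: np.ndarray, w: np.ndarray
) -> np.ndarray:
    res = optimize.least_squares(
        lambda th: w * (_lorentz_log10(th, f) - logp),
        theta0,
        bounds=([-np.inf, -4.0, 0.25], [np.inf, 8.0, 5.0]),
        loss="huber",
        f_scale=0.3,
        max_nfev=2000,
    )
    return res.x


def fit_aperiodic(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig | None = None
) -> SpectralFit:
    """Iterative Lorentz + Gaussian-peak decomposition of a PSD.

    The Lorentz aperiodic component is fitted in log10-power against linear
    frequency with a robust (Huber) loss; residual peaks above
    ``peak_threshold_sd`` residual SDs are fitted as Gaussians, and the
    aperiodic component is refitted with the peak bands (within 3 fitted
    widths of each center) masked out, iterating to convergence.  Masking
    rather than subtracting the peak model keeps imperfections of the peak
    shape from biasing the knee.
    """
    cfg = cfg or SpectralConfig()
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = cfg.fit_range_hz
    sel = (freqs >= lo) & (freqs <= hi)
    f = freqs[sel]
    p = psd[sel]
    if f.size < 5:
        raise ValueError("fewer than 5 frequency bins in the fit range")
    if np.any(p <= 0):
        raise ValueError("PSD must be positive on the fit range")
    logp = np.log10(p)

    # initialization: chi=2; k from the frequency where power halves
    p0 = p[0]
    below = np.flatnonzero(p <= p0 / 2)
    f_half = f[below[0]] if below.size else f[len(f) // 2]
    k0 = max(f_half**2, 1e-3)
    A0 = p0 * (k0 + f[0] ** 2)
    theta = np.array([np.log10(A0), np.log10(k0), 2.0])

    w = f ** (-cfg.freq_weight_exp)
    w /= w.mean()
    peaks = np.empty((0, 3))
    for _ in range(3):
        mask = np.ones_like(f, dtype=bool)
        for ctr, _height, width in peaks:
            mask &= np.abs(f - ctr) > 3 * width
        if mask.sum() < 5:
            mask = np.ones_like(f, dtype=bool)
        theta = _fit_lorentz(f[mask], logp[mask], theta, w[mask])
        resid = logp - _lorentz_log10(theta, f) - _gauss_log10(peaks, f)
        sd = float(np.std(resid))
        if sd == 0:
            break
        idx, props = signal.find_peaks(resid, height=cfg.peak_threshold_sd * sd)
        if idx.size == 0 or peaks.shape[0] >= cfg.max_peaks:
            break
        order = np.argsort(props["peak_heights"])[::-1]
        new = []
        for j in idx[order][: cfg.max_peaks - peaks.shape[0]]:
            new.append([f[j], resid[j], 1.0])
        guess = np.vstack([peaks, np.array(new)])
        wlo, whi = cfg.peak_width_bounds_hz
        m = guess.shape[0]
        lb = np.tile([lo, 0.0, wlo], m)
        ub = np.tile([hi, np.inf, whi], m)
        base = _lorentz_log10(theta, f)
        try:
            res = optimize.least_squares(
                lambda th: base + _gauss_log10(th, f) - logp,
                np.clip(guess.ravel(), lb + 1e-9, ub - 1e-9),
                bounds=(lb, ub),
                max_nfev=2000,
            )
            peaks = res.x.reshape(-1, 3)
        except Exception:
            break

    resid = logp - _lorentz_log10(theta, f) - _gauss_log10(peaks, f)
    log10A, log10k, chi = theta
    return SpectralFit(
        A=10.0**log10A,
        k=10.0**log10k,
        chi=float(chi),
        peaks=[tuple(pk) for pk in peaks],
        fit_error=float(np.sqrt(np.mean(resid**2))),
        fit_range_hz=cfg.fit_range_hz,
    )


def estimate_timescales(
    series: np.ndarray,
    fs: float,
    channel_map: list[str] | dict[int, str],
    cfg: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Per-area timescale table from multichannel activity.

    ``channel_map`` assigns each channel (row of ``series``) to an area;
    channels sharing an area have their PSDs averaged before fitting.
    Returns a DataFrame (area, tau_ms, f_knee_hz, chi, fit_error,
    n_channels); areas whose knee is undefined get tau_ms = NaN rather
    than being dropped.
    """
    cfg = cfg or SpectralConfig()
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if isinstance(channel_map, dict):
        channel_map = [channel_map[i] for i in range(series.shape[0])]
    if len(channel_map) != series.shape[0]:
        raise ValueError("channel_map must cover all channels")
    areas: list[str] = list(dict.fromkeys(channel_map))
    rows = []
    for area in areas:
        chans = [i for i, a in enumerate(channel_map) if a == area]
        if not chans:
            raise ValueError(f"no channels mapped to area {area!r}")
        freqs, psd = welch_psd(series[chans], fs, cfg)
        fit = fit_aperiodic(freqs, psd, cfg)
        rows.append(
            {
                "area": area,
                "tau_ms": fit.tau * 1000.0 if fit.knee_defined else np.nan,
                "f_knee_hz": fit.f_knee,
                "chi": fit.chi,
                "fit_error": fit.fit_error,
                "n_channels": len(chans),
            }
        )
    return pd.DataFrame(rows)


def fit_exp_decay(
    trace: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] | None = None,
) -> ExpDecayFit:
    """Fit r(t) = a exp(-t / tau_tilde) to a post-peak decay (times in ms).

    The window defaults to [time of max, end].  A log-linear least-squares
    fit is used when the samples are positive; otherwise a nonlinear fit.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    i_max = int(np.argmax(trace))
    if window is None:
        window = (times[i_max], times[-1])
    if window[0] < times[i_max] - 1e-9:
        raise ValueError("window must start at or after the trace maximum")
    sel = (times >= window[0]) & (times <= window[1])
    t = times[sel] - window[0]
    y = trace[sel]
    if t.size < 5:
        raise ValueError("need at least 5 samples in the fit window")
    if np.ptp(y) == 0:
        raise ValueError("constant trace: no decay to fit")

    pos = y > 0
    if pos.sum() >= t.size / 2 and pos.sum() >= 5:
        coef = np.polyfit(t[pos], np.log(y[pos]), 1)
        slope, intercept = coef[0], coef[1]
        if slope >= 0:
            raise ValueError("trace does not decay over the window")
        a0, tau0 = float(np.exp(intercept)), float(-1.0 / slope)
    else:
        a0, tau0 = float(max(y.max(), 1e-12)), float(max(t[-1] / 3.0, 1.0))

    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t, y, p0=(a0, tau0), maxfev=5000,
            bounds=((0, 1e-6), (np.inf, np.inf)),
        )
        a_fit, tau_fit = float(popt[0]), float(popt[1])
    except Exception:
        a_fit, tau_fit = a0, tau0
    if tau_fit <= 0 or not np.isfinite(tau_fit):
        raise ValueError("degenerate exponential fit")
    resid = y - a_fit * np.exp(-t / tau_fit)
    return ExpDecayFit(
        a=a_fit, tau_tilde=tau_fit, window=(float(window[0]), float(window[1])),
        fit_error=float(np.sqrt(np.mean(resid**2))),
    )
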