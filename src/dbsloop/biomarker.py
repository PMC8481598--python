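"""Feedback and evaluation signals derived from population voltages.

The local field potential (LFP) of a nucleus is the arithmetic mean of its
membrane potentials.  The feedback biomarker is the beta-band (13–30 Hz)
power of the GPi LFP, estimated with a sliding-window multitaper spectrum
(1 s windows, 0.1 s step, time-bandwidth product 3, 5 DPSS tapers) and
reported in decibels.

dB convention: beta power is the one-sided multitaper PSD integrated over
the band (PSD bins × bin width, units mV²), converted as 10·log₁₀(P/1 mV²)
plus a fixed calibration offset.  The default offset (+120 dB) places the
healthy-state setpoint of the shipped network on the ~120 dB display scale
customary for analyses of this biomarker; it is a pure display convention
and cancels from every error, gain and RMSE computation carried out on the
dB scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .model import ConfigError

__all__ = [
    "SpectralConfig",
    "BetaPowerSeries",
    "SynchronyReport",
    "compute_lfp",
    "beta_power",
    "multitaper_psd",
    "bandpass_beta",
    "detect_spikes",
    "firing_rate",
    "synchrony_chi",
    "rmse",
]

#: calibration offset (dB) aligning the package's mV²-referenced band power
#: with the customary display scale for this biomarker
DEFAULT_CALIBRATION_DB = 120.0


@dataclass(frozen=True)
class SpectralConfig:
    """Sliding-window multitaper settings for beta-band power."""

    window_length: float = 1.0   # s
    step: float = 0.1            # s
    time_bandwidth: float = 3.0  # NW
    n_tapers: int = 5            # K <= 2*NW − 1
    band: tuple[float, float] = (13.0, 30.0)  # Hz
    sample_rate: float = 1000.0  # Hz of the analysed series
    power_scale: str = "dB"      # "dB" | "linear"
    calibration_db: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self):
        if not (0 < self.step <= self.window_length):
            raise ConfigError("require 0 < step <= window_length")
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ConfigError("n_tapers must be <= 2*time_bandwidth - 1")
        lo, hi = self.band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ConfigError("band must lie within (0, Nyquist)")
        if self.power_scale not in ("dB", "linear"):
            raise ConfigError("power_scale must be 'dB' or 'linear'")


@dataclass
class BetaPowerSeries:
    """Beta-band power per sliding window, indexed by window-center time."""

    times: np.ndarray            # s
    power: np.ndarray            # dB (or linear, per config)
    config_echo: SpectralConfig = field(default_factory=SpectralConfig)

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class SynchronyReport:
    """Golomb-style population synchrony χ = σ²_V / mean_i σ²_{v_i}."""

    nucleus: str
    chi: float
    population_variance: float       # mV²
    mean_individual_variance: float  # mV²


def compute_lfp(v_traces: np.ndarray) -> np.ndarray:
    """Population LFP: pointwise mean over neurons of an (n, T) voltage array."""
    v = np.asarray(v_traces, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ConfigError("v_traces must be a nonempty (neurons, time) array")
    return v.mean(axis=0)


@lru_cache(maxsize=8)
def _dpss_cached(N: int, nw: float, k: int) -> np.ndarray:
    return signal.windows.dpss(N, nw, Kmax=k, sym=False)


def multitaper_psd(x: np.ndarray, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD (mV²/Hz) of a single demeaned window.

    Averages direct spectral estimates under unit-energy DPSS tapers; the
    one-sided density satisfies Σ PSD·df ≈ var(x) (Parseval).
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    fs = cfg.sample_rate
    tapers = _dpss_cached(N, cfg.time_bandwidth, cfg.n_tapers)
    x = x - x.mean()
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    psd[1:-1] *= 2.0  # one-sided (DC and Nyquist unscaled)
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    return freqs, psd


def band_power(x: np.ndarray, cfg: SpectralConfig) -> float:
    """Integrated band power (mV²) of one window: Σ PSD bins × bin width."""
    freqs, psd = multitaper_psd(x, cfg)
    df = freqs[1] - freqs[0]
    lo, hi = cfg.band
    sel = (freqs >= lo) & (freqs <= hi)
    return float(psd[sel].sum() * df)


def _to_scale(p: float, cfg: SpectralConfig) -> float:
    if cfg.power_scale == "linear":
        return p
    return 10.0 * np.log10(max(p, 1e-300)) + cfg.calibration_db


def beta_power(lfp: np.ndarray, cfg: SpectralConfig | None = None) -> BetaPowerSeries:
    """Sliding-window beta-band power of an LFP sampled at cfg.sample_rate.

    Windows of ``window_length`` advance by ``step``; each is demeaned and
    multitaper-estimated; the band power is the PSD integrated over
    ``band``.  Times are window centers.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(lfp, dtype=float)
    nwin = int(round(cfg.window_length * cfg.sample_rate))
    nstep = int(round(cfg.step * cfg.sample_rate))
    if x.size < nwin:
        raise ConfigError("LFP shorter than one spectral window")
    starts = np.arange(0, x.size - nwin + 1, nstep)
    times = (starts + nwin / 2.0) / cfg.sample_rate
    power = np.array([_to_scale(band_power(x[s:s + nwin], cfg), cfg)
                      for s in starts])
    return BetaPowerSeries(times=times, power=power, config_echo=cfg)


def window_beta_power(x: np.ndarray, cfg: SpectralConfig | None = None) -> float:
    """Beta power (on the configured scale) of a single trailing window."""
    cfg = cfg or SpectralConfig()
    nwin = int(round(cfg.window_length * cfg.sample_rate))
    x = np.asarray(x, dtype=float)
    if x.size < nwin:
        raise ConfigError("LFP shorter than one spectral window")
    return _to_scale(band_power(x[-nwin:], cfg), cfg)


def bandpass_beta(lfp: np.ndarray, band: tuple[float, float] = (13.0, 30.0),
                  sample_rate: float = 1000.0, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass of the LFP (4th-order Butterworth, filtfilt)."""
    lo, hi = band
    if not (0 < lo < hi < sample_rate / 2):
        raise ConfigError("band must lie within (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(lfp, dtype=float))


def detect_spikes(v: np.ndarray, dt: float, threshold: float = -20.0,
                  lockout: float = 1.0) -> np.ndarray:
    """Upward threshold-crossing times (ms) of one voltage trace.

    ``dt`` is the sample spacing in ms; crossings within ``lockout`` ms of
    the previous detection are suppressed.
    """
    v = np.asarray(v, dtype=float)
    above = v >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if idx.size == 0:
        return np.zeros(0)
    times = idx * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= lockout:
            kept.append(t)
    return np.asarray(kept)


def firing_rate(spike_times: list[np.ndarray] | np.ndarray,
                duration: float) -> tuple[np.ndarray, float]:
    """Per-neuron firing rates (Hz) and the population mean.

    ``duration`` is in ms; rates are spike counts divided by the simulated
    time, converted to spikes/s.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    if isinstance(spike_times, np.ndarray) and spike_times.ndim == 1:
        spike_times = [spike_times]
    rates = np.array([len(s) / duration * 1000.0 for s in spike_times])
    return rates, float(rates.mean()) if rates.size else 0.0


def synchrony_chi(v_traces: np.ndarray, nucleus: str = "") -> SynchronyReport:
    """Population synchrony χ² ratio of one (n, T) voltage array.

    χ = σ²_V / (1/n Σ σ²_{v_i}) where V(t) is the population mean; χ = 1
    for identical nonconstant traces, χ → 0 for asynchronous populations.
    Invariant to a common affine rescaling of all traces.
    """
    v = np.asarray(v_traces, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ConfigError("synchrony requires >= 2 neurons")
    ind = v.var(axis=1)
    denom = ind.mean()
    if denom == 0.0:
        raise ConfigError("synchrony undefined for all-constant traces")
    chi = float(v.mean(axis=0).var() / denom)
    return SynchronyReport(nucleus=nucleus, chi=chi,
                           population_variance=float(v.mean(axis=0).var()),
                           mean_individual_variance=float(denom))


def rmse(y: np.ndarray, y_d: np.ndarray | float) -> float:
    """Root mean square error between a series and its reference."""
    y = np.asarray(y, dtype=float)
    yd = np.broadcast_to(np.asarray(y_d, dtype=float), y.shape) \
        if np.ndim(y_d) == 0 else np.asarray(y_d, dtype=float)
    if yd.shape != y.shape:
        raise ValueError("series and reference lengths differ")
    if y.size == 0:
        raise ValueError("rmse requires at least one sample")
    return float(np.sqrt(np.mean((y - yd) ** 2)))
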