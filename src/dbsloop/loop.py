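"""Closed-loop coupling of plant, biomarker and controller.

The measure→control→stimulate cycle: after a ≥1 s unstimulated warm-up
(the spectral window requirement), each iteration simulates one
stimulation period at the commanded pulse frequency, appends the GPi
voltages to a rolling LFP buffer, re-estimates beta power on the trailing
1 s window, and feeds the supervisory controller to obtain the next
command.  DBS is a train of monophasic rectangular pulses (default
300 μA/cm², 0.3 ms) delivered intracellularly to every GPi neuron, with
period 1000/u(t) ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import (ConfigError, NetworkConfig, apply_parkinsonism,
                    default_network, simulate)
from .biomarker import (BetaPowerSeries, SpectralConfig, beta_power,
                        compute_lfp, rmse, window_beta_power)
from .control import (ControlSample, PIGains, SupervisoryController,
                      U_MAX, U_MIN, clamp_command)

__all__ = [
    "PulseSpec",
    "ScenarioSpec",
    "LoopRecord",
    "build_pulse_train",
    "run_closed_loop",
    "frequency_sweep",
    "healthy_reference",
    "settling_time",
    "piecewise_constant_pd",
    "square_reference",
]


@dataclass(frozen=True)
class PulseSpec:
    """Monophasic positive rectangular DBS pulse."""

    amplitude: float = 300.0  # μA/cm²
    width: float = 0.3        # ms

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError("pulse amplitude must be >= 0")
        if self.width <= 0:
            raise ConfigError("pulse width must be positive")


def build_pulse_train(u: float, t_start: float, t_end: float,
                      spec: PulseSpec = PulseSpec(), dt: float = 0.025,
                      phase: float = 0.0) -> np.ndarray:
    """Stimulus segment (μA/cm² per step) for frequency ``u`` on [t_start, t_end).

    Rectangular pulses of the given amplitude and width start at onsets
    t_start + phase, t_start + phase + 1000/u, … below t_end.
    """
    if not (U_MIN <= u <= U_MAX):
        raise ConfigError(f"frequency {u} Hz outside the [5, 200] Hz command range")
    period = 1000.0 / u
    if spec.width >= period:
        raise ConfigError("pulse width must be shorter than the pulse period")
    steps = int(round((t_end - t_start) / dt))
    stim = np.zeros(steps)
    wsteps = max(1, int(round(spec.width / dt)))
    onset = phase
    while onset < t_end - t_start:
        i0 = int(round(onset / dt))
        stim[i0:i0 + wsteps] = spec.amplitude
        onset += period
    return stim


@dataclass
class ScenarioSpec:
    """One closed-loop experiment.

    ``pd_schedule`` and ``reference_schedule`` are functions of time since
    control onset (s); a None reference self-calibrates to the measured
    healthy-state beta power of the same network build.  ``open_loop_freq``
    replaces the controller with a fixed stimulation frequency.
    """

    controller: str = "rbf_p"             # p | pi | rbf_p | rbf_pi | none
    kp: float = 0.1
    ki: float = 0.0
    duration: float = 6.0                 # s of closed-loop control
    warmup: float = 1.0                   # s, unstimulated (>= spectral window)
    seed: int = 0
    pd_schedule: Callable[[float], float] | None = None
    reference_schedule: Callable[[float], float] | None = None
    reference_value: float | None = None  # fixed-dB mode
    open_loop_freq: float | None = None
    pulse: PulseSpec = field(default_factory=PulseSpec)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    rmse_window: float = 4.0              # s, evaluation window (last part)
    rbf_five_node: bool = False

    def __post_init__(self):
        if self.warmup < self.spectral.window_length:
            raise ConfigError("warm-up must cover at least one spectral window")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")


@dataclass
class LoopRecord:
    """Time-aligned log of one closed-loop run."""

    samples: list[ControlSample]
    beta_series: BetaPowerSeries          # post-hoc sliding series, t from run start
    lfp: np.ndarray                       # GPi LFP at 1 kHz from run start
    pulse_times: np.ndarray               # ms, pulse onsets
    rmse_last_window: float
    reference: Callable[[float], float]
    warmup: float
    config_echo: dict

    def reference_at(self, times_s: np.ndarray) -> np.ndarray:
        return np.array([self.reference(t - self.warmup) for t in times_s])


def piecewise_constant_pd(dwell: float = 1.0, seed: int = 0,
                          lo: float = 0.0, hi: float = 1.0) -> Callable[[float], float]:
    """Random piecewise-constant parkinsonism schedule: a fresh uniform
    draw on [lo, hi] every ``dwell`` seconds (seeded, time-deterministic)."""
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=4096)

    def schedule(t: float) -> float:
        return float(draws[min(int(max(t, 0.0) / dwell), draws.size - 1)])

    return schedule


def square_reference(low: float, high: float, freq: float = 1.0) -> Callable[[float], float]:
    """Square-wave reference switching between two beta levels at ``freq`` Hz."""

    def schedule(t: float) -> float:
        return high if int(math.floor(2.0 * freq * max(t, 0.0))) % 2 else low

    return schedule


def healthy_reference(network: NetworkConfig, duration: float = 3.0,
                      spectral: SpectralConfig | None = None,
                      discard: float = 1.0) -> float:
    """Self-calibrated setpoint: beta power of the same build at pd = 0.

    Simulates the healthy network and averages the sliding-window beta
    power over window centers after ``discard`` seconds.
    """
    spectral = spectral or SpectralConfig()
    cfg = apply_parkinsonism(network, 0.0)
    res = simulate(cfg, duration * 1000.0, rec_every=max(1, int(round(1.0 / cfg.dt))))
    series = beta_power(res.lfp("GPi"), spectral)
    sel = series.times >= discard
    return float(series.power[sel].mean())


def _decimate_to_1khz(x_dt: np.ndarray, dt: float) -> np.ndarray:
    step = int(round(1.0 / dt))
    return x_dt[::step]


def run_closed_loop(scenario: ScenarioSpec, network: NetworkConfig) -> LoopRecord:
    """Run the measure→control→stimulate cycle.

    Returns the full trajectory log: per-cycle control samples, the post-hoc
    sliding beta-power series on the regular 0.1 s grid, the 1 kHz GPi LFP,
    pulse onsets, and the RMSE between beta power and the reference over the
    final ``rmse_window`` seconds.
    """
    dt = network.dt
    spectral = scenario.spectral
    pd0 = (scenario.pd_schedule(0.0) if scenario.pd_schedule is not None
           else network.pd)
    cfg = apply_parkinsonism(network, pd0)
    cfg.seed = scenario.seed

    # reference
    if scenario.reference_schedule is not None:
        ref = scenario.reference_schedule
    else:
        if scenario.reference_value is not None:
            target = scenario.reference_value
        else:
            target = healthy_reference(network, spectral=spectral)
        ref = (lambda tgt: (lambda t: tgt))(target)

    controller = None
    if scenario.open_loop_freq is None and scenario.controller != "none":
        from .control import rbf_init
        rbf = (rbf_init(seed=scenario.seed, paper_five_node=scenario.rbf_five_node)
               if scenario.controller.startswith("rbf") else None)
        controller = SupervisoryController(
            kind=scenario.controller, gains=PIGains(kp=scenario.kp, ki=scenario.ki),
            rbf=rbf, seed=scenario.seed)

    # ---- warm-up (unstimulated) ----
    warm_ms = scenario.warmup * 1000.0
    total_ms_all = warm_ms + scenario.duration * 1000.0
    lfp_all = np.empty(int(round(total_ms_all / dt)) + 1)
    res = simulate(cfg, warm_ms, rec_every=1)
    state = res.final_state
    warm_lfp = res.lfp("GPi")
    lfp_all[:warm_lfp.size] = warm_lfp
    n_dt = warm_lfp.size - 1  # index of the last written sample
    nwin_dt = int(round(spectral.window_length * 1000.0 / dt))

    pulse_times = []
    t_ctrl = 0.0  # s since control onset
    u = float(scenario.open_loop_freq) if scenario.open_loop_freq is not None else U_MIN
    u = clamp_command(u)
    current_pd = pd0
    total_ms = scenario.duration * 1000.0
    elapsed_ms = 0.0

    while elapsed_ms < total_ms - 1e-9:
        period = 1000.0 / u
        seg_ms = min(period, total_ms - elapsed_ms)
        steps = max(1, int(round(seg_ms / dt)))
        seg_ms = steps * dt
        if scenario.pd_schedule is not None:
            pd_now = scenario.pd_schedule(t_ctrl)
            if pd_now != current_pd:
                cfg = apply_parkinsonism(cfg, pd_now)
                current_pd = pd_now
        stim = np.zeros(steps)
        wsteps = max(1, int(round(scenario.pulse.width / dt)))
        if scenario.pulse.amplitude > 0:
            stim[:wsteps] = scenario.pulse.amplitude
            pulse_times.append(scenario.warmup * 1000.0 + elapsed_ms)
        seg = simulate(cfg, seg_ms, stimulus=stim, state=state, rec_every=1)
        state = seg.final_state
        lfp_seg = seg.lfp("GPi")
        lfp_all[n_dt:n_dt + steps + 1] = lfp_seg  # first sample re-records t0
        n_dt += steps
        elapsed_ms += seg_ms
        t_ctrl = elapsed_ms / 1000.0

        # measure beta power on the trailing 1 s window (1 kHz, end-anchored)
        trailing = lfp_all[n_dt + 1 - nwin_dt:n_dt + 1]
        onekhz = trailing[::-int(round(1.0 / dt))][::-1]
        y = window_beta_power(onekhz, spectral)
        y_d = ref(t_ctrl)

        if scenario.open_loop_freq is not None or controller is None:
            continue
        sample = controller.step(y, y_d, dt=seg_ms / 1000.0,
                                 t=scenario.warmup + t_ctrl)
        u = sample.u

    lfp_1k = _decimate_to_1khz(lfp_all[:n_dt + 1], dt)
    series = beta_power(lfp_1k, spectral)
    total_s = scenario.warmup + scenario.duration
    w0 = total_s - scenario.rmse_window
    sel = series.times >= w0
    ref_vals = np.array([ref(t - scenario.warmup) for t in series.times[sel]])
    err = rmse(series.power[sel], ref_vals)
    samples = controller.samples if controller is not None else []
    echo = {"scenario": {
        "controller": scenario.controller, "kp": scenario.kp, "ki": scenario.ki,
        "duration": scenario.duration, "warmup": scenario.warmup,
        "seed": scenario.seed, "open_loop_freq": scenario.open_loop_freq},
        "network_pd": network.pd, "network_seed": cfg.seed}
    return LoopRecord(samples=samples, beta_series=series, lfp=lfp_1k,
                      pulse_times=np.asarray(pulse_times),
                      rmse_last_window=err, reference=ref,
                      warmup=scenario.warmup, config_echo=echo)


def settling_time(record: LoopRecord, band_frac: float = 0.10) -> float:
    """Time (s, from control onset) for beta power to enter and stay within
    ±``band_frac``·|reference| of the reference.  Returns inf if never."""
    times = record.beta_series.times
    power = record.beta_series.power
    refv = record.reference_at(times)
    inside = np.abs(power - refv) <= band_frac * np.abs(refv)
    post = times >= record.warmup
    idx = np.flatnonzero(post)
    for k in idx:
        if inside[k] and inside[k:].all():
            return float(times[k] - record.warmup)
    return float("inf")


def frequency_sweep(freqs, network: NetworkConfig, trials: int = 5,
                    duration: float = 3.0, settle: float = 1.0,
                    spectral: SpectralConfig | None = None,
                    pulse: PulseSpec = PulseSpec(), base_seed: int = 0):
    """Open-loop beta power vs DBS pulse frequency (f = 0 ⇒ no DBS).

    For each frequency and trial seed, simulates the network with a constant
    pulse train and averages sliding-window beta power over window centers
    after ``settle`` seconds.  Returns a DataFrame (freq, mean, se, n).
    """
    import pandas as pd

    spectral = spectral or SpectralConfig()
    rows = []
    per_trial = {}
    for f in freqs:
        if f != 0 and not (U_MIN <= f <= U_MAX):
            raise ConfigError(f"frequency {f} outside {{0}} ∪ [5, 200] Hz")
        vals = []
        for tr in range(trials):
            cfg = apply_parkinsonism(network, network.pd)
            cfg.seed = base_seed + tr
            dur_ms = duration * 1000.0
            stim = None if f == 0 else build_pulse_train(
                f, 0.0, dur_ms, pulse, cfg.dt)
            res = simulate(cfg, dur_ms, stimulus=stim,
                           rec_every=max(1, int(round(1.0 / cfg.dt))))
            series = beta_power(res.lfp("GPi"), spectral)
            sel = series.times >= settle
            vals.append(float(series.power[sel].mean()))
        vals = np.asarray(vals)
        per_trial[f] = vals
        rows.append({"freq": f, "beta_mean": vals.mean(),
                     "beta_se": vals.std(ddof=1) / math.sqrt(len(vals))
                     if len(vals) > 1 else 0.0,
                     "n": len(vals)})
    df = pd.DataFrame(rows)
    df.attrs["per_trial"] = per_trial
    return df
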