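"""Conductance-based cortex–basal-ganglia–thalamus network model.

The plant for the closed-loop deep-brain-stimulation testbed: eight
populations of ten neurons each — subthalamic nucleus (STN), external and
internal globus pallidus (GPe, GPi), thalamus (TH), direct- and
indirect-pathway striatum (dSTR, idSTR) as Hodgkin–Huxley-type single
compartments, plus excitatory and inhibitory cortex (eCTX, iCTX) as
Izhikevich neurons.  Nuclei are coupled by delayed alpha synapses along the
direct (eCTX→dSTR→GPi→TH→eCTX), indirect (eCTX→idSTR→GPe→GPi→TH→eCTX) and
hyper-direct (eCTX→STN→GPi→TH→eCTX) pathways, the reciprocal STN↔GPe loop,
GPe→GPe collaterals and the eCTX↔iCTX pair.

The degree of parkinsonism is a scalar ``pd`` in [0, 1] that linearly
rescales three conductances: the striatal M-type potassium conductance
``g_m = 2.6 − 0.9·pd``, the cortico-striatal coupling
``g_CTX,STR = 0.07 − 0.044·pd`` and the GPe collateral coupling
``g_GPe,GPe = 0.0125 + 0.0375·pd``.

Integration is fixed-step explicit RK4 (default dt = 0.025 ms) in a
numba-compiled kernel.  Alpha synapses S(t) = ((t−t_d)/τ)·exp(−(t−t_d)/τ)
are integrated exactly as the equivalent linear two-state system
(ds/dt = (z−s)/τ, dz/dt = −z/τ, z incremented by 1 per delayed presynaptic
spike arrival), which reproduces the kernel's impulse response without
per-step spike-list summation.  DBS current is injected into the GPi
membrane equation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "NUCLEI",
    "GatingSpec",
    "IonChannelSpec",
    "NeuronModelSpec",
    "SynapseSpec",
    "NetworkConfig",
    "NetworkState",
    "SimulationResult",
    "IntegrationError",
    "ConfigError",
    "steady_state_gate",
    "gate_derivative",
    "ionic_currents",
    "synapse_drive",
    "alpha_kernel",
    "izhikevich_step",
    "izhikevich_equilibrium",
    "neuron_model",
    "default_network",
    "apply_parkinsonism",
    "initial_state",
    "simulate",
]

# ---------------------------------------------------------------------------
# Constants and population bookkeeping
# ---------------------------------------------------------------------------

NUCLEI = ("STN", "GPe", "GPi", "TH", "dSTR", "idSTR", "eCTX", "iCTX")
_POP = {name: k for k, name in enumerate(NUCLEI)}

#: state variables per neuron, per population (membrane potential first)
_VARS = {
    "STN": ("v", "m", "h", "n", "p", "q", "r", "a", "b", "c", "d1", "d2"),
    "GPe": ("v", "h", "n", "r", "CA"),
    "GPi": ("v", "h", "n", "r", "CA"),
    "TH": ("v", "h", "r"),
    "dSTR": ("v", "m", "h", "n", "p"),
    "idSTR": ("v", "m", "h", "n", "p"),
    "eCTX": ("v", "u"),
    "iCTX": ("v", "u"),
}

MEMBRANE_CAPACITANCE = 1.0  # μF/cm², all HH-type nuclei
SPIKE_THRESHOLD = -20.0     # mV, upward-crossing spike definition (HH nuclei)
SPIKE_LOCKOUT = 1.0         # ms refractory lockout for crossing detection
CTX_PEAK = 30.0             # mV, Izhikevich spike peak / reset trigger
CTX_RESET = -65.0           # mV, Izhikevich reset potential
SYN_TAU = 5.0               # ms, alpha-synapse time constant


class ConfigError(ValueError):
    """Invalid model configuration."""


class IntegrationError(RuntimeError):
    """State became non-finite during integration."""


# ---------------------------------------------------------------------------
# Gating-variable specifications (generic layer)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingSpec:
    """Kinetics of one activation/inactivation variable.

    ``sigmoid_tau`` gates relax to a Boltzmann steady state
    X∞(v) = 1/(1+exp(−(v+w)/σ)) with rate λ/τ(v); ``alpha_beta`` gates follow
    dX/dt = α(v)(1−X) − β(v)X; ``instantaneous`` gates are evaluated at X∞(v).
    """

    form: str  # "sigmoid_tau" | "alpha_beta" | "instantaneous"
    lam: float = 1.0          # dimensionless rate scale λ
    half_voltage: float = 0.0  # w, mV
    slope: float = 1.0         # σ, mV (sign selects activation/inactivation)
    tau_fn: Callable[[float], float] | None = None   # ms
    alpha_fn: Callable[[float], float] | None = None  # 1/ms
    beta_fn: Callable[[float], float] | None = None   # 1/ms

    def __post_init__(self):
        if self.form in ("sigmoid_tau", "instantaneous") and self.slope == 0:
            raise ConfigError("sigmoid gate requires a nonzero slope")
        if self.form == "sigmoid_tau" and self.tau_fn is None:
            raise ConfigError("sigmoid_tau gate requires tau_fn")
        if self.form == "alpha_beta" and (self.alpha_fn is None or self.beta_fn is None):
            raise ConfigError("alpha_beta gate requires alpha_fn and beta_fn")


def steady_state_gate(v: float, spec: GatingSpec) -> float:
    """Boltzmann steady state X∞(v) = 1/(1+exp(−(v+w)/σ))."""
    if spec.form == "alpha_beta":
        a, b = spec.alpha_fn(v), spec.beta_fn(v)
        return a / (a + b)
    if spec.slope == 0:
        raise ConfigError("sigmoid gate requires a nonzero slope")
    x = -(v + spec.half_voltage) / spec.slope
    # exp may overflow for very steep slopes; the limit is exact
    if x > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def gate_derivative(X: float, v: float, spec: GatingSpec) -> float:
    """dX/dt (1/ms) for a gate at value ``X`` and membrane potential ``v``."""
    if spec.form == "alpha_beta":
        return spec.alpha_fn(v) * (1.0 - X) - spec.beta_fn(v) * X
    tau = spec.tau_fn(v)
    if tau <= 0:
        raise ConfigError(f"gate time constant must be positive, got {tau} at v={v}")
    return spec.lam * (steady_state_gate(v, spec) - X) / tau


def _vtrap(x: float, k: float) -> float:
    """x / (1 − exp(−x/k)) with its removable singularity at x = 0."""
    if abs(x) < 1e-7:
        return k
    return x / (1.0 - math.exp(-x / k))


# ---------------------------------------------------------------------------
# Ionic-current specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonChannelSpec:
    """One ionic current I = g_max · Π X^exponent · (v − E_rev).

    ``calcium_dependent`` multiplies the current by CA/(CA+10) (the
    pallidal after-hyperpolarization current).  Gate names ending in
    ``_inf`` are evaluated instantaneously at the current potential.
    """

    name: str
    g_max: float            # mS/cm²
    reversal: float         # mV
    gate_exponents: dict[str, int] = field(default_factory=dict)
    calcium_dependent: bool = False

    def __post_init__(self):
        if self.g_max < 0:
            raise ConfigError(f"g_max must be >= 0 for channel {self.name}")
        if any(e < 0 for e in self.gate_exponents.values()):
            raise ConfigError(f"gate exponents must be >= 0 for channel {self.name}")


@dataclass(frozen=True)
class NeuronModelSpec:
    """Full single-neuron model for one nucleus."""

    nucleus: str
    capacitance: float = MEMBRANE_CAPACITANCE
    channels: tuple[IonChannelSpec, ...] = ()
    gates: dict[str, GatingSpec] = field(default_factory=dict)
    bias_current: float = 0.0  # μA/cm² (I_app)
    izhikevich_params: dict[str, float] | None = None
    has_calcium: bool = False


def ionic_currents(
    v: np.ndarray | float,
    gates: dict[str, np.ndarray | float],
    model: NeuronModelSpec,
    ca: np.ndarray | float | None = None,
) -> dict[str, np.ndarray | float]:
    """Per-channel membrane currents (μA/cm²), outward positive.

    Instantaneous gates (``*_inf``) are evaluated from ``v``; all others are
    looked up in ``gates``.
    """
    out = {}
    for ch in model.channels:
        cur = ch.g_max * (np.asarray(v, dtype=float) - ch.reversal)
        for gname, expo in ch.gate_exponents.items():
            if gname.endswith("_inf"):
                base = gname[:-4]
                if base not in model.gates:
                    raise ConfigError(f"channel {ch.name} references unknown gate {base}")
                g = steady_state_gate(v, model.gates[base]) if np.isscalar(v) else (
                    np.vectorize(lambda vv: steady_state_gate(vv, model.gates[base]))(v))
            elif gname == "kth":  # thalamic K gate: (0.75·(1−h))
                g = 0.75 * (1.0 - np.asarray(gates["h"]))
            else:
                if gname not in gates:
                    raise ConfigError(f"channel {ch.name} requires gate {gname}")
                g = np.asarray(gates[gname])
            cur = cur * g ** expo
        if ch.calcium_dependent:
            if ca is None:
                raise ConfigError(f"channel {ch.name} requires a calcium concentration")
            ca = np.asarray(ca, dtype=float)
            cur = cur * ca / (ca + 10.0)
        out[ch.name] = cur
    return out


# ---------------------------------------------------------------------------
# Per-nucleus model tables
# ---------------------------------------------------------------------------
# STN gate time constants (ms)

def _stn_tau_m(v): return 0.2 + 3.0 / (1.0 + math.exp((v + 53.0) / 0.7))
def _stn_tau_h(v): return 24.5 / (math.exp((v + 50.0) / 15.0) + math.exp((v + 50.0) / 16.0))
def _stn_tau_n(v): return 11.0 / (math.exp(-(v + 40.0) / 14.0) + math.exp(-(v + 40.0) / 50.0))
def _stn_tau_p(v): return 5.0 + 0.33 / (math.exp((v + 27.0) / 10.0) + math.exp(-(v + 102.0) / 15.0))
def _stn_tau_q(v): return 400.0 / (math.exp((v + 50.0) / 15.0) + math.exp(-(v + 50.0) / 16.0))
def _stn_tau_r(v): return 2.0
def _stn_tau_a(v): return 1.0 + 1.0 / (1.0 + math.exp((v + 40.0) / 0.5))
def _stn_tau_b(v): return 200.0 / (math.exp((v + 60.0) / 30.0) + math.exp(-(v + 40.0) / 10.0))
def _stn_tau_c(v): return 45.0 + 10.0 / (math.exp((v + 27.0) / 20.0) + math.exp(-(v + 50.0) / 15.0))
def _stn_tau_d1(v): return 400.0 + 500.0 / (math.exp((v + 40.0) / 15.0) + math.exp(-(v + 20.0) / 20.0))
def _stn_tau_d2(v): return 130.0

# GP gate time constants
def _gp_tau_hn(v): return 0.05 + 0.27 / (1.0 + math.exp((v + 40.0) / 12.0))
def _gp_tau_r(v): return 15.0

# TH gate time constants
def _th_tau_h(v):
    return 1.0 / (0.128 * math.exp(-(v + 46.0) / 18.0) + 4.0 / (1.0 + math.exp(-(v + 23.0) / 5.0)))
def _th_tau_r(v): return 0.15 * (28.0 + math.exp(-(v + 25.0) / 10.5))

# STR rate functions (1/ms)
def _str_am(v): return 0.32 * _vtrap(v + 54.0, 4.0)
def _str_bm(v): return 0.28 * _vtrap(-(v + 27.0), 5.0)
def _str_ah(v): return 0.128 * math.exp(-(v + 50.0) / 18.0)
def _str_bh(v): return 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))
def _str_an(v): return 0.032 * _vtrap(v + 52.0, 5.0)
def _str_bn(v): return 0.5 * math.exp(-(v + 57.0) / 40.0)
def _str_ap(v): return 3.209e-4 * _vtrap(v + 30.0, 9.0)
def _str_bp(v): return 3.209e-4 * _vtrap(-(v + 30.0), 9.0)


def _sg(lam, w, s, tau):
    return GatingSpec("sigmoid_tau", lam=lam, half_voltage=w, slope=s, tau_fn=tau)


def _inst(w, s):
    return GatingSpec("instantaneous", half_voltage=w, slope=s)


def _ab(a, b):
    return GatingSpec("alpha_beta", alpha_fn=a, beta_fn=b)


_STN_GATES = {
    "m": _sg(1.0, 40.0, 8.0, _stn_tau_m),
    "h": _sg(1.0, 45.5, -6.4, _stn_tau_h),
    "n": _sg(1.0, 41.0, 14.0, _stn_tau_n),
    "p": _sg(1.0, 56.0, 6.7, _stn_tau_p),
    "q": _sg(1.0, 85.0, -5.8, _stn_tau_q),
    "r": _sg(1.0, -0.17, 0.08, _stn_tau_r),
    "a": _sg(1.0, 45.0, 14.7, _stn_tau_a),
    "b": _sg(1.0, 90.0, -7.5, _stn_tau_b),
    "c": _sg(1.0, 30.6, 5.0, _stn_tau_c),
    "d1": _sg(1.0, 60.0, -7.5, _stn_tau_d1),
    "d2": _sg(1.0, -0.1, -0.02, _stn_tau_d2),
}

_GP_GATES = {
    "m": _inst(37.0, 10.0),
    "h": _sg(0.05, 58.0, -12.0, _gp_tau_hn),
    "n": _sg(0.1, 50.0, 14.0, _gp_tau_hn),
    "r": _sg(1.0, 70.0, -2.0, _gp_tau_r),
    "a": _inst(57.0, 2.0),
    "s": _inst(35.0, 2.0),
}

_TH_GATES = {
    "m": _inst(37.0, 7.0),
    "h": _sg(1.0, 41.0, -4.0, _th_tau_h),
    "p": _inst(60.0, 6.2),
    "r": _sg(1.0, 84.0, -4.0, _th_tau_r),
}

_STR_GATES = {
    "m": _ab(_str_am, _str_bm),
    "h": _ab(_str_ah, _str_bh),
    "n": _ab(_str_an, _str_bn),
    "p": _ab(_str_ap, _str_bp),
}

_STN_CHANNELS = (
    IonChannelSpec("Na", 49.0, 60.0, {"m": 3, "h": 1}),
    IonChannelSpec("K", 57.0, -90.0, {"n": 4}),
    IonChannelSpec("l", 0.35, -60.0),
    IonChannelSpec("T", 5.0, 165.0, {"p": 2, "q": 1}),
    IonChannelSpec("CaK", 1.0, -90.0, {"r": 2}),
    IonChannelSpec("a", 5.0, -90.0, {"a": 2, "b": 1}),
    IonChannelSpec("L", 15.0, 165.0, {"c": 2, "d1": 1, "d2": 1}),
)

_GP_CHANNELS = (
    IonChannelSpec("Na", 120.0, 55.0, {"m_inf": 3, "h": 1}),
    IonChannelSpec("K", 30.0, -80.0, {"n": 4}),
    IonChannelSpec("l", 0.1, -65.0),
    IonChannelSpec("T", 0.5, 0.0, {"a_inf": 3, "r": 1}),
    IonChannelSpec("Ca", 0.15, 120.0, {"s_inf": 2}),
    IonChannelSpec("AHP", 10.0, -80.0, calcium_dependent=True),
)

_TH_CHANNELS = (
    IonChannelSpec("Na", 3.0, 50.0, {"m_inf": 3, "h": 1}),
    IonChannelSpec("K", 5.0, -75.0, {"kth": 4}),
    IonChannelSpec("l", 0.05, -70.0),
    IonChannelSpec("T", 5.0, 0.0, {"p_inf": 2, "r": 1}),
)


def _str_channels(g_m: float) -> tuple[IonChannelSpec, ...]:
    return (
        IonChannelSpec("Na", 100.0, 50.0, {"m": 3, "h": 1}),
        IonChannelSpec("K", 80.0, -100.0, {"n": 4}),
        IonChannelSpec("l", 0.1, -67.0),
        IonChannelSpec("m", g_m, -100.0, {"p": 1}),
    )


def neuron_model(nucleus: str, pd: float = 0.0, bias_current: float = 0.0) -> NeuronModelSpec:
    """Build the single-neuron model for one nucleus at parkinsonism ``pd``."""
    if nucleus == "STN":
        return NeuronModelSpec("STN", channels=_STN_CHANNELS, gates=_STN_GATES,
                               bias_current=bias_current)
    if nucleus in ("GPe", "GPi"):
        return NeuronModelSpec(nucleus, channels=_GP_CHANNELS, gates=_GP_GATES,
                               bias_current=bias_current, has_calcium=True)
    if nucleus == "TH":
        return NeuronModelSpec("TH", channels=_TH_CHANNELS, gates=_TH_GATES,
                               bias_current=bias_current)
    if nucleus in ("dSTR", "idSTR"):
        return NeuronModelSpec(nucleus, channels=_str_channels(2.6 - 0.9 * pd),
                               gates=_STR_GATES, bias_current=bias_current)
    if nucleus in ("eCTX", "iCTX"):
        a, d = (0.02, 8.0) if nucleus == "eCTX" else (0.1, 2.0)
        return NeuronModelSpec(nucleus, channels=(), gates={},
                               bias_current=bias_current,
                               izhikevich_params={"a": a, "b": 0.2, "reset": CTX_RESET,
                                                  "d": d, "peak": CTX_PEAK})
    raise ConfigError(f"unknown nucleus {nucleus!r}")


# ---------------------------------------------------------------------------
# Alpha synapse (spike-sum form) and Izhikevich step
# ---------------------------------------------------------------------------

def alpha_kernel(t: np.ndarray | float, tau: float = SYN_TAU) -> np.ndarray | float:
    """Alpha-function kernel (t/τ)·exp(−t/τ) for t > 0, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, (t / tau) * np.exp(-np.clip(t, 0, None) / tau), 0.0)
    return out if out.ndim else float(out)


@dataclass
class SynapseSpec:
    """One nucleus-to-nucleus projection.

    ``pairs`` lists neuron-level (pre, post) connections; ``reversal`` may be
    left None, in which case it is derived from ``sign`` (0 mV excitatory,
    −85 mV inhibitory) or forced to −85 mV everywhere in literal-reversal
    mode.
    """

    source: str
    target: str
    g: float                       # mS/cm², maximal synaptic conductance
    sign: str                      # "excitatory" | "inhibitory"
    delay: float                   # ms, transmission delay t_d
    tau: float = SYN_TAU           # ms
    reversal: float | None = None  # mV (E_syn); None → derived from sign
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.g < 0:
            raise ConfigError(f"synaptic conductance must be >= 0 ({self.source}->{self.target})")
        if self.delay < 0:
            raise ConfigError(f"synaptic delay must be >= 0 ({self.source}->{self.target})")
        if self.tau <= 0:
            raise ConfigError(f"synaptic tau must be > 0 ({self.source}->{self.target})")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigError(f"unknown synapse sign {self.sign!r}")

    def effective_reversal(self, literal_esyn: bool = False) -> float:
        if literal_esyn:
            return -85.0
        if self.reversal is not None:
            return self.reversal
        return 0.0 if self.sign == "excitatory" else -85.0


def synapse_drive(pre_spikes: Sequence[float], t: float, spec: SynapseSpec) -> float:
    """Summed alpha-synapse drive S(t) given presynaptic spike times (ms).

    Each spike at t_s contributes ((t−t_s−t_d)/τ)·exp(−(t−t_s−t_d)/τ) once
    t exceeds t_s + t_d.  The synaptic current is then
    g·(v_post − E_syn)·S(t).
    """
    s = 0.0
    for ts in pre_spikes:
        dtms = t - ts - spec.delay
        if dtms > 0:
            s += (dtms / spec.tau) * math.exp(-dtms / spec.tau)
    return s


def izhikevich_step(v: float, u: float, i_syn: float, dt: float,
                    params: dict[str, float]) -> tuple[float, float, bool]:
    """One RK4 step of the cortical neuron, with peak-triggered reset.

    dv/dt = 0.04v² + 5v + 140 − u − I_syn, du/dt = a(0.2v − u); when v
    exceeds the 30 mV peak the neuron is reset to −65 mV and u ← u + d.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    a = params["a"]

    def f(vv, uu):
        return (0.04 * vv * vv + 5.0 * vv + 140.0 - uu - i_syn,
                a * (0.2 * vv - uu))

    k1v, k1u = f(v, u)
    k2v, k2u = f(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u)
    k3v, k3u = f(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u)
    k4v, k4u = f(v + dt * k3v, u + dt * k3u)
    v2 = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    u2 = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
    if v2 > params.get("peak", CTX_PEAK):
        return params.get("reset", CTX_RESET), u2 + params["d"], True
    return v2, u2, False


def izhikevich_equilibrium() -> tuple[float, float]:
    """Input-free fixed point: 0.04v²+5v+140 = u with u = 0.2v."""
    # 0.04 v² + 4.8 v + 140 = 0; the lower root is the stable rest point
    disc = 4.8 * 4.8 - 4 * 0.04 * 140.0
    v = (-4.8 - math.sqrt(disc)) / (2 * 0.04)
    return v, 0.2 * v


# ---------------------------------------------------------------------------
# Network configuration
# ---------------------------------------------------------------------------

def _one_to_one(n: int) -> tuple[tuple[int, int], ...]:
    return tuple((i, i) for i in range(n))


def _fanout(n: int, k: int) -> tuple[tuple[int, int], ...]:
    """Each presynaptic neuron i contacts post neurons i, i+1, …, i+k−1 (ring)."""
    return tuple((i, (i + j) % n) for i in range(n) for j in range(k))


def _ring_neighbors(n: int) -> tuple[tuple[int, int], ...]:
    """Each post neuron i receives from its two ring neighbours (collaterals)."""
    return tuple((pre, post) for post in range(n)
                 for pre in ((post - 1) % n, (post + 1) % n))


def ctx_str_conductance(pd: float) -> float:
    """Cortico-striatal coupling, g_CTX,STR = 0.07 − 0.044·pd (mS/cm²)."""
    return 0.07 - 0.044 * pd


def gpe_gpe_conductance(pd: float) -> float:
    """GPe collateral coupling, g_GPe,GPe = 0.0125 + 0.0375·pd (mS/cm²)."""
    return 0.0125 + 0.0375 * pd


def striatal_m_conductance(pd: float) -> float:
    """Striatal M-current conductance, g_m = 2.6 − 0.9·pd (mS/cm²)."""
    return 2.6 - 0.9 * pd


@dataclass
class NetworkConfig:
    """Full, serializable description of one network build.

    Per-connection conductances, delays, bias currents and neuron-level
    wiring are editorial defaults (the network-level topology is fixed by the
    model; the neuron-level values are config fields and freely overridable).
    """

    pd: float = 0.0
    dt: float = 0.025            # ms, RK4 step
    seed: int = 0
    n: int = 10                  # neurons per population
    synapses: list[SynapseSpec] = field(default_factory=list)
    bias_currents: dict[str, float] = field(default_factory=dict)  # μA/cm²
    v_init: tuple[float, float] = (-70.0, -50.0)  # uniform range for v(0), mV
    ca_init: float = 0.1
    paper_literal_esyn: bool = False  # force E_syn = −85 mV on every synapse
    # background noise: std (μA/cm²) of a zero-mean current per neuron,
    # redrawn every noise_hold ms (seeded, counter-based, resumable)
    noise_sigma: dict[str, float] = field(default_factory=dict)
    noise_hold: float = 0.1  # ms

    def __post_init__(self):
        if not (0.0 <= self.pd <= 1.0):
            raise ConfigError(f"pd must lie in [0, 1], got {self.pd}")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n < 1:
            raise ConfigError("population size must be >= 1")
        for syn in self.synapses:
            for pre, post in syn.pairs:
                if not (0 <= pre < self.n and 0 <= post < self.n):
                    raise ConfigError(
                        f"wiring index out of range in {syn.source}->{syn.target}")

    def synapse(self, source: str, target: str) -> SynapseSpec:
        for syn in self.synapses:
            if syn.source == source and syn.target == target:
                return syn
        raise KeyError(f"no projection {source}->{target}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synapses"] = [asdict(s) for s in self.synapses]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["synapses"] = [SynapseSpec(**{**s, "pairs": tuple(map(tuple, s["pairs"]))})
                         for s in d.get("synapses", [])]
        d["v_init"] = tuple(d.get("v_init", (-70.0, -50.0)))
        return cls(**d)


#: index of the divergent ("hub") indirect-pathway striatal neuron in the
#: shipped default wiring; it receives no direct cortical contact and
#: innervates every pallidal neuron, standing for the aggregate divergent
#: striato-pallidal innervation that a 10-neuron sample underrepresents.
HUB_NEURON = 0


def default_network(pd: float = 0.0, seed: int = 0, dt: float = 0.025,
                    n: int = 10, paper_literal_esyn: bool = False) -> NetworkConfig:
    """Shipped default network at parkinsonism level ``pd``.

    Wiring is one-to-one along the pathways, with two-fold divergence in the
    STN↔GPe loop (the two pallido-subthalamic contacts per neuron carry
    dispersed conduction delays), 4-neighbour GPe collaterals, and one
    divergent indirect-pathway striatal neuron contacting all pallidal
    cells.  Conductances, delays, bias currents and background-noise levels
    are the package's documented editorial defaults, calibrated once so the
    model expresses the established pathophysiology of the full
    Parkinsonian state (raised STN/GPi and lowered GPe rates, raised spike
    synchrony, and an exaggerated beta-band GPi LFP rhythm paced by the
    disinhibited indirect-pathway striatum).
    """
    o = _one_to_one(n)
    f2 = _fanout(n, 2)
    all_gpe = tuple((HUB_NEURON, j) for j in range(n))
    syns = [
        SynapseSpec("eCTX", "dSTR", ctx_str_conductance(pd), "excitatory", 5.1, pairs=o),
        # the hub neuron has no direct cortical contact
        SynapseSpec("eCTX", "idSTR", ctx_str_conductance(pd), "excitatory", 5.1,
                    pairs=tuple((i, i) for i in range(n) if i != HUB_NEURON)),
        SynapseSpec("eCTX", "STN", 0.08, "excitatory", 5.9, pairs=o),
        SynapseSpec("eCTX", "iCTX", 0.3, "excitatory", 1.0, pairs=o),
        SynapseSpec("iCTX", "eCTX", 0.2, "inhibitory", 1.0, pairs=o),
        SynapseSpec("TH", "eCTX", 0.08, "excitatory", 5.0, pairs=o),
        SynapseSpec("dSTR", "GPi", 0.05, "inhibitory", 4.0, pairs=o),
        SynapseSpec("idSTR", "GPe", 1.2, "inhibitory", 5.0, pairs=o),
        SynapseSpec("idSTR", "GPe", 2.0, "inhibitory", 5.0, pairs=all_gpe),
        SynapseSpec("idSTR", "GPi", 2.5, "inhibitory", 5.0,
                    pairs=tuple((HUB_NEURON, j) for j in range(n))),
        SynapseSpec("STN", "GPe", 0.08, "excitatory", 8.0, pairs=f2),
        SynapseSpec("STN", "GPi", 0.2, "excitatory", 1.5, pairs=f2),
        # two pallido-subthalamic contacts per STN cell, dispersed delays
        SynapseSpec("GPe", "STN", 0.15, "inhibitory", 8.0, pairs=o),
        SynapseSpec("GPe", "STN", 0.15, "inhibitory", 15.0,
                    pairs=tuple((i, (i + 1) % n) for i in range(n))),
        SynapseSpec("GPe", "GPi", 1.0, "inhibitory", 3.0, pairs=o),
        SynapseSpec("GPe", "GPe", gpe_gpe_conductance(pd), "inhibitory", 1.0,
                    pairs=tuple((pre % n, post) for post in range(n)
                                for pre in (post - 2, post - 1, post + 1, post + 2))),
        SynapseSpec("GPi", "TH", 0.2, "inhibitory", 5.0, pairs=o),
    ]
    bias = {"STN": 0.0, "GPe": 1.5, "GPi": 2.5, "TH": 1.2,
            "dSTR": 1.0, "idSTR": 2.0, "eCTX": 2.5, "iCTX": 2.0}
    noise = {"STN": 3.0, "GPe": 2.0, "GPi": 3.0, "TH": 1.0,
             "dSTR": 0.3, "idSTR": 0.3, "eCTX": 1.0, "iCTX": 1.0}
    return NetworkConfig(pd=pd, dt=dt, seed=seed, n=n, synapses=syns,
                         bias_currents=bias, noise_sigma=noise,
                         paper_literal_esyn=paper_literal_esyn)


def apply_parkinsonism(config: NetworkConfig, pd: float) -> NetworkConfig:
    """Return a copy of ``config`` at parkinsonism level ``pd``.

    Recomputes the three pd-dependent conductances from their closed forms
    (g_m is applied at simulation time from ``config.pd``); idempotent: pd is
    stored, never compounded.
    """
    if not (0.0 <= pd <= 1.0):
        raise ConfigError(f"pd must lie in [0, 1], got {pd}")
    new_syns = []
    for syn in config.synapses:
        if syn.source == "eCTX" and syn.target in ("dSTR", "idSTR"):
            syn = SynapseSpec(syn.source, syn.target, ctx_str_conductance(pd),
                              syn.sign, syn.delay, syn.tau, syn.reversal, syn.pairs)
        elif syn.source == "GPe" and syn.target == "GPe":
            syn = SynapseSpec(syn.source, syn.target, gpe_gpe_conductance(pd),
                              syn.sign, syn.delay, syn.tau, syn.reversal, syn.pairs)
        new_syns.append(syn)
    return NetworkConfig(pd=pd, dt=config.dt, seed=config.seed, n=config.n,
                         synapses=new_syns, bias_currents=dict(config.bias_currents),
                         v_init=config.v_init, ca_init=config.ca_init,
                         paper_literal_esyn=config.paper_literal_esyn,
                         noise_sigma=dict(config.noise_sigma),
                         noise_hold=config.noise_hold)


# ---------------------------------------------------------------------------
# State layout and initialization
# ---------------------------------------------------------------------------

def _layout(n: int) -> tuple[np.ndarray, int, int]:
    """Block offsets per population, synapse-state offset, total length."""
    off = np.zeros(8, dtype=np.int64)
    pos = 0
    for k, name in enumerate(NUCLEI):
        off[k] = pos
        pos += len(_VARS[name]) * n
    return off, pos, pos  # synapse offset appended later


@dataclass
class NetworkState:
    """Resumable integrator state (flat state vector plus delay buffers)."""

    y: np.ndarray              # flat state (neurons + synapse s,z pairs)
    arrivals: np.ndarray       # ring buffer of scheduled spike arrivals
    step0: int                 # absolute step index (ring phase)
    t0: float                  # ms, absolute time of y
    last_spike: np.ndarray     # per-neuron time of last detected spike


def initial_state(config: NetworkConfig) -> NetworkState:
    """Seeded initial condition: v(0) ~ U[v_init], gates at steady state."""
    n = config.n
    rng = np.random.default_rng(config.seed)
    off, nneuron, _ = _layout(n)
    npairs = sum(len(s.pairs) for s in config.synapses)
    y = np.zeros(nneuron + 2 * npairs)
    lo, hi = config.v_init
    pd = config.pd
    for k, name in enumerate(NUCLEI):
        names = _VARS[name]
        v0 = rng.uniform(lo, hi, size=n)
        o = int(off[k])
        y[o:o + n] = v0
        model = neuron_model(name, pd=pd)
        for gi, gname in enumerate(names[1:], start=1):
            if gname == "CA":
                y[o + gi * n:o + (gi + 1) * n] = config.ca_init
            elif gname == "u":
                y[o + gi * n:o + (gi + 1) * n] = 0.2 * v0
            else:
                y[o + gi * n:o + (gi + 1) * n] = [
                    steady_state_gate(v, model.gates[gname]) for v in v0]
    max_delay = max((s.delay for s in config.synapses), default=0.0)
    buflen = int(round(max_delay / config.dt)) + 2
    arrivals = np.zeros((buflen, max(npairs, 1)))
    return NetworkState(y=y, arrivals=arrivals, step0=0, t0=0.0,
                        last_spike=np.full(8 * n, -1e9))


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _xinf(v, w, s):
    x = -(v + w) / s
    if x > 700.0:
        return 0.0
    if x < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=False)
def _nb_vtrap(x, k):
    if abs(x) < 1e-7:
        return k
    return x / (1.0 - math.exp(-x / k))


@njit(cache=False)
def _splitmix64(x):
    """Counter-based 64-bit mix (SplitMix64 finalizer)."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x ^ (x >> np.uint64(31))


@njit(cache=False)
def _gauss_at(seed, counter):
    """Standard normal from a (seed, counter) pair via Box–Muller."""
    a = _splitmix64(seed ^ (np.uint64(counter) * np.uint64(0x9E3779B97F4A7C15)))
    b = _splitmix64(a)
    u1 = (np.float64(a >> np.uint64(11)) + 1.0) / 9007199254740993.0
    u2 = np.float64(b >> np.uint64(11)) / 9007199254740992.0
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(6.283185307179586 * u2)


@njit(cache=False)
def _rhs(y, dy, isyn, n, off, osyn, npairs, pair_post, pair_g, pair_E,
         tau_syn, gm_str, iapp, istim, noise):
    # synaptic currents, outward positive: I = g (v_post − E_syn) S
    for k in range(8 * n):
        isyn[k] = 0.0
    for p in range(npairs):
        s = y[osyn + 2 * p]
        tgt = pair_post[p]
        vpost = y[off[tgt // n] + (tgt % n)]
        isyn[tgt] += pair_g[p] * (vpost - pair_E[p]) * s
    # synapse states
    for p in range(npairs):
        s = y[osyn + 2 * p]
        z = y[osyn + 2 * p + 1]
        dy[osyn + 2 * p] = (z - s) / tau_syn
        dy[osyn + 2 * p + 1] = -z / tau_syn

    # ---- STN ----
    o = off[0]
    for i in range(n):
        v = y[o + i]
        m = y[o + n + i]; h = y[o + 2 * n + i]; nn = y[o + 3 * n + i]
        pp = y[o + 4 * n + i]; q = y[o + 5 * n + i]; r = y[o + 6 * n + i]
        a = y[o + 7 * n + i]; b = y[o + 8 * n + i]; c = y[o + 9 * n + i]
        d1 = y[o + 10 * n + i]; d2 = y[o + 11 * n + i]
        ina = 49.0 * m * m * m * h * (v - 60.0)
        ik = 57.0 * nn * nn * nn * nn * (v + 90.0)
        il = 0.35 * (v + 60.0)
        it = 5.0 * pp * pp * q * (v - 165.0)
        icak = r * r * (v + 90.0)
        ia = 5.0 * a * a * b * (v + 90.0)
        iL = 15.0 * c * c * d1 * d2 * (v - 165.0)
        dy[o + i] = -(ina + ik + il + it + icak + ia + iL) - isyn[i] + iapp[i] + noise[i]
        dy[o + n + i] = (_xinf(v, 40.0, 8.0) - m) / (0.2 + 3.0 / (1.0 + math.exp((v + 53.0) / 0.7)))
        dy[o + 2 * n + i] = (_xinf(v, 45.5, -6.4) - h) * (math.exp((v + 50.0) / 15.0) + math.exp((v + 50.0) / 16.0)) / 24.5
        dy[o + 3 * n + i] = (_xinf(v, 41.0, 14.0) - nn) * (math.exp(-(v + 40.0) / 14.0) + math.exp(-(v + 40.0) / 50.0)) / 11.0
        dy[o + 4 * n + i] = (_xinf(v, 56.0, 6.7) - pp) / (5.0 + 0.33 / (math.exp((v + 27.0) / 10.0) + math.exp(-(v + 102.0) / 15.0)))
        dy[o + 5 * n + i] = (_xinf(v, 85.0, -5.8) - q) * (math.exp((v + 50.0) / 15.0) + math.exp(-(v + 50.0) / 16.0)) / 400.0
        dy[o + 6 * n + i] = (_xinf(v, -0.17, 0.08) - r) / 2.0
        dy[o + 7 * n + i] = (_xinf(v, 45.0, 14.7) - a) / (1.0 + 1.0 / (1.0 + math.exp((v + 40.0) / 0.5)))
        dy[o + 8 * n + i] = (_xinf(v, 90.0, -7.5) - b) * (math.exp((v + 60.0) / 30.0) + math.exp(-(v + 40.0) / 10.0)) / 200.0
        dy[o + 9 * n + i] = (_xinf(v, 30.6, 5.0) - c) / (45.0 + 10.0 / (math.exp((v + 27.0) / 20.0) + math.exp(-(v + 50.0) / 15.0)))
        dy[o + 10 * n + i] = (_xinf(v, 60.0, -7.5) - d1) / (400.0 + 500.0 / (math.exp((v + 40.0) / 15.0) + math.exp(-(v + 20.0) / 20.0)))
        dy[o + 11 * n + i] = (_xinf(v, -0.1, -0.02) - d2) / 130.0

    # ---- GPe (1) and GPi (2) ----
    for popk in range(1, 3):
        o = off[popk]
        for i in range(n):
            v = y[o + i]
            h = y[o + n + i]; nn = y[o + 2 * n + i]; r = y[o + 3 * n + i]
            ca = y[o + 4 * n + i]
            minf = _xinf(v, 37.0, 10.0)
            ainf = _xinf(v, 57.0, 2.0)
            sinf = _xinf(v, 35.0, 2.0)
            ina = 120.0 * minf * minf * minf * h * (v - 55.0)
            ik = 30.0 * nn * nn * nn * nn * (v + 80.0)
            il = 0.1 * (v + 65.0)
            it = 0.5 * ainf * ainf * ainf * r * v
            ica = 0.15 * sinf * sinf * (v - 120.0)
            iahp = 10.0 * (v + 80.0) * ca / (ca + 10.0)
            drive = iapp[popk * n + i]
            if popk == 2:
                drive += istim
            dy[o + i] = -(ina + ik + il + it + ica + iahp) - isyn[popk * n + i] + drive + noise[popk * n + i]
            tau_hn = 0.05 + 0.27 / (1.0 + math.exp((v + 40.0) / 12.0))
            dy[o + n + i] = 0.05 * (_xinf(v, 58.0, -12.0) - h) / tau_hn
            dy[o + 2 * n + i] = 0.1 * (_xinf(v, 50.0, 14.0) - nn) / tau_hn
            dy[o + 3 * n + i] = (_xinf(v, 70.0, -2.0) - r) / 15.0
            dy[o + 4 * n + i] = 1e-4 * (-ica - it - 15.0 * ca)

    # ---- TH (3) ----
    o = off[3]
    for i in range(n):
        v = y[o + i]
        h = y[o + n + i]; r = y[o + 2 * n + i]
        minf = _xinf(v, 37.0, 7.0)
        pinf = _xinf(v, 60.0, 6.2)
        ina = 3.0 * minf * minf * minf * h * (v - 50.0)
        kg = 0.75 * (1.0 - h)
        ik = 5.0 * kg * kg * kg * kg * (v + 75.0)
        il = 0.05 * (v + 70.0)
        it = 5.0 * pinf * pinf * r * v
        dy[o + i] = -(ina + ik + il + it) - isyn[3 * n + i] + iapp[3 * n + i] + noise[3 * n + i]
        dy[o + n + i] = (_xinf(v, 41.0, -4.0) - h) * (0.128 * math.exp(-(v + 46.0) / 18.0) + 4.0 / (1.0 + math.exp(-(v + 23.0) / 5.0)))
        dy[o + 2 * n + i] = (_xinf(v, 84.0, -4.0) - r) / (0.15 * (28.0 + math.exp(-(v + 25.0) / 10.5)))

    # ---- dSTR (4) and idSTR (5) ----
    for popk in range(4, 6):
        o = off[popk]
        for i in range(n):
            v = y[o + i]
            m = y[o + n + i]; h = y[o + 2 * n + i]; nn = y[o + 3 * n + i]
            pp = y[o + 4 * n + i]
            ina = 100.0 * m * m * m * h * (v - 50.0)
            ik = 80.0 * nn * nn * nn * nn * (v + 100.0)
            il = 0.1 * (v + 67.0)
            im = gm_str * pp * (v + 100.0)
            dy[o + i] = -(il + ik + ina + im) - isyn[popk * n + i] + iapp[popk * n + i] + noise[popk * n + i]
            am = 0.32 * _nb_vtrap(v + 54.0, 4.0)
            bm = 0.28 * _nb_vtrap(-(v + 27.0), 5.0)
            ah = 0.128 * math.exp(-(v + 50.0) / 18.0)
            bh = 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))
            an = 0.032 * _nb_vtrap(v + 52.0, 5.0)
            bn = 0.5 * math.exp(-(v + 57.0) / 40.0)
            ap = 3.209e-4 * _nb_vtrap(v + 30.0, 9.0)
            bp = 3.209e-4 * _nb_vtrap(-(v + 30.0), 9.0)
            dy[o + n + i] = am * (1.0 - m) - bm * m
            dy[o + 2 * n + i] = ah * (1.0 - h) - bh * h
            dy[o + 3 * n + i] = an * (1.0 - nn) - bn * nn
            dy[o + 4 * n + i] = ap * (1.0 - pp) - bp * pp

    # ---- eCTX (6) and iCTX (7), Izhikevich ----
    for popk in range(6, 8):
        o = off[popk]
        aiz = 0.02 if popk == 6 else 0.1
        for i in range(n):
            v = y[o + i]
            u = y[o + n + i]
            dy[o + i] = 0.04 * v * v + 5.0 * v + 140.0 - u - isyn[popk * n + i] + iapp[popk * n + i] + noise[popk * n + i]
            dy[o + n + i] = aiz * (0.2 * v - u)


@njit(cache=False)
def _run(y, steps, dt, n, off, osyn, ny, npairs, pair_post, pair_g, pair_E,
         pre_ptr, pre_pairs, pair_delay, arrivals, buflen, step0, t0,
         tau_syn, gm_str, iapp, stim, last_spike,
         spk_t, spk_n, rec_v, rec_every,
         k1, k2, k3, k4, ytmp, isyn, vpre,
         noise_sigma, noise_seed, hold_steps, noise):
    d_ctx = np.empty(2)
    d_ctx[0] = 8.0   # eCTX reset increment
    d_ctx[1] = 2.0   # iCTX reset increment
    for step in range(steps):
        if step % rec_every == 0:
            r = step // rec_every
            for popk in range(8):
                o = off[popk]
                for i in range(n):
                    rec_v[popk, i, r] = y[o + i]
        ph = (step0 + step) % buflen
        for p in range(npairs):
            if arrivals[ph, p] != 0.0:
                y[osyn + 2 * p + 1] += arrivals[ph, p]
                arrivals[ph, p] = 0.0
        ist = stim[step]
        absstep = step0 + step
        if absstep % hold_steps == 0:
            blk = np.uint64(absstep // hold_steps)
            for fl in range(8 * n):
                sg = noise_sigma[fl // n]
                if sg > 0.0:
                    noise[fl] = sg * _gauss_at(
                        noise_seed, blk * np.uint64(8 * n) + np.uint64(fl))
                else:
                    noise[fl] = 0.0
        for popk in range(8):
            o = off[popk]
            for i in range(n):
                vpre[popk * n + i] = y[o + i]
        _rhs(y, k1, isyn, n, off, osyn, npairs, pair_post, pair_g, pair_E,
             tau_syn, gm_str, iapp, ist, noise)
        for j in range(ny):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(ytmp, k2, isyn, n, off, osyn, npairs, pair_post, pair_g, pair_E,
             tau_syn, gm_str, iapp, ist, noise)
        for j in range(ny):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(ytmp, k3, isyn, n, off, osyn, npairs, pair_post, pair_g, pair_E,
             tau_syn, gm_str, iapp, ist, noise)
        for j in range(ny):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(ytmp, k4, isyn, n, off, osyn, npairs, pair_post, pair_g, pair_E,
             tau_syn, gm_str, iapp, ist, noise)
        for j in range(ny):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        t = t0 + (step + 1) * dt
        # spike detection: HH nuclei by −20 mV upward crossing with lockout
        for popk in range(6):
            o = off[popk]
            for i in range(n):
                vnew = y[o + i]
                if not math.isfinite(vnew):
                    return step, popk, i
                fl = popk * n + i
                if vnew >= -20.0 and vpre[fl] < -20.0 and (t - last_spike[fl]) >= 1.0:
                    last_spike[fl] = t
                    if spk_n[fl] < spk_t.shape[1]:
                        spk_t[fl, spk_n[fl]] = t
                        spk_n[fl] += 1
                    for pp in range(pre_ptr[fl], pre_ptr[fl + 1]):
                        pr = pre_pairs[pp]
                        arrivals[(step0 + step + 1 + pair_delay[pr]) % buflen, pr] += 1.0
        # cortex: peak-triggered reset
        for popk in range(6, 8):
            o = off[popk]
            for i in range(n):
                vnew = y[o + i]
                if not math.isfinite(vnew):
                    return step, popk, i
                if vnew > 30.0:
                    fl = popk * n + i
                    y[o + i] = -65.0
                    y[o + n + i] += d_ctx[popk - 6]
                    last_spike[fl] = t
                    if spk_n[fl] < spk_t.shape[1]:
                        spk_t[fl, spk_n[fl]] = t
                        spk_n[fl] += 1
                    for pp in range(pre_ptr[fl], pre_ptr[fl + 1]):
                        pr = pre_pairs[pp]
                        arrivals[(step0 + step + 1 + pair_delay[pr]) % buflen, pr] += 1.0
    if steps % rec_every == 0:
        r = steps // rec_every
        for popk in range(8):
            o = off[popk]
            for i in range(n):
                rec_v[popk, i, r] = y[o + i]
    return -1, -1, -1


# ---------------------------------------------------------------------------
# Packing and the public simulate() entry point
# ---------------------------------------------------------------------------

class _Packed:
    """Kernel-ready arrays derived from a NetworkConfig."""

    def __init__(self, config: NetworkConfig):
        n = config.n
        self.n = n
        self.off, self.nneuron, _ = _layout(n)
        pair_post, pair_g, pair_E, pair_delay, pair_pre = [], [], [], [], []
        for syn in config.synapses:
            rev = syn.effective_reversal(config.paper_literal_esyn)
            dsteps = int(round(syn.delay / config.dt))
            for pre, post in syn.pairs:
                pair_pre.append(_POP[syn.source] * n + pre)
                pair_post.append(_POP[syn.target] * n + post)
                pair_g.append(syn.g)
                pair_E.append(rev)
                pair_delay.append(dsteps)
        self.npairs = len(pair_post)
        self.pair_post = np.asarray(pair_post, dtype=np.int64).reshape(-1)
        self.pair_g = np.asarray(pair_g, dtype=np.float64).reshape(-1)
        self.pair_E = np.asarray(pair_E, dtype=np.float64).reshape(-1)
        self.pair_delay = np.asarray(pair_delay, dtype=np.int64).reshape(-1)
        # CSR: pairs grouped by presynaptic neuron (flat index)
        order = np.argsort(np.asarray(pair_pre, dtype=np.int64), kind="stable") \
            if pair_pre else np.zeros(0, dtype=np.int64)
        self.pre_pairs = order.astype(np.int64)
        self.pre_ptr = np.zeros(8 * n + 1, dtype=np.int64)
        pre_sorted = np.asarray(pair_pre, dtype=np.int64)[order] if len(order) else order
        np.add.at(self.pre_ptr, pre_sorted + 1, 1)
        self.pre_ptr = np.cumsum(self.pre_ptr).astype(np.int64)
        self.osyn = self.nneuron
        self.ny = self.nneuron + 2 * self.npairs
        self.gm_str = striatal_m_conductance(config.pd)
        iapp = np.zeros(8 * n)
        for k, name in enumerate(NUCLEI):
            val = config.bias_currents.get(name, 0.0)
            iapp[k * n:(k + 1) * n] = np.asarray(val, dtype=float)
        self.iapp = iapp
        max_delay = int(self.pair_delay.max()) if self.npairs else 0
        self.buflen = max_delay + 2


@dataclass
class SimulationResult:
    """Simulated trajectories on a fixed time grid (ms)."""

    time: np.ndarray
    v_traces: dict[str, np.ndarray]        # nucleus -> (n, T) mV
    spike_times: dict[str, list[np.ndarray]]  # nucleus -> per-neuron ms arrays
    config_echo: NetworkConfig
    final_state: NetworkState

    def lfp(self, nucleus: str = "GPi") -> np.ndarray:
        return self.v_traces[nucleus].mean(axis=0)

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.time}
        for name, arr in self.v_traces.items():
            for i in range(arr.shape[0]):
                cols[f"{name}_{i}"] = arr[i]
        return pd.DataFrame(cols)


def simulate(config: NetworkConfig, duration: float,
             stimulus: np.ndarray | None = None,
             state: NetworkState | None = None,
             rec_every: int = 1) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    ``stimulus`` is an optional per-step DBS current (μA/cm²) applied to the
    GPi membrane equation only, sampled on the step grid (piecewise constant
    over each step); it must cover the full duration.  ``state`` resumes a
    previous run (same layout); otherwise a seeded initial condition is
    drawn.  Results are reproducible bit-for-bit given (config, seed).
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    dt = config.dt
    steps = int(round(duration / dt))
    if steps < 1:
        raise ConfigError("duration shorter than one time step")
    pk = _Packed(config)
    if state is None:
        state = initial_state(config)
    if stimulus is None:
        stim = np.zeros(steps)
    else:
        stim = np.asarray(stimulus, dtype=float).reshape(-1)
        if stim.size < steps:
            raise ConfigError("stimulus must be defined on the full time grid")
        stim = stim[:steps]
    n = config.n
    nrec = steps // rec_every + 1
    rec_v = np.empty((8, n, nrec))
    maxspk = int(steps * dt) + 8  # lockout bounds the spike count
    spk_t = np.zeros((8 * n, maxspk))
    spk_n = np.zeros(8 * n, dtype=np.int64)
    k1 = np.empty(pk.ny); k2 = np.empty(pk.ny); k3 = np.empty(pk.ny)
    k4 = np.empty(pk.ny); ytmp = np.empty(pk.ny)
    isyn = np.empty(8 * n)
    vpre = np.empty(8 * n)
    noise = np.zeros(8 * n)
    noise_sigma = np.array([config.noise_sigma.get(name, 0.0) for name in NUCLEI])
    hold_steps = max(1, int(round(config.noise_hold / dt)))
    noise_seed = np.uint64((config.seed * 2654435761 + 0x5DEECE66D) % (2 ** 63))
    if state.arrivals.shape[0] < pk.buflen:
        raise ConfigError("resumed state has an incompatible delay buffer")
    fail_step, fail_pop, fail_i = _run(
        state.y, steps, dt, n, pk.off, pk.osyn, pk.ny, pk.npairs,
        pk.pair_post, pk.pair_g, pk.pair_E, pk.pre_ptr, pk.pre_pairs,
        pk.pair_delay, state.arrivals, state.arrivals.shape[0], state.step0,
        state.t0, SYN_TAU, pk.gm_str, pk.iapp, stim, state.last_spike,
        spk_t, spk_n, rec_v, rec_every, k1, k2, k3, k4, ytmp, isyn, vpre,
        noise_sigma, noise_seed, hold_steps, noise)
    if fail_step >= 0:
        raise IntegrationError(
            f"non-finite membrane potential at t = {state.t0 + (fail_step + 1) * dt:.3f} ms "
            f"in {NUCLEI[fail_pop]} neuron {fail_i}")
    time = state.t0 + np.arange(nrec) * rec_every * dt
    v_traces = {name: rec_v[k].copy() for k, name in enumerate(NUCLEI)}
    spikes = {name: [spk_t[k * n + i, :spk_n[k * n + i]].copy() for i in range(n)]
              for k, name in enumerate(NUCLEI)}
    new_state = NetworkState(y=state.y, arrivals=state.arrivals,
                             step0=state.step0 + steps,
                             t0=state.t0 + steps * dt,
                             last_spike=state.last_spike)
    return SimulationResult(time=time, v_traces=v_traces, spike_times=spikes,
                            config_echo=config, final_state=new_state)


# ---------------------------------------------------------------------------
# Pure-Python reference right-hand side (oracle for the compiled kernel)
# ---------------------------------------------------------------------------

def reference_rhs(y: np.ndarray, config: NetworkConfig,
                  istim: float = 0.0) -> np.ndarray:
    """Independent evaluation of the network right-hand side.

    Built on the generic :class:`GatingSpec`/:class:`IonChannelSpec` tables
    rather than the hand-fused kernel arithmetic; used to cross-check the
    compiled kernel on arbitrary states.
    """
    pk = _Packed(config)
    n = config.n
    dy = np.zeros_like(y)
    isyn = np.zeros(8 * n)
    osyn = pk.osyn
    for p in range(pk.npairs):
        s = y[osyn + 2 * p]
        tgt = int(pk.pair_post[p])
        vpost = y[int(pk.off[tgt // n]) + tgt % n]
        isyn[tgt] += pk.pair_g[p] * (vpost - pk.pair_E[p]) * s
        dy[osyn + 2 * p] = (y[osyn + 2 * p + 1] - s) / SYN_TAU
        dy[osyn + 2 * p + 1] = -y[osyn + 2 * p + 1] / SYN_TAU
    for k, name in enumerate(NUCLEI):
        o = int(pk.off[k])
        names = _VARS[name]
        model = neuron_model(name, pd=config.pd)
        for i in range(n):
            v = y[o + i]
            vals = {gn: y[o + gi * n + i] for gi, gn in enumerate(names)}
            if name in ("eCTX", "iCTX"):
                a = model.izhikevich_params["a"]
                u = vals["u"]
                dy[o + i] = (0.04 * v * v + 5.0 * v + 140.0 - u
                             - isyn[k * n + i] + pk.iapp[k * n + i])
                dy[o + n + i] = a * (0.2 * v - u)
                continue
            ca = vals.get("CA")
            gates = {gn: vals[gn] for gn in names[1:] if gn not in ("CA",)}
            cur = ionic_currents(v, gates, model, ca=ca)
            total = sum(cur.values())
            drive = pk.iapp[k * n + i] + (istim if name == "GPi" else 0.0)
            dy[o + i] = -total - isyn[k * n + i] + drive
            for gi, gn in enumerate(names[1:], start=1):
                if gn == "CA":
                    dy[o + gi * n + i] = 1e-4 * (-cur["Ca"] - cur["T"] - 15.0 * ca)
                else:
                    dy[o + gi * n + i] = gate_derivative(vals[gn], v, model.gates[gn])
    return dy
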