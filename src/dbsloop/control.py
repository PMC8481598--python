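"""P/PI feedback controllers and the RBF-network supervisory controller.

The supervisory scheme sums a fixed-gain feedback term u_p with the output
u_rbf of a single-hidden-layer Gaussian RBF network trained on line by
gradient descent on E = ½(u_rbf − u)², i.e. toward the total command the
plant actually received.  As the feedback error vanishes u_p → 0 and the
RBF network — acting as a learned inverse model of the plant — carries the
whole command.  The total command is the DBS pulse repetition frequency,
clamped to [5, 200] Hz.

Sign convention: the tracking error is defined as e = y − y_d, the *excess*
of measured beta power over the reference, so that positive controller
gains raise the stimulation frequency when beta power is exaggerated
(beta power falls monotonically with frequency above ~50 Hz).  This is
equivalent to the textbook e = y_d − y law with negated gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ConfigError

__all__ = [
    "U_MIN",
    "U_MAX",
    "PIGains",
    "RBFState",
    "ControlSample",
    "clamp_command",
    "p_step",
    "pi_step",
    "rbf_forward",
    "rbf_init",
    "rbf_update",
    "SupervisoryController",
]

U_MIN = 5.0    # Hz, stimulation never fully off
U_MAX = 200.0  # Hz
WIDTH_FLOOR = 0.1  # minimum Gaussian width, prevents division blow-up


def clamp_command(u: float) -> float:
    """Clamp a frequency command to the permitted [5, 200] Hz range."""
    return float(min(max(u, U_MIN), U_MAX))


@dataclass
class PIGains:
    """Proportional(-integral) gains; the derivative term is omitted.

    Units: kp in Hz per dB of beta-power error, ki in Hz per dB·s.  The
    integral state is clamped to ±anti_windup_limit (command scale) so the
    output clamp cannot stall recovery.
    """

    kp: float = 0.1
    ki: float = 0.0
    integral_state: float = 0.0
    anti_windup_limit: float | None = None  # default 200/ki at first use

    def __post_init__(self):
        if self.kp < 0 or self.ki < 0:
            raise ConfigError("controller gains must be >= 0")


def p_step(e: float, gains: PIGains) -> float:
    """Proportional law u_p = kp·e."""
    return gains.kp * e


def pi_step(e: float, dt: float, gains: PIGains) -> float:
    """PI law: accumulate the error integral (anti-windup-clamped) and
    return kp·e + ki·∫e dt.  ``dt`` is the time since the last update, s."""
    if dt <= 0:
        raise ConfigError("dt must be positive")
    limit = gains.anti_windup_limit
    if limit is None:
        limit = U_MAX / gains.ki if gains.ki > 0 else np.inf
    gains.integral_state = float(np.clip(gains.integral_state + e * dt,
                                         -limit, limit))
    return gains.kp * e + gains.ki * gains.integral_state


@dataclass
class RBFState:
    """Gaussian RBF network parameters with two-step momentum history."""

    weights: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    eta: float = 0.30           # learning rate η
    alpha_momentum: float = 0.05  # momentum factor α
    # previous two values of (w, c, b) for the momentum terms
    history: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths <= 0):
            raise ConfigError("RBF widths must be positive")
        if not (0 <= self.eta < 1) or not (0 <= self.alpha_momentum < 1):
            raise ConfigError("require eta in [0,1) and alpha in [0,1)")

    @property
    def n_hidden(self) -> int:
        return self.weights.size


def rbf_init(n_hidden: int = 11, seed: int = 0, eta: float = 0.30,
             alpha_momentum: float = 0.05,
             paper_five_node: bool = False) -> RBFState:
    """Fresh RBF state: weights uniform on [0, 1] (seeded).

    Default: 11 hidden nodes with centers linearly spaced over [−2, 2] and
    widths 5.  ``paper_five_node`` selects the printed 5-node preset
    c = [−2, −1, 0, 1, 2], b = [5, 5, 5, 5, 5].
    """
    rng = np.random.default_rng(seed)
    if paper_five_node:
        centers = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    else:
        centers = np.linspace(-2.0, 2.0, n_hidden)
    widths = np.full(centers.size, 5.0)
    weights = rng.uniform(0.0, 1.0, size=centers.size)
    return RBFState(weights=weights, centers=centers, widths=widths,
                    eta=eta, alpha_momentum=alpha_momentum)


def rbf_forward(x: float, state: RBFState) -> tuple[float, np.ndarray]:
    """Network output and hidden activations h_j = exp(−‖x−c_j‖²/(2b_j²))."""
    d2 = (x - state.centers) ** 2
    h = np.exp(-d2 / (2.0 * state.widths ** 2))
    return float(h @ state.weights), h


def rbf_update(u: float, u_rbf: float, h: np.ndarray, x: float,
               state: RBFState) -> RBFState:
    """One gradient-descent step on E = ½(u_rbf − u)² with momentum.

    Gradients (with err = u_rbf − u):
        Δw_j = −η·err·h_j
        Δb_j = −η·err·w_j·h_j·‖x−c_j‖²/b_j³
        Δc_j = −η·err·w_j·h_j·(x−c_j)/b_j²
    Each parameter then receives the momentum term α·(θ(t−1) − θ(t−2));
    before two updates have accumulated the momentum term is zero.  Widths
    are floored at a positive minimum.  ``u`` is the (clamped) command the
    plant received.
    """
    err = u_rbf - u
    w, c, b = state.weights, state.centers, state.widths
    d = x - c
    with np.errstate(invalid="ignore", over="ignore"):
        dw = -state.eta * err * h
        db = -state.eta * err * w * h * d ** 2 / b ** 3
        dc = -state.eta * err * w * h * d / b ** 2
    if not (np.all(np.isfinite(dw)) and np.all(np.isfinite(db))
            and np.all(np.isfinite(dc))):
        raise FloatingPointError("non-finite RBF gradient (learning diverged)")
    if len(state.history) >= 2:
        (w1, c1, b1), (w2, c2, b2) = state.history[-1], state.history[-2]
        mw = state.alpha_momentum * (w1 - w2)
        mc = state.alpha_momentum * (c1 - c2)
        mb = state.alpha_momentum * (b1 - b2)
    else:
        mw = mc = mb = 0.0
    new_w = w + dw + mw
    new_c = c + dc + mc
    new_b = np.maximum(b + db + mb, WIDTH_FLOOR)
    hist = (state.history + [(w.copy(), c.copy(), b.copy())])[-2:]
    return replace(state, weights=new_w, centers=new_c, widths=new_b,
                   history=hist)


@dataclass
class ControlSample:
    """One supervisory-control step, time-aligned for the loop log."""

    t: float        # s
    y: float        # measured beta power, dB
    y_d: float      # reference beta power, dB
    e: float        # excess-beta error y − y_d, dB
    u_p: float      # P/PI branch output, Hz
    u_rbf: float    # RBF branch output, Hz
    u: float        # total command after clamping, Hz


class SupervisoryController:
    """P/PI (+ optional RBF) supervisory controller over beta power.

    ``kind`` selects {"p", "pi", "rbf_p", "rbf_pi"}.  The RBF input is the
    reference beta power y_d mapped affinely onto [−2, 2] over
    ``beta_range`` (a feedforward inverse-model input); set
    ``rbf_input="error"`` to feed the tracking error instead.
    """

    def __init__(self, kind: str = "rbf_p", gains: PIGains | None = None,
                 rbf: RBFState | None = None, seed: int = 0,
                 beta_range: tuple[float, float] = (100.0, 140.0),
                 rbf_input: str = "reference"):
        if kind not in ("p", "pi", "rbf_p", "rbf_pi"):
            raise ConfigError(f"unknown controller kind {kind!r}")
        if rbf_input not in ("reference", "error"):
            raise ConfigError(f"unknown rbf_input {rbf_input!r}")
        self.kind = kind
        self.gains = gains if gains is not None else PIGains()
        self.rbf = rbf if rbf is not None else (
            rbf_init(seed=seed) if kind.startswith("rbf") else None)
        self.beta_range = beta_range
        self.rbf_input = rbf_input
        self.samples: list[ControlSample] = []

    def _normalize(self, value: float) -> float:
        lo, hi = self.beta_range
        return -2.0 + 4.0 * (value - lo) / (hi - lo)

    def step(self, y: float, y_d: float, dt: float, t: float = 0.0) -> ControlSample:
        """One measure→command cycle; updates internal states and logs."""
        e = y - y_d  # excess beta above target
        if self.kind in ("p", "rbf_p"):
            u_p = p_step(e, self.gains)
        else:
            u_p = pi_step(e, dt, self.gains)
        if self.rbf is not None:
            x = self._normalize(y_d if self.rbf_input == "reference" else e)
            u_rbf, h = rbf_forward(x, self.rbf)
        else:
            x, u_rbf, h = 0.0, 0.0, None
        u = clamp_command(u_p + u_rbf)
        if self.rbf is not None:
            self.rbf = rbf_update(u, u_rbf, h, x, self.rbf)
        sample = ControlSample(t=t, y=y, y_d=y_d, e=e, u_p=u_p,
                               u_rbf=u_rbf, u=u)
        self.samples.append(sample)
        return sample
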