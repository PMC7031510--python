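"""Single-compartment conductance-based HVC_X neuron simulator.

The membrane potential obeys the current balance equation

    C_m dV/dt = -I_L - I_K - I_Na - I_CaL - I_CaT - I_A - I_SK - I_h + I_app

with eight ionic currents: fast sodium (instantaneous cubed activation,
one inactivation gate), delayed-rectifier potassium (n^4), high-threshold
L-type and low-threshold T-type calcium, an A-type potassium current, a
calcium-activated SK potassium current driven by a first-order calcium
pool, a hyperpolarization-activated cation current (h-current), and leak.
The five maximal conductances g_Na, g_K, g_SK, g_h and g_CaT are the
quantities estimated by the fitting machinery; all other parameters are
held fixed at the values in ``reference_params.yaml``.

Units are mV, ms, pA, pF, nS and uM throughout, so that conductance times
voltage is directly a current in pA and C dV/dt balances in pA.

Integration is fixed-step 4th-order Runge-Kutta (default dt = 0.02 ms),
compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from numba import njit

__all__ = [
    "ModelParameters",
    "StimulusProtocol",
    "Trace",
    "SimulationError",
    "reference_parameters",
    "simulate",
    "holding_equilibrium",
    "resting_potential",
    "canonical_protocols",
    "chaotic_stimulus",
    "VARIED_CONDUCTANCES",
]

#: the five conductances varied during fitting, in canonical order
VARIED_CONDUCTANCES = ("g_Na", "g_K", "g_SK", "g_h", "g_CaT")

DEFAULT_DT = 0.02  # ms


class SimulationError(RuntimeError):
    """Raised when the integrator diverges for a parameter set."""


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

_PARAM_FIELDS = (
    # membrane
    "C_m",
    # maximal conductances (nS)
    "g_Na", "g_K", "g_SK", "g_h", "g_CaT", "g_CaL", "g_A", "g_L",
    # reversal potentials (mV)
    "E_Na", "E_K", "E_h", "E_Ca", "E_L",
    # sodium kinetics
    "m_half", "m_slope", "h_half", "h_slope",
    "tau_h_base", "tau_h_amp", "tau_h_mid", "tau_h_width",
    # potassium kinetics
    "n_half", "n_slope", "tau_n_base", "tau_n_amp", "tau_n_mid", "tau_n_width",
    # T-type calcium
    "a_half", "a_slope", "b_half", "b_slope", "tau_b",
    # h-current
    "r_half", "r_slope", "tau_r",
    # L-type calcium
    "s_half", "s_slope",
    # A-type potassium
    "e_half", "e_slope", "f_half", "f_slope", "tau_f",
    # calcium pool / SK
    "ca_influx", "tau_ca", "ca_base", "k_s",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the HVC_X model (units: mV, ms, pA, pF, nS, uM)."""

    C_m: float
    g_Na: float
    g_K: float
    g_SK: float
    g_h: float
    g_CaT: float
    g_CaL: float
    g_A: float
    g_L: float
    E_Na: float
    E_K: float
    E_h: float
    E_Ca: float
    E_L: float
    m_half: float
    m_slope: float
    h_half: float
    h_slope: float
    tau_h_base: float
    tau_h_amp: float
    tau_h_mid: float
    tau_h_width: float
    n_half: float
    n_slope: float
    tau_n_base: float
    tau_n_amp: float
    tau_n_mid: float
    tau_n_width: float
    a_half: float
    a_slope: float
    b_half: float
    b_slope: float
    tau_b: float
    r_half: float
    r_slope: float
    tau_r: float
    s_half: float
    s_slope: float
    e_half: float
    e_slope: float
    f_half: float
    f_slope: float
    tau_f: float
    ca_influx: float
    tau_ca: float
    ca_base: float
    k_s: float

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_SK", "g_h", "g_CaT", "g_CaL", "g_A", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if not (self.E_Na > 0 > self.E_K):
            raise ValueError("require E_Na > 0 > E_K")
        for name in ("tau_b", "tau_r", "tau_f", "tau_ca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _PARAM_FIELDS], dtype=np.float64)

    def with_conductances(self, **g: float) -> "ModelParameters":
        """Return a copy with the given maximal conductances replaced."""
        unknown = set(g) - {"g_Na", "g_K", "g_SK", "g_h", "g_CaT", "g_CaL", "g_A", "g_L"}
        if unknown:
            raise ValueError(f"unknown conductances: {sorted(unknown)}")
        return replace(self, **g)

    @property
    def varied(self) -> tuple[float, float, float, float, float]:
        return tuple(getattr(self, n) for n in VARIED_CONDUCTANCES)


def reference_parameters(juvenile: bool = False) -> ModelParameters:
    """Load the versioned reference parameter set.

    Juvenile neurons use a 50% larger capacitance (75 pF vs 50 pF), reflecting
    their larger somata; all kinetics are shared.
    """
    text = resources.files("hvcx").joinpath("reference_params.yaml").read_text()
    raw = yaml.safe_load(text)
    kw: dict[str, float] = {"C_m": float(raw["capacitance_pF"])}
    kw.update({k: float(v) for k, v in raw["conductances_nS"].items()})
    kw.update({k: float(v) for k, v in raw["reversals_mV"].items()})
    for section in ("sodium", "potassium", "ca_t", "h_current", "ca_l", "a_current"):
        kw.update({k: float(v) for k, v in raw[section].items()})
    pool = raw["calcium_pool"]
    kw.update(
        ca_influx=float(pool["influx"]),
        tau_ca=float(pool["tau_ca"]),
        ca_base=float(pool["ca_base"]),
        k_s=float(pool["k_s"]),
    )
    if juvenile:
        kw["C_m"] *= 1.5
    return ModelParameters(**kw)


# --------------------------------------------------------------------------
# stimulus protocols
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of one current-clamp stimulus.

    ``kind`` is ``step`` (constant pulse of ``amplitude_pA``), ``chaotic``
    (Lorenz-derived waveform stored in ``waveform``) or ``custom``
    (caller-supplied ``waveform``).  The canonical step protocol is 200 ms of
    quiescence, a 200 ms pulse, and 200 ms of quiescence.
    """

    kind: str = "step"
    amplitude_pA: float = 0.0
    pre_ms: float = 200.0
    stim_ms: float = 200.0
    post_ms: float = 200.0
    dt_ms: float = DEFAULT_DT
    holding_mV: float = -70.0
    seed: int | None = None
    waveform: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("step", "chaotic", "custom"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if min(self.pre_ms, self.stim_ms, self.post_ms) < 0:
            raise ValueError("durations must be >= 0")
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.kind in ("chaotic", "custom") and self.waveform is None:
            raise ValueError(f"{self.kind} protocol requires a waveform")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.stim_ms + self.post_ms

    def n_samples(self) -> int:
        return int(round(self.total_ms / self.dt_ms)) + 1

    def current_series(self) -> np.ndarray:
        """Injected current at every sample of the time grid (pA), without bias."""
        n = self.n_samples()
        i = np.zeros(n)
        i0 = int(round(self.pre_ms / self.dt_ms))
        i1 = int(round((self.pre_ms + self.stim_ms) / self.dt_ms))
        if self.kind == "step":
            i[i0:i1] = self.amplitude_pA
        else:
            w = np.asarray(self.waveform, dtype=float)
            m = min(len(w), i1 - i0)
            i[i0 : i0 + m] = w[:m]
        return i


@dataclass
class Trace:
    """One voltage time series with its stimulus and provenance metadata."""

    t: np.ndarray  # ms, uniform grid starting at 0
    v: np.ndarray  # mV
    i: np.ndarray  # injected current, pA (including any holding bias)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.i)):
            raise ValueError("time, voltage and current series must share a length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def canonical_protocols(dt: float = DEFAULT_DT, holding: float = -70.0) -> list[StimulusProtocol]:
    """The standard stimulation family: 40 pA steps out to +/-200 pA, plus the
    canonical +100 pA and -140 pA fitting pulses, each 200/200/200 ms."""
    amps = [40, 80, 120, 160, 200, -40, -80, -120, -160, -200, 100, -140]
    return [
        StimulusProtocol(kind="step", amplitude_pA=float(a), dt_ms=dt, holding_mV=holding)
        for a in amps
    ]


def chaotic_stimulus(
    seed: int,
    scale: float = 150.0,
    duration: float = 1000.0,
    dt: float = DEFAULT_DT,
    pre_ms: float = 200.0,
    post_ms: float = 200.0,
) -> StimulusProtocol:
    """Complex, chaotic current waveform from the x-component of a Lorenz system.

    The seed sets the initial condition; one Lorenz time unit is mapped to
    50 ms.  The waveform is mean-subtracted and rescaled so its peak
    magnitude equals ``scale`` (pA); identical seeds give identical waveforms.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    y = np.array([rng.uniform(-10, 10), rng.uniform(-15, 15), rng.uniform(15, 35)])
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0
    h = dt / 50.0  # Lorenz time step

    def lorenz(y):
        x, yy, z = y
        return np.array([sigma * (yy - x), x * (rho - z) - yy, x * yy - beta * z])

    n = int(round(duration / dt))
    # burn in five Lorenz time units: past the transient and long enough for
    # nearby initial conditions to separate on the attractor
    for _ in range(int(round(5.0 / h))):
        k1 = lorenz(y); k2 = lorenz(y + 0.5 * h * k1)
        k3 = lorenz(y + 0.5 * h * k2); k4 = lorenz(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    xs = np.empty(n)
    for j in range(n):
        k1 = lorenz(y); k2 = lorenz(y + 0.5 * h * k1)
        k3 = lorenz(y + 0.5 * h * k2); k4 = lorenz(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        xs[j] = y[0]
    xs -= xs.mean()
    xs *= scale / np.max(np.abs(xs))
    return StimulusProtocol(
        kind="chaotic",
        pre_ms=pre_ms,
        stim_ms=n * dt,
        post_ms=post_ms,
        dt_ms=dt,
        seed=seed,
        waveform=xs,
    )


# --------------------------------------------------------------------------
# numba core
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _derivs(y, p, i_app, out):
    V = y[0]
    hh = y[1]
    nn = y[2]
    bb = y[3]
    rr = y[4]
    ff = y[5]
    ca = y[6]

    m_inf = 1.0 / (1.0 + math.exp((p[14] - V) / p[15]))
    h_inf = 1.0 / (1.0 + math.exp((p[16] - V) / p[17]))
    dh = (V - p[20]) / p[21]
    tau_h = p[18] + p[19] * math.exp(-dh * dh)
    n_inf = 1.0 / (1.0 + math.exp((p[22] - V) / p[23]))
    dn = (V - p[26]) / p[27]
    tau_n = p[24] + p[25] * math.exp(-dn * dn)
    a_inf = 1.0 / (1.0 + math.exp((p[28] - V) / p[29]))
    b_inf = 1.0 / (1.0 + math.exp((p[30] - V) / p[31]))
    r_inf = 1.0 / (1.0 + math.exp((p[33] - V) / p[34]))
    s_inf = 1.0 / (1.0 + math.exp((p[36] - V) / p[37]))
    e_inf = 1.0 / (1.0 + math.exp((p[38] - V) / p[39]))
    f_inf = 1.0 / (1.0 + math.exp((p[40] - V) / p[41]))

    i_na = p[1] * m_inf * m_inf * m_inf * hh * (V - p[9])
    i_k = p[2] * nn * nn * nn * nn * (V - p[10])
    ca2 = ca * ca
    i_sk = p[3] * (ca2 / (ca2 + p[46] * p[46])) * (V - p[10])
    i_h = p[4] * rr * (V - p[11])
    i_cat = p[5] * a_inf * a_inf * bb * (V - p[12])
    i_cal = p[6] * s_inf * s_inf * (V - p[12])
    i_a = p[7] * e_inf * ff * (V - p[10])
    i_l = p[8] * (V - p[13])

    out[0] = (-(i_na + i_k + i_sk + i_h + i_cat + i_cal + i_a + i_l) + i_app) / p[0]
    out[1] = (h_inf - hh) / tau_h
    out[2] = (n_inf - nn) / tau_n
    out[3] = (b_inf - bb) / p[32]
    out[4] = (r_inf - rr) / p[35]
    out[5] = (f_inf - ff) / p[42]
    out[6] = -p[43] * (i_cat + i_cal) - (ca - p[45]) / p[44]


@njit(cache=True, fastmath=True)
def _integrate(y0, p, i_app, dt):
    """Fixed-step RK4; i_app gives the injected current at each recorded sample
    (zero-order hold across each step).  Returns (V-series, final state, ok)."""
    n = i_app.shape[0]
    v = np.empty(n)
    y = y0.copy()
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    yt = np.empty(7)
    v[0] = y[0]
    ok = True
    for j in range(n - 1):
        i0 = i_app[j]
        _derivs(y, p, i0, k1)
        for q in range(7):
            yt[q] = y[q] + 0.5 * dt * k1[q]
        _derivs(yt, p, i0, k2)
        for q in range(7):
            yt[q] = y[q] + 0.5 * dt * k2[q]
        _derivs(yt, p, i0, k3)
        for q in range(7):
            yt[q] = y[q] + dt * k3[q]
        _derivs(yt, p, i0, k4)
        for q in range(7):
            y[q] = y[q] + (dt / 6.0) * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q])
        if y[6] < 0.0:
            y[6] = 0.0
        v[j + 1] = y[0]
        if not (abs(y[0]) <= 200.0):
            ok = False
            break
    return v, y, ok


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def _steady_currents(params: ModelParameters, V: float) -> float:
    """Total ionic current (pA) with every gate at steady state for voltage V."""
    p = params

    def sig(half, slope):
        return 1.0 / (1.0 + math.exp((half - V) / slope))

    m = sig(p.m_half, p.m_slope)
    h = sig(p.h_half, p.h_slope)
    n = sig(p.n_half, p.n_slope)
    a = sig(p.a_half, p.a_slope)
    b = sig(p.b_half, p.b_slope)
    r = sig(p.r_half, p.r_slope)
    s = sig(p.s_half, p.s_slope)
    e = sig(p.e_half, p.e_slope)
    f = sig(p.f_half, p.f_slope)
    i_cat = p.g_CaT * a * a * b * (V - p.E_Ca)
    i_cal = p.g_CaL * s * s * (V - p.E_Ca)
    ca = max(p.ca_base - p.ca_influx * p.tau_ca * (i_cat + i_cal), 0.0)
    i_sk = p.g_SK * (ca * ca / (ca * ca + p.k_s**2)) * (V - p.E_K)
    total = (
        p.g_Na * m**3 * h * (V - p.E_Na)
        + p.g_K * n**4 * (V - p.E_K)
        + i_sk
        + p.g_h * r * (V - p.E_h)
        + i_cat
        + i_cal
        + p.g_A * e * f * (V - p.E_K)
        + p.g_L * (V - p.E_L)
    )
    return total


def _steady_state(params: ModelParameters, V: float) -> np.ndarray:
    p = params

    def sig(half, slope):
        return 1.0 / (1.0 + math.exp((half - V) / slope))

    a = sig(p.a_half, p.a_slope)
    b = sig(p.b_half, p.b_slope)
    s = sig(p.s_half, p.s_slope)
    i_cat = p.g_CaT * a * a * b * (V - p.E_Ca)
    i_cal = p.g_CaL * s * s * (V - p.E_Ca)
    ca = max(p.ca_base - p.ca_influx * p.tau_ca * (i_cat + i_cal), 0.0)
    return np.array(
        [
            V,
            sig(p.h_half, p.h_slope),
            sig(p.n_half, p.n_slope),
            b,
            sig(p.r_half, p.r_slope),
            sig(p.f_half, p.f_slope),
            ca,
        ]
    )


def holding_equilibrium(
    params: ModelParameters, target: float = -70.0, max_current: float = 500.0
) -> tuple[np.ndarray, float]:
    """State vector and constant bias current that hold the cell at ``target`` mV.

    With all gates at their steady-state values for the target voltage and the
    calcium pool at its steady concentration, the bias current equals the total
    steady ionic current, making the target an exact fixed point.
    """
    if not (-90.0 <= target <= -50.0):
        raise ValueError("holding target must lie in [-90, -50] mV")
    i_hold = _steady_currents(params, target)
    if abs(i_hold) > max_current:
        raise SimulationError(
            f"no holding equilibrium at {target} mV within +/-{max_current} pA "
            f"(required {i_hold:.1f} pA)"
        )
    return _steady_state(params, target), float(i_hold)


def resting_potential(params: ModelParameters, lo: float = -90.0, hi: float = -50.0) -> float:
    """Natural resting potential: the zero of the steady-state I-V curve (mV)."""
    from scipy.optimize import brentq

    f = lambda V: _steady_currents(params, V)
    # the steady-state I-V curve can be N-shaped; bracket the hyperpolarized
    # crossing on a fine scan before root-polishing
    grid = np.linspace(lo, hi, 161)
    vals = np.array([f(V) for V in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if len(sign_change) == 0:
        raise SimulationError("no resting potential in [-90, -50] mV")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    return float(brentq(f, a, b, xtol=1e-6))


def simulate(
    params: ModelParameters,
    protocol: StimulusProtocol,
    initial_state: np.ndarray | None = None,
    hold: bool = True,
    meta: Mapping | None = None,
) -> Trace:
    """Integrate the current balance equation for one stimulus protocol.

    By default the cell is first placed at the holding equilibrium for the
    protocol's holding voltage and the corresponding constant bias current is
    added to the injected stimulus, mirroring the experimental procedure of
    holding every cell at -70 mV before stimulation.  Deterministic for fixed
    parameters and protocol.
    """
    dt = protocol.dt_ms
    i_stim = protocol.current_series()
    if hold:
        state, i_bias = holding_equilibrium(params, protocol.holding_mV)
    else:
        state, i_bias = _steady_state(params, resting_potential(params)), 0.0
    if initial_state is not None:
        state = np.asarray(initial_state, dtype=float).copy()
    i_app = i_stim + i_bias
    v, _, ok = _integrate(state, params.to_vector(), i_app, dt)
    if not ok:
        raise SimulationError(
            "integration diverged (|V| > 200 mV or non-finite) for conductances "
            f"g_Na={params.g_Na}, g_K={params.g_K}, g_SK={params.g_SK}, "
            f"g_h={params.g_h}, g_CaT={params.g_CaT}"
        )
    t = np.arange(len(i_app)) * dt
    md = {
        "provenance": "simulated",
        "protocol_kind": protocol.kind,
        "amplitude_pA": protocol.amplitude_pA,
        "pre_ms": protocol.pre_ms,
        "stim_ms": protocol.stim_ms,
        "post_ms": protocol.post_ms,
        "dt_ms": dt,
        "holding_mV": protocol.holding_mV,
        "holding_pA": i_bias,
    }
    if meta:
        md.update(meta)
    return Trace(t=t, v=v, i=i_app, meta=md)
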