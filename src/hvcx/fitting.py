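"""Conductance estimation by exhaustive grid search.

The estimator compares a neuron's responses to the canonical +100 pA and
-140 pA pulses against model simulations at every point of a 5-D grid over
(g_Na, g_K, g_SK, g_h, g_CaT), scoring each candidate with a unit-free
error that sums normalized squared differences over eight response
features: plateau amplitude, spike amplitude, spike duration, number of
spikes, the timing of each individual spike, resting membrane potential,
sag ratio and rebound firing.  During the search, any candidate whose
simulated spike count differs from the biological trace is disregarded
before the error is computed.  Prediction scoring (held-out current
amplitudes) and leave-bird-out cross-validation reuse the same error with
a spike-count penalty instead of the disregard rule, since a prediction
cannot be discarded.

The full published grid has 2,426,127,936 points and is cluster-scale; the
default desk grid subsamples each axis over the same ranges.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hvcx import hh
from hvcx.features import FeatureVector, extract_features
from hvcx.hh import ModelParameters, StimulusProtocol, Trace

__all__ = [
    "ConductanceSet",
    "GridSpec",
    "FitResult",
    "GridSearchFit",
    "fit_error",
    "grid_size",
    "prediction_scores",
    "cross_validate",
    "local_search",
    "DEFAULT_NORMALIZERS",
]

AXES = hh.VARIED_CONDUCTANCES  # ("g_Na", "g_K", "g_SK", "g_h", "g_CaT")

#: species-scale constants dividing each feature difference before squaring
DEFAULT_NORMALIZERS = {
    "voltage_mV": 10.0,  # plateau amplitude, spike amplitude, resting potential
    "time_ms": 5.0,  # spike timing, spike duration
    "count": 1.0,  # spike count, rebound count
    "sag": 0.1,  # sag ratio
}
#: penalty (normalized units, squared before use) for a waveform feature
#: defined on exactly one side of a comparison
MISSING_FEATURE_PENALTY = 2.0


@dataclass(frozen=True, order=True)
class ConductanceSet:
    """The five varied maximal conductances of one neuron (nS).

    Ordering is lexicographic on (g_Na, g_K, g_SK, g_h, g_CaT), the
    deterministic tie-break used by the grid search.
    """

    g_Na: float
    g_K: float
    g_SK: float
    g_h: float
    g_CaT: float

    def __post_init__(self) -> None:
        for name in AXES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in AXES)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple())

    def apply(self, base: ModelParameters) -> ModelParameters:
        return base.with_conductances(**{n: getattr(self, n) for n in AXES})


@dataclass(frozen=True)
class GridSpec:
    """Per-conductance (min, max, step) in nS defining an exhaustive grid."""

    axes: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if tuple(self.axes) != AXES:
            raise ValueError(f"grid must define exactly the axes {AXES}")
        for name, (lo, hi, step) in self.axes.items():
            if lo > hi:
                raise ValueError(f"{name}: min > max")
            if step <= 0:
                raise ValueError(f"{name}: step must be > 0")

    @classmethod
    def published(cls) -> "GridSpec":
        """The full cluster-scale grid: g_Na 200-2500 by 20, g_K 50-750 by 10,
        g_SK 0-15 by 0.2, g_h 0-15 by 0.2, g_CaT 0-10 by 0.2."""
        return cls(
            {
                "g_Na": (200.0, 2500.0, 20.0),
                "g_K": (50.0, 750.0, 10.0),
                "g_SK": (0.0, 15.0, 0.2),
                "g_h": (0.0, 15.0, 0.2),
                "g_CaT": (0.0, 10.0, 0.2),
            }
        )

    @classmethod
    def desk(cls, points: int | Sequence[int] = 5) -> "GridSpec":
        """Coarse grid spanning the published ranges with ``points`` values
        per axis (scalar or one count per axis)."""
        pub = cls.published()
        if np.isscalar(points):
            points = [int(points)] * 5
        axes = {}
        for name, n in zip(AXES, points):
            lo, hi, _ = pub.axes[name]
            axes[name] = (lo, hi, (hi - lo) / (n - 1))
        return cls(axes)

    def axis_values(self, name: str) -> np.ndarray:
        lo, hi, step = self.axes[name]
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    def axis_counts(self) -> tuple[int, ...]:
        return tuple(len(self.axis_values(n)) for n in AXES)

    @property
    def size(self) -> int:
        return int(np.prod([len(self.axis_values(n)) for n in AXES], dtype=object))

    def points(self) -> Iterable[ConductanceSet]:
        """All grid candidates in lexicographic order."""
        values = [self.axis_values(n) for n in AXES]
        for combo in itertools.product(*values):
            yield ConductanceSet(*(float(x) for x in combo))

    def snap(self, point: ConductanceSet) -> ConductanceSet:
        """Nearest grid point to an arbitrary conductance set."""
        out = []
        for name in AXES:
            vals = self.axis_values(name)
            out.append(float(vals[np.argmin(np.abs(vals - getattr(point, name)))]))
        return ConductanceSet(*out)


def grid_size(grid: GridSpec) -> int:
    """Number of candidates: product over axes of floor((max-min)/step) + 1."""
    return grid.size


# --------------------------------------------------------------------------
# error function
# --------------------------------------------------------------------------


def _term(a: float, b: float, scale: float) -> float:
    a_ok, b_ok = math.isfinite(a), math.isfinite(b)
    if a_ok and b_ok:
        return ((a - b) / scale) ** 2
    if a_ok != b_ok:  # defined on exactly one side: penalized, never skipped
        return MISSING_FEATURE_PENALTY**2
    return 0.0


def fit_error(
    model_fv: FeatureVector,
    bio_fv: FeatureVector,
    normalizers: Mapping[str, float] | None = None,
    pulse_ms: float = 200.0,
) -> float:
    """Unit-free sum of normalized squared feature differences.

    Symmetric in its arguments, non-negative, and zero iff every compared
    feature is equal.  Spike trains with unequal counts are matched in order
    up to the shorter count; each unmatched spike contributes a fixed
    penalty of (pulse duration / timing normalizer)^2.
    """
    s = dict(DEFAULT_NORMALIZERS)
    if normalizers:
        s.update(normalizers)
    sv, st, sc, ss = s["voltage_mV"], s["time_ms"], s["count"], s["sag"]

    err = 0.0
    err += _term(model_fv.plateau_amplitude, bio_fv.plateau_amplitude, sv)
    err += _term(model_fv.first_spike_amplitude, bio_fv.first_spike_amplitude, sv)
    err += _term(model_fv.first_spike_duration, bio_fv.first_spike_duration, st)
    err += ((model_fv.n_spikes - bio_fv.n_spikes) / sc) ** 2
    err += _term(model_fv.resting_potential, bio_fv.resting_potential, sv)
    err += _term(model_fv.sag_ratio, bio_fv.sag_ratio, ss)
    err += ((model_fv.rebound_spikes - bio_fv.rebound_spikes) / sc) ** 2

    ta, tb = model_fv.spike_times, bio_fv.spike_times
    m = min(len(ta), len(tb))
    if m:
        err += float(np.sum(((ta[:m] - tb[:m]) / st) ** 2))
    err += abs(len(ta) - len(tb)) * (pulse_ms / st) ** 2
    return err


# --------------------------------------------------------------------------
# fast canonical-pulse simulation used by the search
# --------------------------------------------------------------------------


def _fast_step_trace(
    params: ModelParameters,
    amplitude: float,
    dt: float,
    pre_ms: float,
    stim_ms: float,
    post_ms: float,
    holding: float = -70.0,
) -> Trace:
    """Step-pulse simulation that synthesizes the constant pre-pulse segment
    analytically (the cell sits at its holding equilibrium, an exact fixed
    point) and integrates only the pulse and post-pulse intervals."""
    state, bias = hh.holding_equilibrium(params, holding)
    n_pre = int(round(pre_ms / dt))
    n_stim = int(round(stim_ms / dt))
    n_post = int(round(post_ms / dt))
    i_dyn = np.empty(n_stim + n_post + 1)
    i_dyn[:n_stim] = bias + amplitude  # pulse half-open: [onset, offset)
    i_dyn[n_stim:] = bias
    v_dyn, _, ok = hh._integrate(state, params.to_vector(), i_dyn, dt)
    if not ok:
        raise hh.SimulationError(
            f"integration diverged at {amplitude} pA for g_Na={params.g_Na}, "
            f"g_K={params.g_K}, g_SK={params.g_SK}, g_h={params.g_h}, g_CaT={params.g_CaT}"
        )
    n = n_pre + n_stim + n_post + 1
    v = np.empty(n)
    i = np.empty(n)
    v[:n_pre] = holding
    i[:n_pre] = bias
    v[n_pre:] = v_dyn
    i[n_pre:] = i_dyn
    t = np.arange(n) * dt
    return Trace(t=t, v=v, i=i, meta={"provenance": "simulated", "dt_ms": dt})


def simulate_canonical_pair(
    params: ModelParameters,
    dt: float = hh.DEFAULT_DT,
    depol_pA: float = 100.0,
    hyperpol_pA: float = -140.0,
    depol_post_ms: float = 40.0,
) -> tuple[Trace, Trace]:
    """(depolarizing, hyperpolarizing) canonical-pulse traces for a parameter
    set, using the fast fixed-point pre-pulse path.  The depolarizing trace
    carries a short post-pulse tail (no feature is read there); the
    hyperpolarizing trace keeps the full 200 ms tail for rebound counting."""
    d = _fast_step_trace(params, depol_pA, dt, 200.0, 200.0, depol_post_ms)
    h = _fast_step_trace(params, hyperpol_pA, dt, 200.0, 200.0, 200.0)
    return d, h


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of an exhaustive search for one neuron."""

    params: ConductanceSet
    error: float
    n_evaluated: int
    n_disregarded: int
    neuron_id: str | None
    grid: GridSpec
    base_params: ModelParameters
    bio_features: FeatureVector
    model_features: FeatureVector
    normalizers: Mapping[str, float]
    dt: float
    error_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Exhaustive conductance fit",
            "=" * 42,
            f"neuron:            {self.neuron_id or '-'}",
            f"grid candidates:   {self.grid.size}",
            f"evaluated:         {self.n_evaluated}",
            f"disregarded:       {self.n_disregarded} (spike-count mismatch)",
            f"best error:        {self.error:.6g}",
            "-" * 42,
        ]
        for name in AXES:
            lo, hi, step = self.grid.axes[name]
            lines.append(
                f"{name:<7} {getattr(self.params, name):>10.3f} nS   "
                f"(grid {lo:g}..{hi:g} step {step:g})"
            )
        return "\n".join(lines)

    def fitted_parameters(self) -> ModelParameters:
        return self.params.apply(self.base_params)

    def predict(self, amplitude: float, dt: float | None = None) -> Trace:
        """Simulate the fitted model's response to a canonical-geometry step."""
        prot = StimulusProtocol(kind="step", amplitude_pA=amplitude, dt_ms=dt or self.dt)
        return hh.simulate(self.fitted_parameters(), prot)

    def landscape(self, axis_x: str, axis_y: str) -> pd.DataFrame:
        """2-D error-slice: minimum error over the other axes, for each
        (axis_x, axis_y) pair.  Requires the search to have stored errors."""
        if self.error_table is None:
            raise ValueError("search was run without store_errors=True")
        ok = self.error_table[~self.error_table["disregarded"]]
        return ok.pivot_table(index=axis_y, columns=axis_x, values="error", aggfunc="min")


class GridSearchFit:
    """Exhaustive grid-search estimator for one neuron's five conductances.

    Parameters
    ----------
    depol_trace, hyperpol_trace
        The neuron's responses to the canonical +100 pA and -140 pA pulses.
    grid
        Search grid; defaults to the 5-points-per-axis desk grid over the
        published ranges.
    base_params
        Fixed model parameters (kinetics, capacitance, fixed conductances);
        defaults to the adult reference set.
    """

    def __init__(
        self,
        depol_trace: Trace,
        hyperpol_trace: Trace,
        grid: GridSpec | None = None,
        base_params: ModelParameters | None = None,
        normalizers: Mapping[str, float] | None = None,
        dt: float | None = None,
        neuron_id: str | None = None,
    ) -> None:
        self.depol_trace = depol_trace
        self.hyperpol_trace = hyperpol_trace
        self.grid = grid or GridSpec.desk(5)
        self.base_params = base_params or hh.reference_parameters()
        self.normalizers = dict(DEFAULT_NORMALIZERS)
        if normalizers:
            self.normalizers.update(normalizers)
        self.dt = dt or depol_trace.dt
        self.neuron_id = neuron_id
        self.bio_features = extract_features(depol_trace, hyperpol_trace)

    def fit(self, store_errors: bool = False) -> FitResult:
        """Evaluate every grid candidate and return the global minimum.

        Candidates whose +100 pA spike count differs from the biological
        trace are disregarded before the error is computed; ties on the error
        break lexicographically on (g_Na, g_K, g_SK, g_h, g_CaT).
        """
        bio = self.bio_features
        best: tuple[float, tuple[float, ...]] | None = None
        best_model_fv: FeatureVector | None = None
        n_eval = 0
        n_disregarded = 0
        rows = [] if store_errors else None

        for cand in self.grid.points():
            n_eval += 1
            params = cand.apply(self.base_params)
            try:
                d_tr = _fast_step_trace(params, 100.0, self.dt, 200.0, 200.0, 40.0)
            except hh.SimulationError:
                n_disregarded += 1
                if rows is not None:
                    rows.append((*cand.as_tuple(), math.nan, True))
                continue
            if _pulse_spike_count(d_tr) != bio.n_spikes:
                n_disregarded += 1
                if rows is not None:
                    rows.append((*cand.as_tuple(), math.nan, True))
                continue
            try:
                h_tr = _fast_step_trace(params, -140.0, self.dt, 200.0, 200.0, 200.0)
            except hh.SimulationError:
                n_disregarded += 1
                if rows is not None:
                    rows.append((*cand.as_tuple(), math.nan, True))
                continue
            model_fv = extract_features(d_tr, h_tr)
            err = fit_error(model_fv, bio, self.normalizers)
            if rows is not None:
                rows.append((*cand.as_tuple(), err, False))
            key = (err, cand.as_tuple())
            if best is None or key < best:
                best = key
                best_model_fv = model_fv

        if best is None:
            raise RuntimeError(
                "no admissible candidate: every grid point was disregarded "
                "(spike-count mismatch or divergence)"
            )
        table = None
        if rows is not None:
            table = pd.DataFrame(rows, columns=[*AXES, "error", "disregarded"])
        return FitResult(
            params=ConductanceSet(*best[1]),
            error=best[0],
            n_evaluated=n_eval,
            n_disregarded=n_disregarded,
            neuron_id=self.neuron_id,
            grid=self.grid,
            base_params=self.base_params,
            bio_features=bio,
            model_features=best_model_fv,
            normalizers=self.normalizers,
            dt=self.dt,
            error_table=table,
        )


def _pulse_spike_count(trace: Trace) -> int:
    """Spike count inside the depolarizing pulse (the disregard-rule quantity)."""
    from hvcx.features import detect_spikes, pulse_window

    t_on, t_off, _ = pulse_window(trace)
    return sum(1 for e in detect_spikes(trace) if t_on <= e.peak_time < t_off)


# --------------------------------------------------------------------------
# prediction scoring and cross-validation
# --------------------------------------------------------------------------


def prediction_scores(
    fit: FitResult,
    held_out: Mapping[float, Trace],
    epsilon: float = 1e-6,
) -> dict[float, float]:
    """Ratio of held-out prediction error to the fitted 100 pA error.

    For each held-out amplitude the fitted model is simulated at that
    amplitude, features are extracted (pairing with the fitted -140 pA
    responses for the hyperpolarizing-side features), and the error against
    the held-out biological trace is divided by the 100 pA fit error.
    Spike-count mismatches contribute the unmatched-spike penalty; a
    prediction cannot be disregarded.
    """
    denom = fit.error
    if denom <= 0:
        warnings.warn("perfect 100 pA fit; prediction ratios use a floor epsilon")
        denom = epsilon
    params = fit.fitted_parameters()
    model_h = _fast_step_trace(params, -140.0, fit.dt, 200.0, 200.0, 200.0)
    out = {}
    for amp, bio_tr in held_out.items():
        model_d = _fast_step_trace(params, float(amp), fit.dt, 200.0, 200.0, 40.0)
        model_fv = extract_features(model_d, model_h)
        bio_fv = extract_features(bio_tr, model_h)
        # hyperpolarizing-side features cancel (shared trace); the score is
        # driven by the depolarizing response at the held-out amplitude
        out[float(amp)] = fit_error(model_fv, bio_fv, fit.normalizers) / denom
    return out


def cross_validate(
    records: Sequence[Mapping],
    base_params: ModelParameters | None = None,
    dt: float = hh.DEFAULT_DT,
    normalizers: Mapping[str, float] | None = None,
    epsilon: float = 1e-6,
) -> tuple[pd.DataFrame, float]:
    """Leave-bird-out cross-prediction matrix of normalized errors.

    ``records`` holds one best-fit neuron per bird:
    ``{"bird_id", "fitted": ConductanceSet, "bio_100", "bio_140", "bio_150"}``.
    Entry (j, k) is the error of bird j's model prediction at 150 pA against
    bird k's actual 150 pA response, divided by bird j's own 100 pA fit
    error.  Returns the matrix and the summary ratio
    mean(off-diagonal) / mean(diagonal).
    """
    if len(records) < 3:
        raise ValueError("cross-validation requires at least 3 birds")
    base = base_params or hh.reference_parameters()
    ids = [r["bird_id"] for r in records]

    model_fv_150 = []
    fit_err_100 = []
    bio_fv_150 = []
    for r in records:
        params = r["fitted"].apply(base)
        m100 = _fast_step_trace(params, 100.0, dt, 200.0, 200.0, 40.0)
        m140 = _fast_step_trace(params, -140.0, dt, 200.0, 200.0, 200.0)
        m150 = _fast_step_trace(params, 150.0, dt, 200.0, 200.0, 40.0)
        model_fv_150.append(extract_features(m150, m140))
        bio_fv_150.append(extract_features(r["bio_150"], r["bio_140"]))
        e100 = fit_error(
            extract_features(m100, m140),
            extract_features(r["bio_100"], r["bio_140"]),
            normalizers,
        )
        fit_err_100.append(max(e100, epsilon))

    n = len(records)
    mat = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            e = fit_error(model_fv_150[j], bio_fv_150[k], normalizers)
            mat[j, k] = e / fit_err_100[j]
    df = pd.DataFrame(mat, index=ids, columns=ids)
    off = mat[~np.eye(n, dtype=bool)]
    summary = float(off.mean() / np.diag(mat).mean())
    return df, summary


def local_search(
    model: GridSearchFit,
    n_restarts: int = 3,
    seed: int = 0,
    max_steps: int = 50,
) -> FitResult:
    """Randomized-restart greedy descent on the same grid (utility; by
    construction it can never return a lower error than the exhaustive
    search on the same grid)."""
    rng = np.random.default_rng(seed)
    values = [model.grid.axis_values(n) for n in AXES]
    bio = model.bio_features

    def evaluate(idx: tuple[int, ...]) -> float:
        cand = ConductanceSet(*(float(values[a][i]) for a, i in enumerate(idx)))
        params = cand.apply(model.base_params)
        try:
            d_tr = _fast_step_trace(params, 100.0, model.dt, 200.0, 200.0, 40.0)
        except hh.SimulationError:
            return math.inf
        if _pulse_spike_count(d_tr) != bio.n_spikes:
            return math.inf
        try:
            h_tr = _fast_step_trace(params, -140.0, model.dt, 200.0, 200.0, 200.0)
        except hh.SimulationError:
            return math.inf
        return fit_error(extract_features(d_tr, h_tr), bio, model.normalizers)

    cache: dict[tuple[int, ...], float] = {}

    def ev(idx):
        if idx not in cache:
            cache[idx] = evaluate(idx)
        return cache[idx]

    best_idx, best_err = None, math.inf
    for _ in range(n_restarts):
        # draw restart points until one is admissible (spike count can match)
        idx = tuple(rng.integers(0, len(v)) for v in values)
        err = ev(idx)
        for _ in range(30):
            if math.isfinite(err):
                break
            idx = tuple(rng.integers(0, len(v)) for v in values)
            err = ev(idx)
        for _ in range(max_steps):
            improved = False
            for a in range(5):
                for d in (-1, 1):
                    j = idx[a] + d
                    if 0 <= j < len(values[a]):
                        cand = (*idx[:a], j, *idx[a + 1 :])
                        e = ev(cand)
                        if e < err:
                            idx, err, improved = cand, e, True
            if not improved:
                break
        if err < best_err:
            best_idx, best_err = idx, err

    if best_idx is None or not math.isfinite(best_err):
        raise RuntimeError("no admissible candidate found by local search")
    cand = ConductanceSet(*(float(values[a][i]) for a, i in enumerate(best_idx)))
    params = cand.apply(model.base_params)
    d_tr = _fast_step_trace(params, 100.0, model.dt, 200.0, 200.0, 40.0)
    h_tr = _fast_step_trace(params, -140.0, model.dt, 200.0, 200.0, 200.0)
    return FitResult(
        params=cand,
        error=best_err,
        n_evaluated=len(cache),
        n_disregarded=sum(1 for v in cache.values() if not math.isfinite(v)),
        neuron_id=model.neuron_id,
        grid=model.grid,
        base_params=model.base_params,
        bio_features=bio,
        model_features=extract_features(d_tr, h_tr),
        normalizers=model.normalizers,
        dt=model.dt,
    )
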