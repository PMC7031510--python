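"""Population-level statistics over fitted conductances and spike features.

Implements the dispersion measures (trace volume, determinant-based
geometric volume, species normalization), Mahalanobis distance between
birds' conductance clouds, a from-scratch one-way MANOVA with Wilks'
lambda (Rao's F approximation, optional pairwise mode with Bonferroni
correction), the bespoke clustering-distance, spike-time-ratio,
waveform-MSE and rundown tests, the song-similarity vs conductance-
distance correlation, volume-vs-covariate regressions, and PCA
variance-explained summaries.

All covariances are sample covariances with 1/(N-1) normalization, so
that the trace volume satisfies V(B)^2 = trace(cov) exactly.  All t and
F tests are two-tailed; every resampling operation takes an explicit
seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BirdConductances",
    "VolumeStats",
    "ManovaResult",
    "trace_volume",
    "geometric_volume",
    "volume_stats",
    "mahalanobis_distance",
    "conductance_distance_matrix",
    "manova",
    "pairwise_manova",
    "clustering_distance_test",
    "spike_time_ratio_test",
    "pairwise_waveform_msd",
    "waveform_mse_test",
    "variance_ratio_test",
    "rundown_check",
    "similarity_distance_correlation",
    "volume_vs_covariate",
    "pca_summary",
]

G_COLUMNS = ["g_Na", "g_K", "g_SK", "g_h", "g_CaT"]


@dataclass(frozen=True)
class BirdConductances:
    """One bird's fitted conductances: an n-neurons-by-5 matrix."""

    bird_id: str
    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[1] != 5 or G.shape[0] < 1:
            raise ValueError("G must be an n-by-5 matrix with n >= 1")
        object.__setattr__(self, "G", G)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bird_id: str) -> "BirdConductances":
        sub = df[df["bird_id"] == bird_id]
        return cls(bird_id=str(bird_id), G=sub[G_COLUMNS].to_numpy(float))

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.G.mean(axis=0)

    def cov(self) -> np.ndarray:
        if self.n < 2:
            raise ValueError("covariance undefined for a single neuron")
        return np.cov(self.G, rowvar=False, ddof=1)


def trace_volume(bird: BirdConductances) -> float:
    """sqrt(1/(N-1) * sum of squared deviations from the per-axis means),
    i.e. the square root of the trace of the sample covariance (nS)."""
    if bird.n < 2:
        raise ValueError("trace volume undefined for fewer than 2 neurons")
    dev = bird.G - bird.centroid
    return float(np.sqrt(np.sum(dev**2) / (bird.n - 1)))


def geometric_volume(bird: BirdConductances) -> tuple[float, bool]:
    """Determinant-based hyperellipsoid volume: sqrt(det of sample covariance),
    which scales as a length^5 measure.  Returns (volume, degenerate_flag);
    rank deficiency (in particular n <= 5) gives 0 with the flag set."""
    if bird.n < 2:
        raise ValueError("geometric volume undefined for fewer than 2 neurons")
    if bird.n <= 5:
        return 0.0, True
    c = bird.cov()
    det = float(np.linalg.det(c))
    if det <= 1e-300:
        return 0.0, True
    return float(np.sqrt(det)), False


@dataclass
class VolumeStats:
    """Per-bird dispersion measures, optionally normalized to the species."""

    bird_id: str
    n_neurons: int
    trace_volume: float
    geometric_volume: float
    degenerate: bool
    norm_trace_volume: float = math.nan
    norm_geometric_volume: float = math.nan


def volume_stats(
    birds: Sequence[BirdConductances],
    species: BirdConductances | None = None,
) -> pd.DataFrame:
    """Volume table for a set of birds.  When ``species`` (the pooled
    reference set, e.g. all neurons of all non-manipulated adults) is given,
    normalized columns divide each bird's volume by the species value
    computed the same way."""
    sp_tv = sp_gv = math.nan
    if species is not None:
        sp_tv = trace_volume(species)
        sp_gv, sp_deg = geometric_volume(species)
        if sp_deg:
            raise ValueError("species reference set is rank-deficient")
    rows = []
    for b in birds:
        tv = trace_volume(b)
        gv, deg = geometric_volume(b)
        rows.append(
            VolumeStats(
                bird_id=b.bird_id,
                n_neurons=b.n,
                trace_volume=tv,
                geometric_volume=gv,
                degenerate=deg,
                norm_trace_volume=tv / sp_tv if species is not None else math.nan,
                norm_geometric_volume=gv / sp_gv if species is not None else math.nan,
            ).__dict__
        )
    return pd.DataFrame(rows)


def mahalanobis_distance(
    g1: BirdConductances,
    g2: BirdConductances,
    allow_pseudo_inverse: bool = True,
) -> float:
    """D = sqrt(x . P^-1 . x') with x the centroid difference and P the
    pooled sample covariance of the two birds.  Unitless and invariant under
    any common invertible linear transform of both matrices."""
    if g1.n < 2 or g2.n < 2:
        raise ValueError("each bird needs at least 2 neurons")
    x = g1.centroid - g2.centroid
    pooled = ((g1.n - 1) * g1.cov() + (g2.n - 1) * g2.cov()) / (g1.n + g2.n - 2)
    try:
        sol = np.linalg.solve(pooled, x)
    except np.linalg.LinAlgError:
        if not allow_pseudo_inverse:
            raise
        sol = np.linalg.pinv(pooled) @ x
    d2 = float(x @ sol)
    return math.sqrt(max(d2, 0.0))


def conductance_distance_matrix(
    fits: pd.DataFrame,
    metric: Literal["euclidean", "mahalanobis"] = "euclidean",
    drop_conductance: str | None = None,
) -> pd.DataFrame:
    """Pairwise between-bird distance matrix from a per-neuron fits table
    (columns ``bird_id`` + the five conductances).  ``drop_conductance``
    supports the leave-one-conductance-out control (e.g. removing g_SK)."""
    cols = [c for c in G_COLUMNS if c != drop_conductance]
    bird_ids = list(pd.unique(fits["bird_id"]))
    mats = {b: fits.loc[fits["bird_id"] == b, cols].to_numpy(float) for b in bird_ids}
    n = len(bird_ids)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = mats[bird_ids[i]], mats[bird_ids[j]]
        if metric == "euclidean":
            d = float(np.linalg.norm(gi.mean(axis=0) - gj.mean(axis=0)))
        elif metric == "mahalanobis":
            x = gi.mean(axis=0) - gj.mean(axis=0)
            pooled = (
                (len(gi) - 1) * np.cov(gi, rowvar=False, ddof=1)
                + (len(gj) - 1) * np.cov(gj, rowvar=False, ddof=1)
            ) / (len(gi) + len(gj) - 2)
            try:
                d = math.sqrt(max(float(x @ np.linalg.solve(pooled, x)), 0.0))
            except np.linalg.LinAlgError:
                d = math.sqrt(max(float(x @ np.linalg.pinv(pooled) @ x), 0.0))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=bird_ids, columns=bird_ids)


# --------------------------------------------------------------------------
# MANOVA
# --------------------------------------------------------------------------


@dataclass
class ManovaResult:
    """One-way MANOVA via Wilks' lambda with Rao's F approximation."""

    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    n_groups: int
    n_obs: int
    n_covariates: int
    pairwise: pd.DataFrame | None = None
    bonferroni_m: int | None = None

    def summary(self) -> str:
        lines = [
            "One-way MANOVA (Wilks' lambda)",
            "=" * 40,
            f"groups: {self.n_groups}   observations: {self.n_obs}   covariates: {self.n_covariates}",
            f"Wilks' lambda = {self.wilks_lambda:.6g}",
            f"F({self.df1:.0f}, {self.df2:.1f}) = {self.f_stat:.4g},  p = {self.p_value:.3g}",
        ]
        if self.pairwise is not None:
            lines.append(
                f"pairwise comparisons: {len(self.pairwise)} testable, "
                f"Bonferroni m = {self.bonferroni_m}"
            )
        return "\n".join(lines)


def _wilks(X: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, float]:
    groups = pd.unique(labels)
    p = X.shape[1]
    N = X.shape[0]
    k = len(groups)
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for g in groups:
        sub = X[labels == g]
        m = sub.mean(axis=0)
        d = (m - grand)[:, None]
        B += len(sub) * (d @ d.T)
        r = sub - m
        W += r.T @ r
    T = W + B
    det_T = np.linalg.det(T)
    if det_T <= 0:
        raise ValueError("total scatter matrix is singular; MANOVA undefined")
    lam = float(np.linalg.det(W) / det_T)
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    # Rao's F approximation
    q = k - 1
    v = N - k
    t = (
        math.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
        if (p * p + q * q - 5.0) > 0
        else 1.0
    )
    w = v + q - (p + q + 1.0) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2.0) / 2.0
    if df2 <= 0:
        raise ValueError("insufficient error degrees of freedom for MANOVA")
    lam_t = lam ** (1.0 / t)
    f_stat = ((1.0 - lam_t) / lam_t) * (df2 / df1)
    p_val = float(stats.f.sf(f_stat, df1, df2))
    return lam, f_stat, df1, df2, p_val


def manova(
    features: pd.DataFrame,
    covariates: Sequence[str] = ("spike_rate_hz", "isi1_ms", "isi2_ms", "isi3_ms"),
    group_col: str = "bird_id",
    min_spikes: int | None = 4,
    spike_col: str = "n_spikes",
) -> ManovaResult:
    """Test equality of per-bird mean covariate vectors.

    The canonical covariates are spiking frequency and the first three ISIs;
    neurons with fewer than four spikes (for which a third ISI does not
    exist) are removed before testing, mirroring the covariate filter of the
    source analysis.  Small Wilks' lambda rejects equality of group means.
    """
    df = features
    if min_spikes is not None and spike_col in df.columns:
        df = df[df[spike_col] >= min_spikes]
    df = df.dropna(subset=list(covariates))
    labels = df[group_col].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise ValueError("MANOVA requires at least 2 groups after filtering")
    X = df[list(covariates)].to_numpy(float)
    lam, f_stat, df1, df2, p_val = _wilks(X, labels)
    return ManovaResult(
        wilks_lambda=lam,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        p_value=p_val,
        n_groups=len(pd.unique(labels)),
        n_obs=len(X),
        n_covariates=X.shape[1],
    )


def pairwise_manova(
    features: pd.DataFrame,
    covariates: Sequence[str] = ("spike_rate_hz", "isi1_ms", "isi2_ms", "isi3_ms"),
    group_col: str = "bird_id",
    min_spikes: int | None = 4,
    spike_col: str = "n_spikes",
    alpha: float = 0.05,
) -> ManovaResult:
    """All-pairs MANOVA with Bonferroni control.

    The Bonferroni divisor m is the number of *testable* pairs (both birds
    having more neurons than covariates), which can be smaller than the
    nominal C(n_birds, 2); both counts are reported.
    """
    overall = manova(features, covariates, group_col, min_spikes, spike_col)
    df = features
    if min_spikes is not None and spike_col in df.columns:
        df = df[df[spike_col] >= min_spikes]
    df = df.dropna(subset=list(covariates))
    birds = list(pd.unique(df[group_col]))
    p = len(covariates)
    rows = []
    for b1, b2 in itertools.combinations(birds, 2):
        sub = df[df[group_col].isin([b1, b2])]
        n1 = int((sub[group_col] == b1).sum())
        n2 = int((sub[group_col] == b2).sum())
        # a bird with fewer neurons than covariates makes the pair untestable
        testable = n1 >= p and n2 >= p and (n1 + n2 - 2) > p
        if not testable:
            rows.append((b1, b2, n1, n2, math.nan, math.nan, False, False))
            continue
        try:
            lam, f_stat, _, _, p_val = _wilks(
                sub[list(covariates)].to_numpy(float), sub[group_col].to_numpy()
            )
        except ValueError:
            rows.append((b1, b2, n1, n2, math.nan, math.nan, False, False))
            continue
        rows.append((b1, b2, n1, n2, lam, p_val, True, False))
    pw = pd.DataFrame(
        rows,
        columns=["bird_1", "bird_2", "n_1", "n_2", "wilks_lambda", "p_value", "testable", "significant"],
    )
    m = int(pw["testable"].sum())
    if m:
        pw["significant"] = pw["testable"] & (pw["p_value"] < alpha / m)
    overall.pairwise = pw
    overall.bonferroni_m = m
    return overall


# --------------------------------------------------------------------------
# bespoke comparison tests
# --------------------------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    detail: dict = field(default_factory=dict)
    degenerate: bool = False


def clustering_distance_test(
    points: pd.DataFrame,
    seed: int,
    value_cols: Sequence[str] = ("first_spike_amplitude_mV", "first_spike_threshold_mV"),
    group_col: str = "bird_id",
) -> TestResult:
    """Same-bird vs across-bird distances in a 2-D feature plane.

    For each neuron of each bird with more than 2 neurons, the distance to a
    randomly chosen same-bird neuron is compared with the distance to a
    randomly chosen neuron of another bird (unpaired two-tailed t test; a
    negative statistic means same-bird distances are smaller).
    """
    rng = np.random.default_rng(seed)
    df = points.dropna(subset=list(value_cols))
    counts = df[group_col].value_counts()
    eligible = counts[counts > 2].index
    df_el = df[df[group_col].isin(eligible)]
    if df_el[group_col].nunique() < 2:
        raise ValueError("need at least 2 birds with more than 2 neurons")
    X = df_el[list(value_cols)].to_numpy(float)
    birds = df_el[group_col].to_numpy()
    same, across = [], []
    for i in range(len(X)):
        same_idx = np.flatnonzero((birds == birds[i]))
        same_idx = same_idx[same_idx != i]
        other_idx = np.flatnonzero(birds != birds[i])
        j = rng.choice(same_idx)
        k = rng.choice(other_idx)
        same.append(np.linalg.norm(X[i] - X[j]))
        across.append(np.linalg.norm(X[i] - X[k]))
    same, across = np.array(same), np.array(across)
    if same.std() == 0 and across.std() == 0:
        return TestResult(
            statistic=math.nan, df=math.nan, p_value=math.nan,
            detail={"same_mean": float(same.mean()), "across_mean": float(across.mean())},
            degenerate=True,
        )
    t, p = stats.ttest_ind(same, across)
    return TestResult(
        statistic=float(t),
        df=float(len(same) + len(across) - 2),
        p_value=float(p),
        detail={"same_mean": float(same.mean()), "across_mean": float(across.mean()),
                "n_neurons": int(len(same))},
    )


def variance_ratio_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample two-tailed F test of equal variances: F = var(x)/var(y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0 and vx == 0:
        return TestResult(statistic=math.nan, df=(len(x) - 1, len(y) - 1),
                          p_value=math.nan, degenerate=True)
    if vy == 0:
        return TestResult(statistic=math.inf, df=(len(x) - 1, len(y) - 1), p_value=0.0)
    f = float(vx / vy)
    d1, d2 = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return TestResult(statistic=f, df=(d1, d2), p_value=float(min(p, 1.0)))


def _spike_time_ratios(bird_df: pd.DataFrame, time_cols_prefix: str = "t_spike_") -> np.ndarray:
    """Accumulated pairwise same-order spike-time ratios for one bird.

    Cells are grouped by emitted spike count; singleton groups are dropped;
    within each remaining group all cell pairs contribute the ratios of
    first-spike times, second-spike times, and so on.
    """
    ratios = []
    for _, grp in bird_df.groupby("n_spikes"):
        if len(grp) < 2 or grp["n_spikes"].iloc[0] == 0:
            continue
        k = int(grp["n_spikes"].iloc[0])
        cols = [f"{time_cols_prefix}{i}" for i in range(k)]
        times = grp[cols].to_numpy(float)
        for a, b in itertools.combinations(range(len(times)), 2):
            with np.errstate(divide="ignore", invalid="ignore"):
                r = times[a] / times[b]
            ratios.extend(r[np.isfinite(r)])
    return np.asarray(ratios)


def spike_time_ratio_test(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    time_cols_prefix: str = "t_spike_",
) -> pd.DataFrame:
    """Spike-timing variability comparison between two cohorts.

    Input frames hold one row per neuron with ``bird_id``, ``n_spikes`` and
    spike-time columns (relative to pulse onset).  For every bird pair
    (one from each cohort) with accumulable ratio distributions, a
    two-tailed two-sample F test compares the ratio variances.
    """
    rows = []
    for ba, sub_a in cohort_a.groupby("bird_id"):
        ra = _spike_time_ratios(sub_a, time_cols_prefix)
        for bb, sub_b in cohort_b.groupby("bird_id"):
            rb = _spike_time_ratios(sub_b, time_cols_prefix)
            if len(ra) < 2 or len(rb) < 2:
                rows.append((ba, bb, len(ra), len(rb), math.nan, math.nan, False))
                continue
            res = variance_ratio_test(ra, rb)
            rows.append((ba, bb, len(ra), len(rb), res.statistic, res.p_value, True))
    out = pd.DataFrame(
        rows, columns=["bird_a", "bird_b", "n_ratios_a", "n_ratios_b", "F", "p_value", "testable"]
    )
    if not out["testable"].any():
        raise ValueError("no bird pair with accumulable ratio distributions")
    return out


def pairwise_waveform_msd(
    w1: np.ndarray, w2: np.ndarray | None = None
) -> np.ndarray:
    """Mean squared differences between first-spike snippets.

    With one argument: all unordered pairs within the set.  With two:
    every cross pair (one waveform from each set).  Snippets must share a
    window length (peak-aligned)."""
    w1 = np.asarray(w1, float)
    if w1.ndim != 2:
        raise ValueError("waveforms must be an n-by-samples matrix")
    if w2 is None:
        vals = [
            np.mean((w1[a] - w1[b]) ** 2)
            for a, b in itertools.combinations(range(len(w1)), 2)
        ]
        return np.asarray(vals)
    w2 = np.asarray(w2, float)
    if w1.shape[1] != w2.shape[1]:
        raise ValueError("waveform snippets must share a window length")
    return np.asarray([np.mean((a - b) ** 2) for a in w1 for b in w2])


def waveform_mse_test(msd_a: np.ndarray, msd_b: np.ndarray) -> TestResult:
    """Two-tailed two-sample F test comparing two distributions of pairwise
    waveform mean-squared differences (e.g. a juvenile sibling pair vs an
    adult sibling pair, or pooled adults vs one feedback-perturbed bird)."""
    return variance_ratio_test(np.asarray(msd_a, float), np.asarray(msd_b, float))


def rundown_check(amplitudes: pd.DataFrame) -> dict[str, TestResult]:
    """Stability of first-spike amplitudes over within-bird recording order.

    ``amplitudes`` has columns bird_id, order (0 = first recorded cell) and
    amplitude.  Ratios (later cell / first cell) and (last cell / first
    cell) are each tested against mean 1.0 (two-tailed t)."""
    later, last = [], []
    for _, grp in amplitudes.sort_values("order").groupby("bird_id"):
        a = grp["amplitude"].to_numpy(float)
        if len(a) < 2:
            continue
        later.extend(a[1:] / a[0])
        last.append(a[-1] / a[0])
    if not later:
        raise ValueError("need at least one bird with 2+ cells")

    def against_one(vals):
        vals = np.asarray(vals)
        if vals.std(ddof=1) == 0:
            t = 0.0 if np.allclose(vals, 1.0) else math.inf
            return TestResult(statistic=t, df=len(vals) - 1,
                              p_value=1.0 if t == 0.0 else 0.0,
                              detail={"mean_ratio": float(vals.mean())},
                              degenerate=True)
        t, p = stats.ttest_1samp(vals, 1.0)
        return TestResult(statistic=float(t), df=len(vals) - 1, p_value=float(p),
                          detail={"mean_ratio": float(vals.mean()), "n": len(vals)})

    return {"later_vs_first": against_one(later), "last_vs_first": against_one(last)}


# --------------------------------------------------------------------------
# behavior coupling and regressions
# --------------------------------------------------------------------------


def similarity_distance_correlation(
    similarity: pd.DataFrame,
    distances: pd.DataFrame,
    mode: Literal["pooled", "per-bird"] = "pooled",
    atol: float = 1e-8,
):
    """Correlation between pairwise song similarity and conductance distance.

    Uses the non-identical lower-triangle entries.  Pooled mode returns a
    TestResult with R (signed correlation) and the two-tailed p of the
    regression slope; per-bird mode returns a DataFrame with one row per
    bird, correlating that bird's row against all other birds.
    """
    if list(similarity.index) != list(similarity.columns) or list(distances.index) != list(
        distances.columns
    ):
        raise ValueError("matrices must be square with matching id order")
    if list(similarity.index) != list(distances.index):
        raise ValueError("similarity and distance matrices must share bird ordering")
    S = similarity.to_numpy(float)
    D = distances.to_numpy(float)
    if np.max(np.abs(S - S.T)) > atol or np.max(np.abs(D - D.T)) > atol:
        raise ValueError("matrices must be symmetric")
    n = len(S)
    il = np.tril_indices(n, k=-1)
    if mode == "pooled":
        res = stats.linregress(D[il], S[il])
        return TestResult(
            statistic=float(res.rvalue),
            df=float(len(il[0]) - 2),
            p_value=float(res.pvalue),
            detail={"slope": float(res.slope), "n_pairs": int(len(il[0]))},
        )
    rows = []
    ids = list(similarity.index)
    for i, b in enumerate(ids):
        others = [j for j in range(n) if j != i]
        d = D[i, others]
        s = S[i, others]
        if np.std(d) == 0 or np.std(s) == 0:
            rows.append((b, math.nan, math.nan, len(others)))
            continue
        r = stats.linregress(d, s)
        rows.append((b, float(r.rvalue), float(r.pvalue), len(others)))
    return pd.DataFrame(rows, columns=["bird_id", "R", "p_value", "n_pairs"])


def volume_vs_covariate(
    volumes: Sequence[float],
    covariate: Sequence[float],
    model: Literal["linear", "log"] = "linear",
) -> TestResult:
    """OLS of per-bird volume on a covariate (or its natural log), with the
    slope's two-tailed t-test p-value."""
    v = np.asarray(volumes, float)
    x = np.asarray(covariate, float)
    if len(v) < 4:
        raise ValueError("need at least 4 birds")
    if model == "log":
        if np.any(x <= 0):
            raise ValueError("log model requires a positive covariate")
        x = np.log(x)
    res = stats.linregress(x, v)
    return TestResult(
        statistic=float(res.rvalue),
        df=float(len(v) - 2),
        p_value=float(res.pvalue),
        detail={"slope": float(res.slope), "intercept": float(res.intercept), "model": model},
    )


def pca_summary(matrix: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Ordered variance-explained fractions of a neurons-by-covariates matrix.

    Columns are standardized by default (zero-variance columns are dropped
    with a warning); the shares sum to 1.
    """
    import warnings

    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 informative columns remain")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s**2
    return var / var.sum()
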