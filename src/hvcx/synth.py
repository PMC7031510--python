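"""Synthetic cohorts with the population structure the analysis assumes.

Birds are tight clusters in the 5-D space of maximal conductances: a bird
is a centroid plus independent per-axis multiplicative log-normal jitter.
The adult preset draws centroids across the species ranges with small
within-bird spread; the juvenile preset restricts centroids to the low
g_Na / low g_SK sub-box, inflates dispersion (especially g_h, a fraction
of neurons having g_h near zero and little g_CaT variation); the cDAF
(continuous delayed-auditory-feedback) preset sets each bird's dispersion
so its expected conductance trace volume follows a + b*log(motifs sung),
and shifts g_SK low.  Voltage traces are produced by the conductance
model with additive Gaussian noise; bird-level song-feature similarity is
generated so that it anti-correlates with conductance-centroid distance
with a tunable coupling strength.

All randomness flows from the single config seed; identical configs
reproduce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hvcx import hh
from hvcx.features import extract_features
from hvcx.fitting import ConductanceSet, simulate_canonical_pair
from hvcx.popstats import G_COLUMNS, BirdConductances

__all__ = [
    "CohortConfig",
    "BirdCohort",
    "generate_cohort",
    "attach_traces",
    "generate_song_features",
    "sibling_pair",
    "within_bird_fold_variation",
    "ADULT_FOLD_SPREAD",
    "JUVENILE_FOLD_SPREAD",
]

#: within-bird multiplicative 2-sigma spread per conductance, adult preset
#: (the average per-animal fold-variation of the modeled species)
ADULT_FOLD_SPREAD = {"g_Na": 1.23, "g_K": 1.24, "g_SK": 1.14, "g_h": 1.17, "g_CaT": 1.19}

#: juvenile preset: inflated overall, dominated by g_h and g_K variation,
#: with little g_CaT variation (the inflation factors are free, documented
#: parameters; the source data is qualitative on this point)
JUVENILE_FOLD_SPREAD = {"g_Na": 2.2, "g_K": 2.5, "g_SK": 1.8, "g_h": 4.0, "g_CaT": 1.2}

#: species ranges the centroids are drawn from (the published search ranges)
SPECIES_RANGES = {
    "g_Na": (200.0, 2500.0),
    "g_K": (50.0, 750.0),
    "g_SK": (0.0, 15.0),
    "g_h": (0.0, 15.0),
    "g_CaT": (0.0, 10.0),
}

#: default cDAF exposure ladder: motifs sung under delayed feedback per bird
#: (4 h ... 6 days of 12 h/day exposure; the 4 h bird sang 35 motifs)
CDAF_MOTIFS = (35, 100, 110, 220, 240, 230, 330, 700)

#: cDAF dispersion law: expected trace volume (nS) = a + b * ln(motifs),
#: anchored so the fit intersects the top of the adult per-bird range near
#: 5.9 motifs
CDAF_VOLUME_A = 4.0
CDAF_VOLUME_B = 150.0

#: fraction of juvenile neurons with essentially no h-current
JUVENILE_GH_ZERO_FRACTION = 0.35


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort.  ``fold_spread`` entries are
    the within-bird multiplicative 2-sigma spreads (>= 1); ``ranges`` give
    the between-bird centroid span per conductance."""

    preset: str = "adult"  # adult | juvenile | cdaf
    n_birds: int = 8
    neurons_per_bird: int = 8
    fold_spread: Mapping[str, float] | None = None
    ranges: Mapping[str, tuple[float, float]] | None = None
    noise_sigma_mV: float = 0.3
    coupling: float = 0.8
    motifs: Sequence[int] | None = None
    seed: int = 0
    include_traces: bool = True
    dt_ms: float = hh.DEFAULT_DT

    def __post_init__(self) -> None:
        if self.preset not in ("adult", "juvenile", "cdaf"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.noise_sigma_mV < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.fold_spread is not None:
            for k, v in self.fold_spread.items():
                if v < 1:
                    raise ValueError(f"fold spread for {k} must be >= 1")

    def resolved_folds(self) -> dict[str, float]:
        if self.fold_spread is not None:
            return dict(self.fold_spread)
        return dict(JUVENILE_FOLD_SPREAD if self.preset == "juvenile" else ADULT_FOLD_SPREAD)

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        if self.ranges is not None:
            return {k: tuple(v) for k, v in self.ranges.items()}
        r = {k: tuple(v) for k, v in SPECIES_RANGES.items()}
        if self.preset == "juvenile":
            # juveniles sit in the low-g_Na / low-g_SK corner of the adult box
            r["g_Na"] = (200.0, 700.0)
            r["g_SK"] = (0.5, 4.0)
            r["g_h"] = (0.0, 10.0)
        elif self.preset == "cdaf":
            r["g_SK"] = (0.0, 4.0)  # feedback-perturbed birds shift g_SK low
            # centroids sit in the high-conductance region so the large
            # dispersion budget fits the non-negative conductance support
            r["g_Na"] = (1800.0, 2500.0)
            r["g_K"] = (500.0, 750.0)
        return r


@dataclass
class BirdCohort:
    """A generated cohort: per-bird truth, per-neuron conductances, and
    (optionally) simulated canonical-pulse traces per neuron."""

    config: CohortConfig
    birds: pd.DataFrame  # bird_id, centroid conductances, motifs
    neurons: pd.DataFrame  # neuron_id, bird_id, true conductances
    traces: dict[str, tuple[hh.Trace, hh.Trace]] = field(default_factory=dict)
    similarity: pd.DataFrame | None = None

    @property
    def bird_ids(self) -> list[str]:
        return list(self.birds["bird_id"])

    def bird_conductances(self) -> list[BirdConductances]:
        return [BirdConductances.from_frame(self.neurons, b) for b in self.bird_ids]

    def species(self) -> BirdConductances:
        """All neurons pooled, used as the species normalization reference."""
        return BirdConductances(bird_id="species", G=self.neurons[G_COLUMNS].to_numpy(float))

    def features_frame(self, smooth: bool | None = None) -> pd.DataFrame:
        """Extract the feature table (one row per neuron) from the traces."""
        if not self.traces:
            raise ValueError("cohort was generated without traces")
        rows = []
        max_spikes = 0
        feats = {}
        for nid, (d, h) in self.traces.items():
            fv = extract_features(d, h, smooth=smooth)
            feats[nid] = fv
            max_spikes = max(max_spikes, fv.n_spikes)
        for nid, fv in feats.items():
            bird = nid.rsplit("-", 1)[0]
            row = {"neuron_id": nid, "bird_id": bird, **fv.as_dict()}
            isis = fv.isis
            for k in range(3):
                row[f"isi{k + 1}_ms"] = float(isis[k]) if len(isis) > k else math.nan
            for k in range(max_spikes):
                row[f"t_spike_{k}"] = (
                    float(fv.spike_times[k]) if len(fv.spike_times) > k else math.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)


def within_bird_fold_variation(values: np.ndarray) -> float:
    """The package's dispersion statistic: exp(2 * SD of log values), the
    multiplicative 2-sigma spread.  Sample-size independent, matching the
    generator contract fold = exp(2 * sigma_log)."""
    v = np.asarray(values, float)
    if np.any(v <= 0):
        raise ValueError("fold variation requires positive values")
    return float(np.exp(2.0 * np.std(np.log(v), ddof=1)))


def _draw_centroid(rng: np.random.Generator, ranges: Mapping[str, tuple[float, float]]) -> dict:
    out = {}
    for name in G_COLUMNS:
        lo, hi = ranges[name]
        if name in ("g_Na", "g_K"):
            # wide, strictly positive spans: log-uniform
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


#: variance shares of the cDAF dispersion budget (trace volume is carried
#: mostly by the large-magnitude spike conductances)
CDAF_VARIANCE_SHARES = {"g_Na": 0.60, "g_K": 0.35, "g_SK": 0.02, "g_h": 0.02, "g_CaT": 0.01}


def _stds_for_volume(centroid: dict, target_volume: float) -> dict:
    """Per-axis standard deviations whose additive jitter around the centroid
    yields an expected trace volume equal to ``target_volume``.

    Variance is allocated by CDAF_VARIANCE_SHARES, with each axis capped at
    0.55x its centroid (keeping the non-negativity clip a tail event);
    capped-out excess is redistributed to the remaining axes.
    """
    budget = target_volume**2
    caps = {n: (0.55 * max(centroid[n], 1e-6)) ** 2 for n in G_COLUMNS}
    var = {n: 0.0 for n in G_COLUMNS}
    shares = dict(CDAF_VARIANCE_SHARES)
    remaining = budget
    for _ in range(3):
        total_share = sum(shares.values())
        if total_share <= 0 or remaining <= 1e-12:
            break
        spill = 0.0
        for n in list(shares):
            want = var[n] + remaining * shares[n] / total_share
            if want >= caps[n]:
                spill += want - caps[n]
                var[n] = caps[n]
                shares.pop(n)
            else:
                var[n] = want
        remaining = spill
    return {n: math.sqrt(v) for n, v in var.items()}


def generate_cohort(config: CohortConfig) -> BirdCohort:
    """Generate a cohort of birds per the configured preset.

    Returns truth tables (and simulated noisy traces unless disabled); the
    true conductances are retained for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    ranges = config.resolved_ranges()
    folds = config.resolved_folds()
    motifs = list(config.motifs) if config.motifs is not None else list(CDAF_MOTIFS)
    if config.preset == "cdaf":
        while len(motifs) < config.n_birds:
            motifs.append(motifs[-1])

    bird_rows = []
    neuron_rows = []
    for b in range(config.n_birds):
        bird_id = f"{config.preset}{b:02d}"
        centroid = _draw_centroid(rng, ranges)
        if config.preset == "cdaf":
            m = motifs[b]
            target = CDAF_VOLUME_A + CDAF_VOLUME_B * math.log(m)
            # dissolved clustering: additive Gaussian scatter with the exact
            # per-axis variance budget (tight multiplicative clusters would be
            # wildly heavy-tailed at these dispersions)
            stds = _stds_for_volume(centroid, target)
            sigma = None
        else:
            m = math.nan
            sigma = {n: math.log(folds[n]) / 2.0 for n in G_COLUMNS}
        bird_rows.append({"bird_id": bird_id, **{f"c_{n}": centroid[n] for n in G_COLUMNS},
                          "motifs": m})
        for i in range(config.neurons_per_bird):
            g = {}
            for n in G_COLUMNS:
                base = max(centroid[n], 1e-6)
                if sigma is None:
                    g[n] = max(base + rng.normal(0.0, stds[n]), 0.0)
                else:
                    g[n] = base * math.exp(rng.normal(0.0, sigma[n]))
            if config.preset == "juvenile" and rng.uniform() < JUVENILE_GH_ZERO_FRACTION:
                g["g_h"] = g["g_h"] * 0.02  # essentially no h-current
            neuron_rows.append({"neuron_id": f"{bird_id}-{i:02d}", "bird_id": bird_id, **g})

    birds = pd.DataFrame(bird_rows)
    neurons = pd.DataFrame(neuron_rows)
    cohort = BirdCohort(config=config, birds=birds, neurons=neurons)

    if config.include_traces:
        attach_traces(cohort, rng=rng)

    if config.n_birds >= 3:
        cohort.similarity = generate_song_features(cohort, config.coupling, config.seed + 1)
    return cohort


def attach_traces(cohort: BirdCohort, rng: np.random.Generator | None = None) -> BirdCohort:
    """Simulate the canonical pulse pair for every neuron of a cohort.

    Uses the cohort's current ``neurons`` table (so callers may modify the
    conductances first, e.g. snapping them to a search grid for
    self-consistency validation runs) and the config's noise level; the
    noise stream defaults to a generator seeded by the config seed.
    """
    config = cohort.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 7777)
    base = hh.reference_parameters(juvenile=config.preset == "juvenile")
    for row in cohort.neurons.itertuples(index=False):
        cs = ConductanceSet(*(getattr(row, n) for n in G_COLUMNS))
        try:
            d, h = simulate_canonical_pair(cs.apply(base), dt=config.dt_ms,
                                           depol_post_ms=200.0)
        except hh.SimulationError as exc:
            raise hh.SimulationError(
                f"bird {row.bird_id}: conductances outside the simulator's "
                f"stable region ({exc})"
            ) from exc
        if config.noise_sigma_mV > 0:
            d.v = d.v + rng.normal(0.0, config.noise_sigma_mV, len(d.v))
            h.v = h.v + rng.normal(0.0, config.noise_sigma_mV, len(h.v))
        for tr, kind in ((d, "depol"), (h, "hyperpol")):
            tr.meta.update(
                neuron_id=row.neuron_id,
                bird_id=row.bird_id,
                provenance="synthetic-cohort",
                noise_sigma_mV=config.noise_sigma_mV,
                pulse=kind,
            )
        cohort.traces[row.neuron_id] = (d, h)
    return cohort


#: noise-to-signal multiplier of the song-similarity generator at zero coupling
SONG_NOISE_SCALE = 4.0


def generate_song_features(cohort: BirdCohort, coupling: float, seed: int) -> pd.DataFrame:
    """Pairwise song-similarity matrix anti-correlated with conductance-
    centroid distance.

    A linear decreasing transform of the between-centroid Euclidean distance
    (weight ``coupling``) is mixed with symmetric Gaussian noise (weight
    ``1 - coupling``, scaled by SONG_NOISE_SCALE) and affinely rescaled onto
    a (0, 100] percent-like scale.  At coupling = 1 the similarity is a
    strictly decreasing linear function of centroid distance.
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    ids = cohort.bird_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 birds for a similarity matrix")
    rng = np.random.default_rng(seed)
    C = cohort.birds[[f"c_{n}" for n in G_COLUMNS]].to_numpy(float)
    n = len(ids)
    D = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
    il = np.tril_indices(n, k=-1)
    lin = -D[il]
    z = (lin - lin.mean()) / (lin.std() if lin.std() > 0 else 1.0)
    eps = rng.standard_normal(len(z))
    mix = coupling * z + (1.0 - coupling) * SONG_NOISE_SCALE * eps
    lo, hi = mix.min(), mix.max()
    span = hi - lo if hi > lo else 1.0
    sim_vals = 1.0 + 99.0 * (mix - lo) / span  # (0, 100]
    S = np.full((n, n), 100.0)
    S[il] = sim_vals
    S[(il[1], il[0])] = sim_vals
    return pd.DataFrame(S, index=ids, columns=ids)


def sibling_pair(config: CohortConfig, seed: int | None = None) -> BirdCohort:
    """Two birds sharing a single true centroid (an adult sibling pair).

    With fold spreads of 1 the two birds' neurons coincide with the shared
    centroid; otherwise each bird gets independent within-bird jitter.
    """
    cfg = replace(
        config,
        preset="adult" if config.preset == "cdaf" else config.preset,
        n_birds=2,
        seed=config.seed if seed is None else seed,
    )
    rng = np.random.default_rng(cfg.seed)
    centroid = _draw_centroid(rng, cfg.resolved_ranges())
    folds = cfg.resolved_folds()
    sigma = {n: math.log(folds[n]) / 2.0 for n in G_COLUMNS}
    bird_rows, neuron_rows = [], []
    for b in range(2):
        bird_id = f"sib{b}"
        bird_rows.append({"bird_id": bird_id, **{f"c_{n}": centroid[n] for n in G_COLUMNS},
                          "motifs": math.nan})
        for i in range(cfg.neurons_per_bird):
            g = {n: max(centroid[n], 1e-6) * math.exp(rng.normal(0.0, sigma[n]))
                 for n in G_COLUMNS}
            neuron_rows.append({"neuron_id": f"{bird_id}-{i:02d}", "bird_id": bird_id, **g})
    cohort = BirdCohort(config=cfg, birds=pd.DataFrame(bird_rows),
                        neurons=pd.DataFrame(neuron_rows))
    if cfg.include_traces:
        base = hh.reference_parameters(juvenile=cfg.preset == "juvenile")
        for row in cohort.neurons.itertuples(index=False):
            cs = ConductanceSet(*(getattr(row, n) for n in G_COLUMNS))
            d, h = simulate_canonical_pair(cs.apply(base), dt=cfg.dt_ms, depol_post_ms=200.0)
            if cfg.noise_sigma_mV > 0:
                d.v = d.v + rng.normal(0.0, cfg.noise_sigma_mV, len(d.v))
                h.v = h.v + rng.normal(0.0, cfg.noise_sigma_mV, len(h.v))
            for tr, kind in ((d, "depol"), (h, "hyperpol")):
                tr.meta.update(neuron_id=row.neuron_id, bird_id=row.bird_id,
                               provenance="synthetic-cohort",
                               noise_sigma_mV=cfg.noise_sigma_mV, pulse=kind)
            cohort.traces[row.neuron_id] = (d, h)
    return cohort
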