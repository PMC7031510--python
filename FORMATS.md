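# File formats

All files are plain text. Units follow the package convention: mV, ms, pA,
pF, nS, MOhm.

## Trace CSV (`<name>.csv` + `<name>.meta.json`)

One current-clamp sweep.

| column       | unit | meaning                              |
|--------------|------|--------------------------------------|
| `time_ms`    | ms   | uniform grid starting at 0           |
| `voltage_mV` | mV   | membrane potential                   |
| `current_pA` | pA   | injected current including any holding bias |

The JSON sidecar `<name>.meta.json` carries: `neuron_id`, `bird_id`,
`dt_ms`, protocol fields (`protocol_kind`, `amplitude_pA`, `pre_ms`,
`stim_ms`, `post_ms`, `holding_mV`, `holding_pA`, `seed` for chaotic
stimuli), `provenance` (`simulated` | `synthetic-cohort` | `external`) and
`noise_sigma_mV` when noise was added.

## Fits table (`fits.csv`)

One row per neuron: `neuron_id, bird_id, g_Na, g_K, g_SK, g_h, g_CaT,
error, disregarded_count`. Conductances in nS; `error` is the unit-free
fit error at the grid optimum; `disregarded_count` is the number of grid
candidates rejected by the spike-count rule or by divergence.

## Features table (`features.csv`)

One row per neuron: `neuron_id, bird_id, n_spikes, first_isi_ms,
spike_rate_hz, first_spike_amplitude_mV, first_spike_threshold_mV,
first_spike_duration_ms, plateau_amplitude_mV, resting_potential_mV,
sag_ratio, rebound_spikes, input_resistance_MOhm`, plus `isi1_ms..isi3_ms`
and spike-time columns `t_spike_0..t_spike_{k-1}` (ms relative to pulse
onset). Uncomputable entries are empty (NaN), never zero.

## Similarity matrix (`similarity.csv`)

Square matrix of pairwise song-similarity scores in (0, 100], with a
`bird_id` header row and index column; symmetric, diagonal 100.

## Truth tables (synthetic cohorts)

`truth.csv`: per-neuron true conductances (`neuron_id, bird_id, g_Na ...
g_CaT`). `birds.csv`: per-bird centroids (`c_g_Na ... c_g_CaT`) and
`motifs` (cDAF preset only).

## Grid YAML

```yaml
axes:
  g_Na: [200, 2500, 20]
  g_K: [50, 750, 10]
  g_SK: [0, 15, 0.2]
  g_h: [0, 15, 0.2]
  g_CaT: [0, 10, 0.2]
```

## Pipeline outputs

`report.json` / `report.md` (per-bird volumes, distances, MANOVA,
correlation, recovery summary), `config_snapshot.yaml`, and
`<file>.sidecar.json` carrying the config hash for every produced table.
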