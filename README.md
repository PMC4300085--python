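# calwave

Hybrid stochastic–deterministic modeling and analysis of intracellular
calcium release: puffs, abortive waves and propagating waves.

In many non-excitable cells, cytosolic Ca²⁺ signals are generated by
clusters of IP₃ receptor (IP₃R) channels in the endoplasmic-reticulum
membrane.  Because cytosolic Ca²⁺ itself increases the open probability
of the IP₃R (calcium-induced calcium release, CICR), release events form
a size hierarchy: local *puffs* confined to one cluster, *abortive
waves* that die close to where they start, and *propagating waves* that
travel across the cell.  Which regime dominates depends on how far apart
the release sites are and how strongly SERCA pumps clear the cytosol.

`calwave` is for computational biophysicists who want to simulate this
hierarchy and analyze it the way linescan experiments are analyzed —
from the 8-bit kymograph down.

## Model

The cytosolic concentration is nondimensionalized by the volume-average
concentration, `C = [Ca²⁺]/[Ca²⁺]_ave`, and evolves on a periodic 1-D
grid:

    ∂C/∂t = D ∇²C + (1 + v_r)(γ₁ N_open + γ₀)(1 − C) − p C²/(C² + q²)

* `D` — Ca²⁺ diffusion constant (25 µm²/s),
* `v_r` — ER/cytosol volume ratio (0.185),
* `γ₁ N_open` — channel flux: `N_open` is the number of open channels in
  the cluster occupying a grid cell (γ₁ = 9 s⁻¹ per channel),
* `γ₀` — basal ER leak (0.02 s⁻¹),
* `p C²/(C² + q²)` — SERCA efflux, Hill coefficient 2, with
  `p = p̂/[Ca²⁺]_ave` and `q = q̂/[Ca²⁺]_ave`.

Each channel is a tetramer of four identical, independent subunits.  A
subunit binds IP₃, then activating Ca²⁺, then inhibitory Ca²⁺ —
a sequential four-state chain `X000 ⇌ X100 ⇌ X110 ⇌ X111` — and is
*active* only in `X110`; the channel conducts when ≥ 3 of its 4 subunits
are active.  Gating is simulated stochastically (fixed-step Markov
chain, one categorical draw per subunit per Δt = 0.5 ms), while the
field integrates by explicit finite differences (Δx = 0.18 µm);
`N_open` couples the two per time step.

Runs are recorded as 8-bit kymographs (0.18 µm/pixel, 0.0375 s/row).
The analysis thresholds at 0.3 µM, labels space–time connected
components, and classifies each event twice: by spatial extent
(< 5 µm puff, 5–25 µm abortive, > 25 µm propagating) and by total
released calcium Ca_T = mean intensity × area (< 200 a.u. puff,
200–1800 a.u. abortive, > 1800 a.u. propagating).  Wave speeds come
from the front angle α in the kymograph, `v_w = Δx/(tan α · Δt_row)`,
and a parameter sweep over intercluster distance `d` and pump strength
`p̂` is summarized by Luther's front-velocity law `v_w = a √(D k)`,
fitting the plane `v_w²(d, p) = β₀ + β_d d + β_p p` and reporting the
effective autocatalytic rate constant `k(d, p) = v_w²/(a² D)`.

## Worked example

Simulate 5 s at d = 2.5 µm, p̂ = 1.8 µM/s, then segment and measure:

```sh
$ calwave simulate --seed 1 --d 2.5 --p-hat 1.8 --out kymo.tif
wrote kymo.tif (134 rows x 640 cols), 46 clusters, realized d = 2.52 um

$ calwave analyze --kymo kymo.tif --out events.csv
11 events -> events.csv

$ calwave velocity --kymo kymo.tif
1 propagating waves, mean v_w = 15.09 +/- nan um/s
```

The 134 × 640 kymograph covers 5 s × 115.2 µm.  Of the 11 events, 7 are
puffs, 3 abortive waves and 1 a propagating wave (the triggered wave,
which spans 86 µm before the record ends; with a single wave the
standard error of the mean velocity is undefined).  `events.csv` holds
one row per event with its bounding box, duration (s), extent (µm),
mean concentration (µM), Ca_T (a.u.) and both class labels.

The same stages are available as library calls:

```python
from calwave import (SimulationConfig, run_simulation, binarize,
                     label_events, summarize, wave_velocities)

kymo, info = run_simulation(SimulationConfig(seed=1, d=2.5))
events = label_events(binarize(kymo), kymo)
print(summarize(events, condition=(2.5, 1.6)))
```

Full sweeps (`calwave sweep`) enumerate a (d, p̂) grid with several
seeds per condition, cache per-run results, and emit per-condition
event counts and mean wave velocities ready for `calwave luther`.

## Layout

| module | contents |
| --- | --- |
| `calwave.receptor_kinetics` | subunit chain, tetramer open rule, stationary law |
| `calwave.calcium_field` | reaction–diffusion field, explicit integrator |
| `calwave.hybrid_simulator` | cluster layout, triggers, coupled run, kymographs |
| `calwave.event_analysis` | thresholding, event labeling, classification, phase metrics |
| `calwave.wave_metrics` | front angles, wave velocities, Luther fit |
| `calwave.cli_io` | config files, sweep orchestration, synthetic fixtures |
| `calwave.cli` | `calwave` command-line entry point |

See `docs/methods.md` for the numerical and statistical choices and
their rationale.
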