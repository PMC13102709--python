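# geminirec

Simulation, image analysis and temporal decoding for **granular
intracellular recorders** — engineered protein assemblies that grow
steadily inside live cells and deposit concentric fluorescent layers, so
that a single end-point image of a particle contains a tree-ring-like
record of the cell's activity history.

The package is aimed at people building or analysing such recorders: it
provides (i) a forward simulator that turns a recording protocol into
ground-truthed radial records, rendered midplane images and timelapse
stacks; (ii) the image pipeline that reads them back (particle detection,
reverse-order assignment tracking, radial-profile extraction and band
calling); and (iii) the decoding layer that converts band radii into an
absolute event chronology with Monte-Carlo accuracy benchmarks.

## The model

A particle growing by constant-rate subunit addition has volume linear in
time, so its radius follows the cube-root law

```
r(t) = (K t + A)^(1/3)
```

with `K` the volumetric growth rate (radius-units³/h) and `A` the cubed
radius at `t = 0`. Because the map between layer radius and deposition
time is strictly monotone, each radius `r` inside the particle converts
back to the time `t = (r³ − A)/K` at which that layer was laid down.

Timestamp dyes administered at known times `t₁, t₂, …` appear as bands at
radii `r₁, r₂, …`; two stamps solve `K` and `A` exactly per particle
(`K = (r₂³ − r₁³)/(t₂ − t₁)`, `A = r₁³ − K t₁`), more stamps are combined
by least squares on cubed radii. Any other band — a reporter switched on
by a signalling event — is then decoded through the same map. For
tracking data, projected particle area `A_px` is summarised by the
*volume index* `A_px^(3/2)`, which is linear in time under the model and
is the scale on which growth fits and their R² are computed.

Band positions are called on radial fluorescence profiles extracted
perpendicular to a particle edge (width-averaged, optionally Butterworth
low-pass filtered and baseline subtracted): band **onsets** by the
intercept of the tangent at the 50%-of-peak point with the baseline,
band **peaks** by the intensity maxima. For Gaussian radial localization
noise `σ_r`, error propagation through the cube-root law gives a decoded
timing standard deviation `σ_t ≈ 3 r² σ_r / K` — timing precision
degrades as `t^(2/3)`, which the late-window benchmark quantifies.

## Worked example

Decoding accuracy in the standard early recording window (timestamps at
0 and 11 h, signal onsets at 2–8 h in 1-h groups, 250 particles per
group, band jitter calibrated to a 0.75-h decoded s.d. at the window
midpoint):

```python
from geminirec import scenarios
import json

result = scenarios.early_window_benchmark(seed=42, n_per_group=250)
print(json.dumps(result.summary(), indent=2))
```

```
{
  "n": 1750,
  "error_mean_h": 0.032,
  "error_sd_h": 0.757,
  "group_sd_h": {"2.0": 0.70, "3.0": 0.64, "4.0": 0.72, "5.0": 0.78,
                 "6.0": 0.74, "7.0": 0.85, "8.0": 0.84},
  "fraction_within_h": {"1.0": 0.832, "2.0": 0.986, "3.0": 0.999, "6.0": 1.0}
}
```

Per-group timing s.d. stays sub-hour across the window, 83% of single
particles decode within ±1 h of the true onset and 99% within ±2 h.
`result.confusion` holds the decoded-versus-true crosstab, and
`result.table` the per-particle errors.

The same API covers the other canonical scenarios:
`scenarios.growth_fit_summary(seed)` (cube-root fit quality on noisy
timelapse trajectories — population-mean R² ≈ 0.9999, mean per-particle
R² ≈ 0.996), `scenarios.rapid_switch_band_count(seed)` (recovers all 11
bands of a rapid dye-switch particle from a rendered image), and
`scenarios.boost_resolution_scan(seed)` (with fast-turnover reporter
kinetics, dual events 15 min apart still render and call as two distinct
peaks).

Everything is also reachable from the shell:

```
geminirec simulate  --config protocol.yaml --seed 1 --out run/
geminirec track     --stack run/scene.tif --dt 0.5 --out tracks.csv
geminirec decode    --profile profile.csv --config protocol.yaml --out events.json
geminirec benchmark --seed 1 --out report.json
```

## Layout

- `geminirec.growth` — cube-root law, volume index, linearized fitting,
  timestamp calibration
- `geminirec.synth` — reporter kinetics, deposition map, midplane and
  timelapse rendering, profile-level Monte-Carlo band sets
- `geminirec.imaging` — particle detection, linear-sum-assignment
  tracking, track QC
- `geminirec.profiles` — radial profile extraction, conditioning, band
  onset/peak calling, multi-direction alignment
- `geminirec.decode` — event decoding, ON/OFF sequencing, amplitude
  quantification, benchmarks, resolution limit
- `geminirec.scenarios` — the canonical study conditions used by tests
  and scripts
- `geminirec.io` / `geminirec.config` / `geminirec.cli` — formats,
  validated YAML configuration, command line

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
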