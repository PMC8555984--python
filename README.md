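# mechpatch

Simulation and analysis toolkit for cell-attached patch-clamp recordings
of mechanosensitive channels, plus spatial statistics of channel
distributions sampled through virtual patch pipettes.

The package answers two kinds of questions end to end on synthetic data
with known ground truth:

1. **Spatial**: channels are placed by a Thomas-type cluster process
   (uniform parents, Gaussian-displaced daughters), sampled with circles
   emulating pipette domes (including single-channel-current conversion
   noise), and summarised by channel-count histograms and
   nearest-neighbour statistics.
2. **Functional**: a stochastic two/three-state gating model whose
   equilibrium open probability is a Boltzmann in pressure generates
   ramp and step protocols; the analysis side performs per-pressure
   binning, linear leak subtraction, Boltzmann/sigmoid fitting, channel
   counting (n = I_max / i), trace idealization, all-points amplitude
   histograms with double-Gaussian fits (Freedman–Diaconis binning),
   resting open probability, membrane circle fitting, Laplace-law
   tension conversion, spherical-cap dome areas, and footprint-coverage
   arithmetic.

## Layout

| module | contents |
| --- | --- |
| `mechpatch.spatial_model` | cluster process, patch sampling, NN statistics |
| `mechpatch.synthetic_data` | protocols, gating simulator, membrane-outline images |
| `mechpatch.ramp_analysis` | binning, leak subtraction, Boltzmann fits, idealization |
| `mechpatch.step_analysis` | peak/steady measurement, pressure-response fits, binned mean curves |
| `mechpatch.single_channel` | filtering, baseline, amplitude histograms, Po |
| `mechpatch.tension_geometry` | circle fits, Laplace tension, cap area, coverage |
| `mechpatch.studies` | end-to-end spatial and recording studies with recovery tables |
| `mechpatch.traceio` / `mechpatch.cli` | CSV/JSON formats and the command line |

## Command line

All stages are exposed as subcommands of a single entry point:

```sh
mechpatch simulate-field --seed 1 --out field.csv
mechpatch nn-stats --field field.csv --cutoff 100
mechpatch sample-patches --field field.csv --seed 2 --out counts.csv
mechpatch simulate-traces --protocol ramp --n-patches 5 --seed 3 --out traces/
mechpatch analyze-ramp --in traces/ --reference-current auto --out analysis/
mechpatch analyze-step --in traces/ --out analysis/ --subtract-baseline
mechpatch single-channel --in traces/patch000_ramp.csv --out analysis/
mechpatch geometry --image dome.npy --pixel-scale 61.5 --out analysis/
mechpatch coverage --n 200
mechpatch run-spatial-study --seed 1 --out study/
mechpatch run-recording-study --seed 1 --out study/
```

Traces are plain CSV (`time_ms,pressure_mmHg,voltage_mV,current_pA`)
with a JSON sidecar holding protocol, ground truth and seed; study
reports are JSON with the config hash and the seed embedded, so every
output is reproducible from (config, seed).

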