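# spikebm

Energy-based models of binary population spike rasters: maximum-entropy
Ising models, restricted Boltzmann machines (RBM) with analytically
marginalized hidden units, and semi-restricted Boltzmann machines (sRBM)
combining both — each optionally augmented with a fixed PSTH-derived
stimulus bias. Parameters are estimated by Minimum Probability Flow (MPF)
with single-bit-flip connectivity, L1 sparseness penalties and an L-BFGS
driver; models are normalized exactly (≤ 20–25 units) or by Annealed
Importance Sampling (AIS) with a chain-length convergence ladder, and
compared by held-out excess log-likelihood in bits/spike over the
independent firing-rate model.

## Layout

| module | contents |
|---|---|
| `spikebm.models` | `SpikeRaster`, parameter containers, energy / free-energy functions, PSTH dynamic bias, the `EnergyModel` contract |
| `spikebm.mpf` | MPF objective with analytic gradients, L-BFGS fitting, 4-fold cross-validation of the L1 penalty |
| `spikebm.partition` | exact enumeration, Gibbs sampling, AIS with convergence monitoring, per-bin PSTH partition functions |
| `spikebm.evaluation` | likelihood reports (bits/spike, bits/s), pattern-probability scatter with counting-noise envelopes, synchrony distribution P(K), conditional single-cell prediction, model entropy |
| `spikebm.spatiotemporal` | time-bin concatenation (disjoint/sliding), top-rate cell selection, history-conditioned prediction |
| `spikebm.synthetic` | ground-truth generators (independent / Ising / latent-assembly RBM / sRBM / PSTH trials), exact and Gibbs samplers |
| `spikebm.io`, `spikebm.pipeline`, `spikebm.cli` | raster/model containers, spike-time binning, train/test splitting, the end-to-end `compare` workflow, CLI |

## CLI

```sh
# synthetic raster with known ground truth
spikebm simulate --kind rbm --cells 12 --bins 40000 --rate 0.08 \
    --assembly 0:4:3.0 --assembly 4:8:3.0 --seed 0 --out raster.csv

# fit by MPF (optionally cross-validating the L1 penalty with --cv)
spikebm fit --kind rbm --input raster.csv --l1 1e-3 --seed 0 --out model.json

# attach a log partition function (exact for small models, AIS otherwise)
spikebm normalize --model model.json --method auto --out model_norm.json

# held-out likelihood report vs the independent baseline
spikebm evaluate --model model_norm.json --input raster.csv --out report.json

# whole pipeline: split, fit every kind, normalize, compare
spikebm compare --input raster.csv --kinds independent,ising,rbm,srbm \
    --seed 0 --out-dir results/
```

Also available: `spikebm predict` (per-bin conditional spike probabilities
as TSV) and `spikebm spatiotemporal` (concatenate consecutive bins into
flat spatiotemporal patterns).

## Conventions

States are binary vectors in {0,1}^d; probability ∝ exp(−E(x)), so positive
couplings encourage co-firing. Biases are stored separately from coupling
matrices. Internal math is in nats; reported quantities are in bits, with
bits/spike obtained by normalizing the likelihood gain with the population
firing rate per time bin.
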