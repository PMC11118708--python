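# v2pool

Deriving V2 receptive-field structure from anatomically identified V1
inputs: a tested reimplementation of the analysis pipeline, exercised
end-to-end on synthetic data with known ground truth.

The pipeline covers:

- **`v2pool.synthetic`** — generators for every input the analysis consumes:
  smooth pinwheel-style orientation preference maps with cosine-tuned pixel
  responses, spatially clustered labeled-cell sets with a tunable
  like-to-like orientation bias, model V1 populations, generatively pooled
  V2 tuning curves, and texture families paired with spectrally-matched
  noise.
- **`v2pool.oimaps`** — single-condition response maps from raw trial
  stacks (baseline subtraction, inversion, clipping, control division,
  band-pass filtering, non-specific-response subtraction, 0–100 rescaling),
  vector-sum preferred-orientation maps, and Levenberg–Marquardt Von Mises
  tuning fits with analytic half-width-at-half-height.
- **`v2pool.retinotopy`** — Winslow elliptic grid generation over a
  four-sided cortical outline (transfinite-interpolation start, Jacobi
  relaxation, 1e-5 displacement tolerance), resampling to a fixed
  degree step (a 2.5°×1.5° region at 0.02° gives a 125×75 grid), and
  nearest-node assignment of labeled cells to visual-field positions.
- **`v2pool.connectivity`** — axial circular statistics on doubled angles
  (MRL, CSD), 8-bin PO histograms, chi-square goodness of fit (dof = 7),
  pixel-resampling and rigid pattern-shift null ensembles with exceedance
  fractions, the wrapped-Gaussian perfect like-to-like simulation
  (FWHM 22.5°), and Bonferroni-corrected KS comparisons.
- **`v2pool.ffmodel`** — L2-normalized Gabor receptive fields, half-wave
  rectified simple-cell responses, 4-phase quadrature complex cells,
  phase-averaged grating tunings, aspect-ratio estimation against a
  40-value bank (0.1–4), connection weights as the cosine similarity of
  mean-subtracted tuning curves, linear pooled V2 responses, even/odd RF
  rendering, and eight-fold leave-one-out validation.
- **`v2pool.textures`** — spectrally-matched noise via Fourier phase
  randomization, 320×320 aperture preparation at 100 px/°, 8-rotation
  augmentation (30 images → 240 samples per condition), standardized
  image responses, modulation indices with reliability-based rotation
  selection, and V1-vs-V2 population comparison.
- **`v2pool.io` / `v2pool.pipeline` / `v2pool.cli`** — CSV/NPZ/JSON/YAML
  schemas, a seed-fanned deterministic end-to-end pipeline, and the CLI.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (weight extremes,
grid contract, complex-cell properties, leave-one-out self-consistency,
null-calibration, spectral-noise and chi-square checks); the rest are unit
and property tests per module.

## CLI

```sh
v2pool run --seed 7 --out demo_out       # full synthetic pipeline
v2pool simulate --seed 1 --out sim       # maps + labeled cells only
v2pool maps --stack sim/condition_maps.npz --out po.npz
v2pool grid --cells sim/cells.csv --width-px 63 --height-px 63 \
    --out assignments.csv
v2pool stats --po-map po.npz --cells sim/cells.csv --injection-po 45 \
    --out stats.json
```

`v2pool run` executes simulate → maps → grid → stats → model → textures,
writes all artifacts plus a checksummed `report.json`, and is
byte-reproducible under a fixed seed (one configured seed fans out to
deterministic per-stage child seeds). Configuration can also be given as a
YAML file (`--config`); unknown keys are rejected.

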