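# specindexnet

Interpretable band-selecting attention network for estimating leaf
photosynthetic capacity (V<sub>cmax</sub>, J<sub>max</sub>, μmol m⁻² s⁻¹)
from 400–1000 nm leaf reflectance spectra, together with:

- **Preprocessing** — Savitzky–Golay smoothing (window 21, order 2), power
  compression `|X|^β`, and natural cubic-spline band resampling.
- **Classic index screening** — SR / mNDVI / SIPI with exhaustive λ1×λ2
  correlation maps against trait labels.
- **The attention model** — a gated-convolution + U-shaped
  encoder/LSTM/decoder *mask* stage, ten cosine-similarity attention heads
  with an adaptive cosine scale and a uniform-noise Gumbel softmax that emit
  one hard band choice per channel, three vegetation-index branches
  (double-difference, add-multiply, ratio) and a softmax-gated fusion head.
- **Training** — MSE plus a cosine mask-shape loss (weight 0.05), rectified
  Adam, weight decay 1e-3, triangular cyclic learning rate, 80/10/10 splits,
  best-validation checkpointing.
- **Baselines & benchmark** — SVR, PLSR (component grid 10–15), a 1-D CNN
  and an index-form CNN, compared over preprocessing variants and seeds.
- **Interpretation** — sensitive-band frequency histograms, top-k bands,
  index-form importance scores, discovered-index summaries, and band-subset
  export for filtered-band validation.
- **Synthetic leaf generator** — leaf-like VNIR spectra with a planted
  add-multiply index→trait link at 800/550/670 nm, so every pipeline stage
  is testable without field data.

The neural networks run on `autograd` + NumPy (float32, GEMM-formulated
convolutions with hand-written gradients), so everything works on a plain
CPU with no deep-learning framework.

## CLI

```bash
specindexnet simulate --n 600 --seed 1 --out runs/sim
specindexnet preprocess --spectra runs/sim/spectra.csv --traits runs/sim/traits.csv --out runs/pre
specindexnet screen-indices --formula SIPI --trait vcmax --out runs/screen
specindexnet train --config config.yaml --seed 1 --out runs/train
specindexnet interpret --checkpoint runs/train/checkpoint --out runs/interp
specindexnet benchmark --seed 1 --out runs/bench
specindexnet poc-sweep --betas 0.2,0.6,1.0,1.4 --out runs/poc
specindexnet resolution-sweep --resolutions 60,204,300 --out runs/res
```

Commands read an optional YAML config (`--config`) with `model:`, `train:`,
`preprocess:` and `synthetic:` sections mirroring the dataclass fields;
flags override file values.  Every run writes its resolved config, a log,
and machine-readable CSV/JSON artifacts into the `--out` directory.

Input formats: spectra CSV with a `sample_id` column plus one `R_<nm>`
column per band (reflectance in [0, 1]); traits CSV with
`sample_id,vcmax,jmax`.

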