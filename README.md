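# fibroquant

Quantification pipelines for spontaneous pulmonary fibrosis studies in the
mouse lung. The package reimplements, as tested reusable code, the
quantitative computations that turn raw study readouts into numbers:

* **Trichrome fibrosis scoring** (`fibroquant.mt`) — an automated five-step
  pipeline for Masson's-trichrome-stained lung sections. Collagen stains
  blue, fibrin/vessels red, and the white slide background is achromatic;
  the pipeline segments the dark alveolar-wall tissue, closes it into the
  whole lung region, finds fibrotic regions as densely packed wall areas
  via a 2-D moving average, unmixes collagen from fibrin by a spectral PCA
  of candidate pixel colours (with automatic detection of the component
  order and polarity), and reports the **fibrosis score**

  `score = |collagen-positive area ∩ lung| / |lung tissue area|  ∈ [0, 1]`.

* **Immunofluorescence object counting** (`fibroquant.ifq`) — per-channel
  binarization, fragment bridging by morphological closing, small-object
  removal, and connected-component counting (cells per image per marker).

* **Single-cell computations** (`fibroquant.sc`) — cell QC (200–5,000
  detected features inclusive; mitochondrial count fraction ≤ 5%),
  log-normalization `log1p(count / cell_total × 10,000)`, signature scores
  (per-cell arithmetic mean of log-normalized marker genes, e.g. ILC1/2/3
  signatures), and within-compartment cell-type frequencies per disease
  phase with log2 fold changes against the intact phase.

* **Clinical formulas and statistics** (`fibroquant.clinical`) — static
  lung compliance `C_st = TV / (P_plateau − PEEP)` (PEEP defaults to
  2 cm H2O), the qPCR ddCt quantity and its fold change, collagen mass per
  lung wet weight, and the balanced-resampling two-tailed unpaired
  Student's t-test for comparing fibrosis scores between unequal groups.

* **Synthetic data with planted ground truth** (`fibroquant.synthetic`) —
  seeded generators for trichrome scenes with a known collagen fraction,
  IF fields with a known number of well-separated objects, and count
  matrices with planted QC-failing cells, a high-signature subpopulation,
  and phase-dependent cluster frequencies. These drive every end-to-end
  test.

Intended users: groups quantifying fibrosis histology and the accompanying
cellular/clinical readouts who want the arithmetic explicit, configurable
and tested, rather than buried in one-off analysis scripts.

## Worked example

```python
from fibroquant import MTSceneParams, generate_mt_image, run_mt_pipeline

params = MTSceneParams(collagen_patch_fraction=0.30, seed=11)
image, truth = generate_mt_image(params)
result = run_mt_pipeline(image)

print(f"planted fibrosis score : {truth.planted_score:.4f}")
print(f"estimated fibrosis score: {result.fibrosis_score:.4f}")
print(f"selected PC / polarity  : {result.selected_pc_index} / {result.polarity_sign:+d}")
print(f"PC loading (R, G, B)    : {result.pc_loading.round(3)}")
```

prints

```
planted fibrosis score : 0.3000
estimated fibrosis score: 0.3000
selected PC / polarity  : 1 / +1
PC loading (R, G, B)    : [-0.823  0.016  0.567]
```

The generator planted a collagen patch covering 30% of the lung ellipse;
the pipeline recovers that fraction from the rendered image alone. The
selected principal component's loading contrasts blue (+0.567) against red
(−0.823), and the polarity sign has been chosen so larger projections mean
more blue — on this chroma-dominated scene the blue-vs-red axis is the
first component, while on brightness-dominated real slides it is typically
the second or third; both are detected automatically.

The same stages are available from the shell:

```bash
fibroquant simulate mt --seed 11 --out scene/
fibroquant mt-score scene/mt_image.png --out scored/ --save-masks
fibroquant if-count stacks/*.tif --out counts/
fibroquant sc-qc --matrix counts.mtx --genes genes.txt --cells cells.txt --out qc/
fibroquant stats resample-test --in scores.csv --seed 1 --out test.csv
```

Every command writes a `run_record.json` with the tool version, config
hash and input digests.

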