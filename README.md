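# alveoquant

Fully automatic quantification of alveolar elastin structure in probe-based
confocal laser endomicroscopy (pCLE) snapshots.

The pipeline segments elastin with a trainable pixel classifier, cleans the
mask with physical-unit hole rules, and derives three per-snapshot readouts:

- **T_med** — median local thickness (μm): twice the distance from each
  skeleton pixel to the nearest background pixel.
- **σ_T** — standard deviation of local thickness (μm).
- **C_s** — structural connectivity (mm⁻¹): enclosed-hole count (from the 2D
  Euler number) divided by total skeleton length.

Cohort-level evaluation compares each pathology group (COP, HP, NSIP, IPF)
against the Normal group per parameter with two-tailed Wilcoxon rank-sum
tests and Bonferroni correction.

A synthetic phantom generator (Voronoi-tessellation fiber networks with
known masks, ribbon widths and enclosed-hole counts) makes the whole
workflow testable without patient data.

## Modules

| module | purpose |
| --- | --- |
| `alveoquant.image_io` | TIFF/PNG snapshots with μm spacing + circular FOV, cohort manifests, metrics CSV |
| `alveoquant.phantom` | synthetic elastin-network phantoms with ground truth, SNR degradation, sparse training labels |
| `alveoquant.segmentation` | multi-scale feature bank, undersampling, CFS, gain-ratio ranking, 200-tree random forest, ROC |
| `alveoquant.postprocess` | hole merging (< 2 μm walls) and small-hole filling (< 30 μm equivalent diameter) |
| `alveoquant.metrics` | skeletonization, Euler hole count, C_s, local thickness, per-snapshot quantification |
| `alveoquant.stats` | first-snapshot selection, Wilcoxon rank-sum (exact/normal), Bonferroni, report table |
| `alveoquant.cli` | `alveoquant` command with subcommands below |

## CLI

```sh
# synthesize a phantom snapshot + ground truth + training labels
alveoquant phantom --out-dir scratch/p0 --size 256 --seed 0

# train the pixel classifier (labels: <stem>_labels.png, 0/1/2 coded)
alveoquant train --manifest train.csv --labels-dir labels/ \
    --spacing-um 1.0417 --trees 200 --seed 0 --out model.joblib

# segment / quantify one snapshot
alveoquant segment --model model.joblib --image snap.tif --spacing-um 1.0417 --out mask.png
alveoquant quantify --model model.joblib --image snap.tif --spacing-um 1.0417 \
    --out metrics.json --save-intermediates inter/

# cohort statistics from a metrics CSV
alveoquant cohort-stats --metrics metrics.csv --out report.csv --m-tests 12

# full pipeline over a cohort manifest
alveoquant run --manifest cohort.csv --model model.joblib \
    --spacing-um 1.0417 --out-dir results/
```

The pixel spacing (μm/pixel) is always an explicit input; every threshold and
metric is in physical units. Defaults (200 trees, 2 μm merge distance, 30 μm
fill diameter, probability threshold 0.5) live in `PipelineConfig` and can be
overridden via a YAML config file (`--config`) or flags.

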