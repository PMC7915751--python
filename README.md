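# mitopop

Detection and cohort-level analysis of a MitoTracker-low monocyte
subpopulation in confocal micrographs: per-cell segmentation and
fluorescence quantification, per-subject kernel-density valley
thresholding, and k-means patient stratification with association
statistics — plus a synthetic image-and-cohort generator with known
ground truth that stands in for unavailable raw study data.

## Modules

| module | role |
| --- | --- |
| `mitopop.simulate` | synthetic three-channel 16-bit tiles (transmitted light, MitoTracker, PpIX), planted per-cell intensity mixtures, planted cohorts with covariates |
| `mitopop.imio` | pseudocolor pack/unpack (R = MitoTracker, G = PpIX, B = transmitted), tile-scan splitting, TIFF/16-bit-PNG tile I/O, per-cell CSV tables |
| `mitopop.segment` | edge-detection pixel classification (gradient + Otsu + morphology), size-based singlet/clump/debris classes, probability and border filters |
| `mitopop.quantify` | background-subtracted per-cell totals and per-pixel means, opening-spectrum granularity, size–granularity unimodality check |
| `mitopop.subpop` | per-subject log10-intensity KDE, valley threshold between the two heaviest modes, MitoTracker-low proportion |
| `mitopop.cohort` | normality test, deterministic 1-D 2-means stratification, Pearson correlations, pooled-variance t-tests, cluster report |
| `mitopop.pipeline` | simulate → segment → quantify → subpop → cohort glue |

## CLI

```sh
mitopop simulate --config cohort.yaml --out DIR --seed N [--fmt tif|png]
mitopop segment  --in DIR/tiles --config seg.yaml --out objects.csv
mitopop quantify --tiles DIR/tiles --out cells.csv
mitopop subpop   --cells cells.csv --out subjects.csv [--intensity mean|total] [--bandwidth silverman|FLOAT]
mitopop cohort   --subjects subjects.csv --covariates DIR/covariates.csv --out report/
```

The YAML config may contain `scene:`, `cohort:` and `subject:` sections
whose keys mirror the `SceneSpec`, `CohortSpec` and `SubjectSpec`
dataclasses (see `mitopop/simulate.py`).

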