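# vesidist

Spherical 3D modelling of intracellular vesicle distributions from
single-cell fluorescence z-stacks.

## The problem

In cells with impaired clathrin-mediated endocytosis — e.g. cardiomyocytes
derived from iPSC lines carrying dilated-cardiomyopathy mutations — early
endosomes (EEA1/Rab5-positive vesicles) no longer disperse homogeneously
through the cytoplasm: a large subpopulation arrests just beneath the plasma
membrane, and another accumulates perinuclearly. `vesidist` quantifies this
phenotype from 3D confocal or STED z-stacks of immunostained cells, one
stack per cell, without any segmentation of nucleus, membrane or individual
vesicles: the cell is modelled as a sphere and the fluorescent signal as a
weighted point cloud.

## The model

For a stack with pixel intensities $y_i$ at voxel centres $x_i$:

1. **Background.** Camera background is Gaussian; its mean $\mu$ is the
   location of the maximum of the pooled intensity histogram and its spread
   $\sigma$ the root mean squared deviation of intensities *below* $\mu$
   (the bright signal lives only in the right tail). The binarization
   threshold is $\theta = \mu + n_\sigma\,\sigma$ with $n_\sigma = 10$ for
   confocal stacks. For STED data a global-moment threshold
   $\theta = \bar y + n_\sigma\,\mathrm{sd}(y)$ (the "1σ criterion") is
   used instead.
2. **Weights and centre.** Each suprathreshold pixel gets weight
   $\omega_i \propto [y_i > \theta]\,(y_i - \theta)$; the cell centre is the
   weighted centre of mass
   $c = \sum_i \omega_i x_i / \sum_i \omega_i$.
3. **Size normalisation.** The cell size is the radius of gyration
   $R_g = \sqrt{\sum_i \omega_i \lVert x_i - c\rVert^2 / \sum_i \omega_i}$,
   and every distance is expressed as the dimensionless
   $s_i = \lVert x_i - c\rVert / R_g$.
4. **Distributions.** Per-cell weighted histograms of $s_i$ on a common
   grid ($[0, 2.5]$, 100 bins) are averaged per condition, summarised by a
   *membrane fraction* (integrated mass at $s > 1.2$), screened for
   bimodality (a resolved second mode at $s \approx 0.9$–$1.6$ marks
   membrane-arrested vesicles), and compared across groups by PCA of the
   density rows.

A synthetic-stack generator produces ground-truth-annotated cells —
homogeneous (WT-like), perinuclear-core + membrane-shell mixtures
(MUT-like), and rescued intermediates — with realistic Gaussian detector
background and PSF-blurred puncta at confocal-like or STED-like resolution,
so the entire pipeline is testable without microscope data.

## Worked example

```python
from dataclasses import replace
import vesidist as vd

base = vd.SyntheticCellSpec()
wt  = replace(base, spatial_model="uniform_ball", group="WT")
mut = replace(base, spatial_model="bimodal", membrane_weight=0.5, group="MUT")

cells = vd.generate_population(wt, 12, jitter=0.2, seed=11)
cells += vd.generate_population(mut, 12, jitter=0.2, seed=12)
results, _ = vd.analyze_stacks([stack for stack, _ in cells])
summary = vd.pca_distributions(vd.summarize(results))
```

(`examples/03_population_bimodality.py`) prints:

```
WT: mean membrane fraction (s > 1.2) = 0.225, mean-curve peaks at s = [0.96]
MUT: mean membrane fraction (s > 1.2) = 0.326, mean-curve peaks at s = [0.69, 1.31]
PC1 majority-sign accuracy: 96% (PC1 explains 48% of variance)
```

The WT mean curve is unimodal, as expected for homogeneously dispersed
vesicles; the MUT curve gains a second mode at $s \approx 1.3$ — the
plasma-membrane population — which raises its membrane fraction and lets the
first principal component separate the two groups. The other scripts under
`examples/` walk through background fitting, single-cell analytic limits,
STED-vs-confocal event resolution and the vehicle-vs-treated rescue
comparison, each printing the numbers it computes.

## Command line

```sh
vesidist simulate config.yaml -o data/        # synthetic cohorts + manifest
vesidist analyze data/manifest.csv -o runs/   # per-cell models + histograms
vesidist population runs/ -o report/ --compare MUT WT
```

`analyze` writes per-cell background JSON, scaled/raw histogram CSVs and QC
projections, listing QC failures in `exclusions.csv` (exit code 2 when some
cells were excluded); `population` writes the per-cell summary table, group
mean curves, PCA scores and a JSON report.

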