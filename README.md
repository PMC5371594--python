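# mklpet

Region-kernel SVM analysis of dopaminergic brain PET, built to separate
idiopathic Parkinson's disease (PD) from the atypical parkinsonian syndromes
multiple system atrophy (MSA) and progressive supranuclear palsy (PSP).

Postsynaptic D2/3 radioligand imaging (e.g. ^18F-desmethoxyfallypride PET)
concentrates most of its signal in the striatum, but carries usable
extrastriatal information. A classifier over all brain voxels at once lets
bright striatal voxels drown out small dim regions; a classifier per region
throws away their interactions. `mklpet` implements the middle road: a
**multiple-kernel SVM** whose kernel is a convex combination of per-region
linear kernels,

    k(x_i, x_j) = sum_m q_m k_m(x_i^m, x_j^m),     q_m >= 0,  sum_m q_m = 1,

with the soft-margin SVM trained in its dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j k(x_i, x_j)
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C.

The regions entering the combination are discovered from the data: a linear
SVM on all in-brain voxels yields a weight map |w|, each region is scored by
its mean weight w_r = (1/N_r) sum_{x_i in r} |w_{x_i}|, and the top-5 regions
are kept — inside each cross-validation fold, on training data only. Both C
and the kernel weights q come from a nested grid search
(C = 2^e, e in {-3..5}; q on a 0.1-step simplex lattice).

The package ships everything needed to exercise the method end to end
without clinical data:

| module           | contents |
| ---------------- | -------- |
| `volumes`        | NIfTI volumes/atlases, Gaussian smoothing, midplane reflection, brain masks |
| `phantom`        | synthetic atlas + PET-like cohorts with seeded group effects (PD/MSA/PSP) |
| `preprocess`     | 12-parameter affine registration, symmetric template building, top-0.1% intensity normalization |
| `parcellation`   | atlas region -> feature-matrix blocks, whole-brain feature vectors |
| `svm` / `_smo`   | SMO dual solver (numba-jitted), kernel combination, one-vs-one multiclass |
| `importance`     | voxel weight maps, region importance, top-k selection |
| `evaluation`     | stratified k-fold CV with in-fold selection, nested grid search, metrics, permutation test, ROC/AUC, voxelwise t-maps |
| `cli` / `config` | `mklpet` command-line tool driven by one YAML config |

## Worked example

```python
import numpy as np
from mklpet import phantom as ph, evaluation as ev

spec = ph.PhantomSpec.strong()          # pronounced group effects
atlas = ph.make_toy_atlas(spec)
cohort = ph.simulate_cohort(spec, {"PD": 30, "MSA": 15, "PSP": 15},
                            seed=77, atlas=atlas)

report = ev.run_cv_pipeline(cohort, atlas, ev.EvalOptions(mode="binary",
                                                          k=10, seed=5))
acc, sens, spec_ = report.binary_metrics()
print(f"accuracy {100*acc:.1f}%  sensitivity {100*sens:.1f}%  "
      f"specificity {100*spec_:.1f}%")
print("fold-0 regions:", report.folds[0].selected_regions)
```

prints

```
accuracy 100.0%  sensitivity 100.0%  specificity 100.0%
fold-0 regions: ['putamen', 'caudate', 'olfactory', 'supplementary-motor-area', 'thalamus']
```

i.e. on a 60-subject phantom with pronounced striatal/extrastriatal uptake
reductions the pipeline separates idiopathic from atypical parkinsonism
perfectly, and the in-fold importance ranking recovers exactly the five
regions in which the group effects were seeded (putamen, caudate, olfactory
region, supplementary motor area, thalamus). With the default (milder)
effect sizes accuracies drop below ceiling while the same five regions are
still selected in ~100% of folds — the behaviour the selection stage is
designed to show.

The same pipeline is available from the shell:

```bash
mklpet simulate  -c config.yml          # phantom cohort -> NIfTI + manifest
mklpet evaluate  -c config.yml          # cross-validated metrics -> JSON
mklpet permtest  -c config.yml          # permutation significance
mklpet ttest     -c config.yml          # voxelwise two-sample t-map
mklpet roc       -c config.yml          # ROC/AUC from the CV report
```

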