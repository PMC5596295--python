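# graicar

Group-ICA reproducibility analysis (gRAICAR) with a discover-confirm scheme
for two-group resting-state-fMRI-like cohorts.

Spatial ICA of a subject's time x voxel matrix returns components in no
particular order, different at every run. For multi-subject studies the
useful components are the *reproducible* ones — those that reappear across
random ICA restarts of the same subject and across subjects. This package
ranks components by exactly that criterion and builds on it a scheme for
finding group-discriminative brain networks without ever showing the
diagnosis to the model:

1. **gRAICAR.** For each subject, run spatial FastICA `d` times from random
   initial values (realizations, REs). Fill a full similarity matrix (FSM)
   with the normalized mutual information
   `NMI(x, y) = (H(x) + H(y)) / H(x, y) − 1`
   between all component pairs, standardize it within realization blocks
   (SNMI), and greedily align matching components across subjects and
   realizations into aligned components (ACs). Each AC is summarized by its
   inter-subject consistency matrix `α`, subject centralities `τ`, and
   intra-subject reliabilities `β`; its group map is the `β·τ`-weighted
   average of member maps. ACs whose mean consistency exceeds the 95th
   percentile of a 500-resample bootstrap null (pseudo-ACs of randomly
   drawn components) are significant.
2. **Discover.** Run gRAICAR three times — on group A, group B, and the
   merged cohort — and drop every group component that is also reproducible
   in the merged cohort (spatial |r| ≥ 0.5). What survives is reproducible
   *within* a group but not *across* groups: the candidate discriminators.
3. **Confirm.** For each (A-component, B-component) pairing, stack one
   spatial map per subject into a matrix, cluster it with k-means (k = 2)
   blind to the labels, and score cluster purity, sensitivity and
   specificity against the diagnosis. A 5x5 self-organizing map renders the
   separation as a grid of group-composition pie charts.

Everything runs on synthetic cohorts from the built-in generator (planted
spatial sources x band-limited time courses + noise, with shared and
group-exclusive sources), so the whole pipeline is testable at desk scale.
See `docs/methods.md` for the model, estimators, null distributions, and
design decisions.

## Worked example

```python
import numpy as np
from graicar import CohortSpec, GraicarConfig, generate_cohort, make_blob_sources
from graicar.workflow import confirm, discover

sources = make_blob_sources(["shared", "group_A_only", "group_B_only"],
                            n_voxels=2000, seed=11)
spec = CohortSpec(n_subjects_per_group=8, n_timepoints=120,
                  sources=sources, snr=10.0, seed=11)
datasets, truth = generate_cohort(spec)

disc = discover(datasets, GraicarConfig(n_components=3, n_realizations=5, seed=0))
print("significant components: A =", len(disc.result_a.reproducible),
      " B =", len(disc.result_b.reproducible),
      " combined =", len(disc.result_combined.reproducible))
print("after exclusion: A =", len(disc.exclusive_a), " B =", len(disc.exclusive_b))

results, table, summary = confirm(disc, seed=0)
print(table.to_string(index=False))
a_map = truth.spatial_maps[1]
best = max(abs(np.corrcoef(gc.map, a_map)[0, 1]) for gc in disc.exclusive_a)
print(f"best |r| of a discovered A component with the planted A-only map: {best:.3f}")
```

Output:

```
significant components: A = 2  B = 2  combined = 1
after exclusion: A = 1  B = 1
 component_a  component_b  purity  sensitivity  specificity
           0            0     1.0          1.0          1.0
best |r| of a discovered A component with the planted A-only map: 0.999
```

Reading this: each group run finds its two planted sources (shared + its own
exclusive) reproducible; the merged-cohort run finds only the shared source
reproducible across everyone; exclusion therefore removes the shared source
from both group lists, leaving exactly the two group-exclusive networks. The
single pairing of those two networks separates the 16 subjects perfectly
under label-blind k-means (purity, sensitivity, specificity all 1.0), and
the discovered A map is spatially identical to the planted one (|r| = 0.999).

## Command line

A thin CLI covers the same pipeline on directories of NIfTI/TSV data:

```
graicar simulate  --config cohort.yaml -o cohort/ --seed 3
graicar decompose -i cohort/ -o realizations/ --n-components 3 --seed 3
graicar graicar   -i cohort/ -o run/ --config run.yaml --seed 3
graicar discover  -i cohort/ -o run/ --config run.yaml --seed 3
graicar confirm   -i run/ -o run/ --seed 3
graicar report    -i run/
```

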