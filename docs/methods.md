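# Methods

## The problem

Group ICA of resting-state fMRI yields, per subject, a set of spatially
independent components (spatial map + mixing time course). Components are
unordered and run-dependent, so two questions arise before any group
comparison is possible: which components are *reproducible* — across random
ICA restarts of the same subject and across subjects — and which reproducible
components actually *discriminate* two diagnostic groups. This package
implements a reproducibility-ranking algorithm (gRAICAR, a group extension
of the RAICAR idea of ranking components by their recurrence across random
restarts) together with a discover-confirm scheme: components reproducible
within each group but not in the merged cohort are the candidate
discriminators, and their discriminative power is confirmed with label-blind
k-means clustering scored against the diagnosis afterwards.

## Pipeline

1. **Realizations** (`ica`). Each subject's `t x v` matrix is decomposed `d`
   times by spatial FastICA (voxels as samples, a fixed-point negentropy
   contrast) from distinct random initializations. Maps are variance
   normalized and sign-fixed to non-negative skewness; scale and sign move
   into the time course, leaving the reconstruction unchanged. A
   non-converged run is retried with fresh starts and, failing that,
   returned flagged rather than silently dropped.

2. **Full similarity matrix** (`similarity`). Similarity between two maps is
   normalized mutual information, `NMI(x, y) = (H(x) + H(y)) / H(x, y) - 1`,
   1 for identical and 0 for independent maps. The default estimator is an
   equal-width histogram plug-in with `ceil(sqrt(v))` bins capped at 64 —
   deterministic and bounded; a Kraskov k-nearest-neighbor variant is
   available (`estimator="ksg"`), with the caveat that its differential
   entropies make the normalization approximate. The FSM collects NMI
   between all component pairs across all realizations of all subjects,
   organized in subject blocks (SB) and realization blocks (RB); each
   off-diagonal RB is standardized (SNMI) by the mean/std of the
   row-union-column multiset, with the intersecting entry counted once (a
   flag provides the count-twice reading). Diagonal RBs are zeroed.

3. **Alignment** (`alignment`). Repeatedly: take the global SNMI maximum over
   cross-subject entries as the seed of an aligned component (AC); for every
   other realization locate the row candidate (best match to seed 1) and the
   column candidate (best match to seed 2); equal candidates join outright,
   unequal ones are resolved by the candidate's mean NMI to the members
   agreed so far (ties to the row candidate); eliminate all member
   rows/columns; stop after `c_max` ACs (the maximum per-subject component
   count). Ties in the maximum search break to the lexicographically
   smallest index tuple so results are exactly reproducible.

4. **Group metrics and significance** (`group`). For each AC the
   reproducibility matrix (member-pairwise NMI) is summarized by
   inter-subject consistency `alpha[i, m]` (mean NMI between i's and m's
   members), centrality `tau[i]` (mean of `alpha[i, m]` over `m != i`) and
   intra-subject reliability `beta[i]` (mean within-subject member NMI; 1
   for a single member). The group map is the `beta * tau`-weighted average
   of per-subject mean member maps after sign harmonization against the
   seed map. Significance is non-parametric: 500 pseudo-ACs are drawn by
   sampling one component per (subject, realization) with replacement, and
   an AC is significant when its mean consistency exceeds the 95th
   percentile of the pseudo-AC means (p = 0.05). Optional subject-level
   nulls (random reassignment of members) flag which subjects are
   representative of an AC.

5. **Discover-confirm** (`workflow`). gRAICAR runs on group A, group B and
   the merged cohort; group components spatially matching a merged-cohort
   reproducible component (|Pearson r| >= 0.5) are excluded. For each
   remaining (A component, B component) pairing, per-subject maps are
   stacked into one matrix (group-A rows under the A component, group-B
   rows under the B component), clustered with k-means (k = 2, best of 10
   restarts), and scored by purity, sensitivity and specificity against the
   diagnosis. Per-subject ICA realizations are computed once and shared by
   the three runs; the group similarity matrices are sliced out of the
   combined one (exact, since NMI is pairwise and SNMI is RB-local).

6. **SOM visualization** (`som`). A 5x5 rectangular self-organizing map
   (Gaussian neighborhood, radius 2.5 -> 1, learning rate 0.5 -> 0.01, 500
   sample presentations by default) projects the stacked subject maps onto
   a grid; per-neuron pie charts of group composition visualize separation.

## Selecting "consistent across all subjects"

The mean-consistency significance test has a structural blind spot that
matters for the discover step: a component carried by only one of two
balanced groups keeps roughly half of its subject pairs at full strength,
which places its mean consistency almost exactly at the null's 95th
percentile — selection degenerates to a coin flip. The package therefore
distinguishes *significant* (the mean test, exactly as defined above) from
*reproducible across the cohort*: a significant AC is reproducible when at
least 60% of subject pairs individually exceed the 95th percentile of the
pooled pair-level null. For balanced two-group cohorts a single-group
component is bounded at ~47% of pairs (within-group pairs plus the ~5%
chance exceedances among cross-group pairs), while a genuine cohort-wide
component fails only the pairs touching poorly decomposed subjects; 60%
separates the two regimes with margin on both sides and tolerates roughly a
quarter of subjects decomposing badly. The discover step uses the
reproducible subset in all three runs.

## Synthetic cohorts

`synthetic` generates two-group cohorts under the linear mixing model
`M = A S + E`:

* **Spatial sources** are sparse smooth blob maps. Each source's blobs are
  confined to its own stripe of the grid (distinct networks occupy distinct
  territory), pairwise |Pearson r| < 0.15 is enforced by redraw, and the
  active fraction (|value| above a quarter of the peak) must fall in
  [0.05, 0.20]: a near-empty map carries too little mutual information to
  be matched across subjects, and a diffuse map is too Gaussian for a
  negentropy ICA contrast to isolate reliably. Membership tags
  (`shared` / `group_A_only` / `group_B_only`) plant the group structure.
* **Time courses** are unit-variance Gaussian processes band-passed to
  0.01-0.1 Hz at TR = 2 s (third-order Butterworth, forward-backward),
  emulating already-preprocessed resting-state data, with per-subject
  lognormal amplitude jitter (sigma = 0.1).
* **Noise** is i.i.d. Gaussian scaled so that `var(signal)/var(noise)`
  equals the requested SNR; `snr=inf` gives exact noiseless data.

What this does *not* emulate: hemodynamics, head motion, physiological or
spatially correlated noise, scanner/site effects, inter-subject anatomical
variability. Passing tests therefore demonstrate the correctness and
internal calibration of the algorithm under its own model assumptions, not
performance on real multi-site fMRI.

## Default parameters and problem sizes

| parameter | default | why |
|---|---|---|
| realizations `d` | 10 (5 in recovery studies) | reproducibility logic is d-agnostic; 5 suffices for stable member sets at desk scale |
| components per subject | config or `estimate_dimension` | at desk scale 3 = 2 true sources + 1 extra dimension, mirroring model-order overestimation on real data; exactly 2 makes the SNMI search and both nulls degenerate (random pseudo-ACs chance-match half the time) |
| NMI bins | `min(64, ceil(sqrt(v)))` | plug-in bias ~0.02-0.1; bounded, deterministic |
| null resamples | 500, 95th percentile | calibrated: ~5% of fresh pseudo-ACs exceed the threshold on structureless data |
| pair coverage | 0.60 | see selection section |
| exclusion threshold | \|r\| >= 0.5 | automated stand-in for visual matching of group maps |
| k-means | k=2, 10 restarts | two diagnostic groups |
| recovery cohorts | 8/group, t=120, v=2000, snr=10 | t and v are large enough that FastICA separates the planted sources cleanly (map r ~ 1.0) and accidental NMI spikes between noise components (~1/sqrt(v)) stay below genuine seeds in the saturated SNMI search |

A note on SNMI saturation: within an RB the standardized value of a single
strong entry in an otherwise flat row/column union is pinned near the
algebraic maximum `sqrt(|union| - 1)` regardless of how strong the match is,
so the global-maximum search ranks candidates by the *cleanliness* of their
neighborhoods, not by match magnitude. This is inherent to the published
standardization; the pair-coverage selection and the generous map length are
what keep it benign at desk scale.

## Numerical conventions

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical inputs and seeds give bit-identical
  outputs, including FastICA restarts, nulls, k-means and the SOM.
* Degenerate cases: constant maps are rejected by the NMI estimator;
  constant RBs standardize to 0 with a warning; all-zero group-map weights
  fall back to an unweighted mean with a warning; k-means on fewer than two
  distinct rows retries with fresh seeds and then raises.
* Sign conventions: component maps have non-negative skewness; member maps
  are sign-harmonized to the seed map before averaging; spatial matching is
  signed Pearson correlation on variance-normalized maps (a sign-flipped
  duplicate does not beat the original).

## Known limitations

* The greedy alignment is not globally optimal; on instances small enough
  to enumerate it stays within 5% of the exhaustive optimum (usually at
  it), which is the tested guarantee.
* The pair-coverage rule assumes roughly balanced groups; heavily unbalanced
  cohorts shift the ~47% bound and the 0.60 default should be revisited.
* With only two components per subject the whole procedure becomes
  degenerate (see above); realistic model orders avoid this.
* A cohort whose exclusive source decomposes poorly in one group (roughly
  1 in 40 random cohorts under the default conditions) can still lose that
  source at the discover stage; the confirm metrics are unaffected because
  they are computed only over discovered pairings.
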