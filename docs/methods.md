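# Methods

This document describes the statistical and computational methods implemented
in `sfc_aging`, in pipeline order, followed by the synthetic-cohort model and
its parameter tables.

## 1. Connectome construction

For each subject, the node × time matrix (rows follow the node table built
from the atlas, excluding ventricle and background voxels) is reduced to a
Pearson correlation matrix. Constant node series are rejected with an error
naming the offending nodes; at least three time points are required.

Correlations are converted to one-sided p-values via the t-transform
`t = r sqrt((T − 2)/(1 − r²))` with `df = T − 2`, testing `r > 0`. The
Benjamini–Hochberg procedure (`scipy.stats.false_discovery_control`) at
q = 0.05 (default) selects edges; only positive correlations can survive. A
fixed correlation cut-off (`rule="fixed_r"`) is available as an alternative.
The result is an undirected, unweighted, self-loop-free graph. An empty graph
triggers a warning rather than an error.

## 2. Seed definition

The caudate seed is split by ventricle adjacency:

- **medial caudate** — caudate voxels with at least one *ventricle* neighbour
  under the chosen connectivity (6 face neighbours by default; 18 adds edge
  neighbours, 26 adds corners);
- **lateral caudate** — all remaining caudate voxels.

Left and right hemispheres are pooled into single bilateral seeds. A
whole-caudate seed (the union) is used for the group-level age contrasts.

## 3. Stepwise functional connectivity

Given a binary adjacency matrix `A` and a seed set `S`, the step-k SFC value
of node `j` is the number of length-k walks from any seed node to `j`:

```
sfc_k(j) = Σ_{s ∈ S} (A^k)_{sj},  k = 1 … 4
```

computed as iterated vector–matrix products (the indicator vector of `S`
multiplied by `A`, k times), never by materializing matrix powers. Walks may
revisit nodes and the seed; that is the intended counting semantics.

Each step map is z-scored across an analysis mask that excludes the seed
nodes (seed entries are set to NaN). For the medial/lateral pair the mask
excludes the *whole* caudate so that the two maps are standardized over the
identical node set and are directly comparable within subject. A constant map
z-scores to zero rather than dividing by zero.

The **combined map** assigns each node the step index (1–4) at which its
z-score is largest, ties resolved toward the smaller step; nodes with no
finite positive evidence get the sentinel 0.

## 4. Group and paired inference

Group contrasts use a GLM with a ±½-coded group regressor and centred
nuisance covariates (sex, education by default). Permutation inference
follows the Freedman–Lane scheme: the reduced (nuisance-only) model is fit,
its residuals are permuted, refit under the full model, and the t-statistic
of the group regressor is recomputed per permutation. Family-wise error is
controlled at α = 0.05 by the max-statistic (maxT) over nodes; corrected
p-values use the unbiased estimator `p = (1 + #{maxT_perm ≥ |t|}) / (1 + n_perm)`.

Threshold-free cluster enhancement (TFCE) is available as an alternative
statistic: `TFCE(p) = Σ_h extent(p, h)^E · h^H · dh` with E = 0.5, H = 2 and
dh = max/100, where extent is the size of the connected component containing
`p` at threshold `h` in the voxel 6-connectivity graph (components via
`scipy.sparse.csgraph.connected_components`). The maxT step then runs on the
enhanced values.

The within-subject medial-versus-lateral contrast is a paired test: per-step
difference maps feed a one-sample t-statistic whose null is generated by
random sign flips of the subject differences, again maxT-corrected.

## 5. Region sets and morphometry

**Region sets.** Nodes significant for the medial and lateral seeds are
tallied per atlas region. A region joins the medial-caudate-related (MCR) or
lateral-caudate-related (LCR) set when at least `min_frac = 0.1` of its
voxels are significant for the corresponding seed, majority vote deciding
regions significant for both; everything else is `rest`.

**Normative standardization.** Per region, `Z = (x − μ_young) / σ_young`
with the young-group mean and SD (ddof = 1, ≥ 2 subjects). Regions with zero
young-group SD are excluded with a warning.

**Region-set ANOVA.** With the default `unit="region"`, the observation is a
region's mean Z within the tested group; a one-way ANOVA compares MCR, LCR
and rest, followed by pairwise t-tests using the pooled within-set mean
square, Bonferroni-corrected over the 3 comparisons. `unit="subject"`
switches the observation to a subject's mean Z over the set's regions.

**SFC–morphometry correlation.** Region-level SFC summaries (combined step
index, or step-1 z-strength) are Pearson-correlated with region mean Z in the
middle-aged and elderly groups.

## 6. Synthetic cohort

### Atlas

A rectangular grid contains a one-voxel-thick mid-sagittal ventricle slab,
two-voxel-thick caudate blocks on either side of it (so the medial and
lateral caudate are equal one-voxel layers), and the remaining volume tiled
into roughly equal cortical/subcortical parcels by recursive box splitting.

### Time series

Signals are i.i.d. in time from a stationary Gaussian community factor
model. Node `i` in community `c`:

```
x_i(t) = u_c(t) + sqrt(1 − ρ_c) e_i(t),   Var(u_c) = ρ_c
```

so within-community correlation is exactly ρ_c. The factor covariance Ψ
encodes caudate–network coupling and its planted aging deltas; slight
indefiniteness is repaired by eigenvalue clipping (an error if the most
negative eigenvalue is below −0.05).

### Seed–target pairing

Direct caudate→cortex edges are planted by letting selected cortical voxels
track the *idiosyncratic* components of specific caudate voxels. For a target
with q partners of unit-variance idiosyncratic components `ẽ_p`:

```
x_target = β Σ_p ẽ_p + sqrt(1 − q β²) ε,   β = pair_r / sqrt(1 − ρ_caudate)
```

which gives `corr(target, partner) = pair_r` exactly and unit variance. Three
structural properties matter:

1. **Disjoint partner windows.** Each caudate voxel serves at most one
   target. Shared partners would correlate targets with each other,
   creating target–target edges and hence spurious length-2 walks that leak
   the medial/lateral asymmetry into step-2 SFC; disjointness confines the
   planted asymmetry to direct (step-1) edges.
2. **Sparse targets.** Only `ceil(target_frac × parcel size)` voxels per
   target parcel are paired; the rest are ordinary community members. This
   bounds demand on the finite caudate partner pool.
3. **No community loading on targets.** Paired targets are built purely from
   partner idiosyncrasies plus noise, so their only systematic correlation
   is with their partners.

Parcels designated MCR targets pair with medial voxels, LCR targets with
lateral voxels; the generator records the planted sets so recovery can be
scored.

### Morphometry

Per region: `value = young_baseline_mean + shift × young_baseline_sd +
noise`, with baselines drawn once per cohort, group shifts from the
configured atrophy gradient, and i.i.d. unit-variance subject noise (an optional per-region
random effect, `region_effect_sd`, defaults to 0).

### Default parameters

| Parameter | Default | Role |
| --- | --- | --- |
| `n_per_group` | (52, 42, 58) | young / middle / elderly subjects |
| `grid_dims`, `n_parcels` | (12, 12, 12), 20 | atlas geometry |
| `n_timepoints` | 150 | scan length |
| within-community r | 0.5 (0.4 subcortical) | ρ_c |
| between-community r | 0.10 | baseline factor coupling |
| caudate–DMN / caudate–frontoparietal r | 0.35 | seed coupling (young) |
| aging deltas, middle | −0.15 / −0.15 / +0.15 | DMN / frontoparietal / sensorimotor |
| aging deltas, elderly | −0.25 / −0.25 / +0.20 | same edges |
| `pair_r`, `n_pairs_per_target`, `target_frac` | 0.35, 3, 0.1 | direct-edge planting |
| atrophy shifts, middle | −0.4 everywhere | equal across sets (null gradient) |
| atrophy shifts, elderly | MCR −0.8, LCR −0.4, rest −0.6 | planted gradient |

Every random draw descends from named integer seed sequences
(`[seed, 1, subject]` for time series, `[analysis_seed, …]` for permutation
streams), so cohorts and analyses are bit-reproducible.

## 7. Limitations

- The cohort model is stationary and Gaussian; no autocorrelation, motion,
  or physiological structure is simulated.
- Walk counts conflate path multiplicity with reach; they are the intended
  primitive here, not an approximation of shortest-path or communicability
  measures.
- Region-set ANOVA at the default three MCR/LCR regions has limited power
  for the planted −0.8 vs −0.4 gradient in a single cohort (the
  subject-sampling variance of a region mean-Z is ≈ 1/58 + 1/52 alone);
  detection at ≥ 90% power needs on the order of ten regions per set.
- TFCE is implemented for the voxel-grid adjacency only.
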