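# Methods

## Network model

A group's metabolic network treats the 90 AAL regions as nodes and the
across-subject Pearson correlation of regional SUVR as the connection
weight: for regions i and j, r_ij is computed from the group's M×90 data
matrix (M subjects). This is a *group-level* construct — there is one
network per diagnostic group, not per subject — and it assumes the
across-subject covariance of regional metabolism reflects functional
coupling. Correlations are computed on SUVR as-is: no Fisher
z-transformation, no partial correlation, and no covariate regression.

Binarization keeps an edge where r_ij ≥ τ. Ties count as edges; the grid
is positive (0.50–0.90, step 0.02, 21 values), so negative correlations
never form edges, and no absolute-value mode is applied by default.
Signed-threshold behaviour is deliberate: anticorrelation is not treated
as connectivity here.

**Threshold selection.** A single τ must be shared across groups for edge
counts to be comparable. The rule: among the grid values at which the NC
network retains all 90 nodes (every region has degree ≥ 1), take the
largest. This is the most conservative threshold that still yields a
fully-covered control network; any higher grid value would disconnect at
least one NC region. The alternative reading (the smallest covering grid
value) is available via `select_threshold(..., rule="smallest")` but is
nearly always the grid minimum and is not the default. Node counts in all
reports are *connected* nodes (degree ≥ 1); isolated nodes are excluded.

**Edge accounting.** Each edge is classified by its endpoints' hemispheres
(intra-left / intra-right / inter-hemispheric; the three classes sum to the
total) and by the unordered pair of lobe categories (28 pairs of 7
categories; these counts also sum to the total). The 45×45
inter-hemispheric matrix indexes left regions by rows and right regions by
columns in homologue-aligned order, so homologue (left–right mirror) pairs
lie on its diagonal; its suprathreshold cell count equals the
inter-hemispheric class of the full partition by construction, which the
test suite asserts.

## Atlas conventions

The packaged table (`metaconn/data/aal90_atlas.tsv`) fixes the canonical
AAL-90 label order (left/right interleaved), hemisphere, lobe category and
approximate MNI centroid per region. Lobe categories: frontal (10 pairs),
temporal (7 pairs, including fusiform, which the connectivity literature
groups with the temporal lobe), parietal (6 pairs, including postcentral
and precuneus), occipital (6 pairs), subcortical (thalamus, pallidum,
caudate, putamen, amygdala), hippocampus (its own category), and "other"
(10 pairs: the central structures precentral, rolandic operculum,
supplementary motor area and paracentral lobule, plus olfactory, insula,
the three cingulate regions and parahippocampal). The grouping is a
documented convention — lobar boundaries for AAL structures are not
standardized — and can be replaced wholesale by passing an alternative
table (`load_atlas(path)` / `--atlas PATH`). Centroids are used only in
BrainNet Viewer exports; no statistic depends on them.

## Synthetic cohorts

The generator emulates four-group SUVR studies at the standard sizes
(NC 100, sMCI 45, pMCI 55, AD 100 subjects). Per group, subjects are drawn
i.i.d. from a 90-dimensional Gaussian whose correlation matrix is
assembled by pair class and whose marginals are scaled to SUVR units;
draws are floored at 0.05 to keep the matrix positive.

Default structure (correlation before attenuation):

| pair class                               | r    |
|------------------------------------------|------|
| left–right homologues                    | 0.85 |
| same lobe, same hemisphere               | 0.50 |
| same lobe, opposite hemispheres          | 0.45 |
| different lobes (background)             | 0.15 |

Homotopic coupling is the strongest feature of real metabolic covariance,
hence the 0.85 homologue level; within-lobe coupling exceeds the
between-lobe background. The same-lobe cross-hemisphere level must sit
near the ipsilateral within-lobe level: leaving it at the background while
homologues are strongly coupled makes the assembled matrix badly
indefinite. With the defaults above the matrix is positive semi-definite
outright. When a custom profile is not, it is repaired by eigenvalue
clipping (negative eigenvalues raised to a small floor, then rescaled to
unit diagonal); generation aborts if the repair moves any entry by more
than `psd_tolerance` (default 0.05), and `projection_deviation` exposes
the audit value.

Disease stage is modelled as a global multiplier on all off-diagonal
correlations — attenuation 1.00 / 0.92 / 0.80 / 0.65 for NC / sMCI / pMCI
/ AD — so later stages have stochastically weaker networks at any shared
threshold. Two stage-specific touches: the sMCI profile boosts the
temporal–occipital background to 0.30 and suppresses parietal–occipital to
0.08 (the compensatory-rewiring pattern described for early impairment),
and the AD profile lowers regional means by 8% in parietal and temporal
regions so the group-comparison t-test stage has a hypometabolic signal to
detect. Marginals default to mean 1.0, SD 0.12 — a typical SUVR scale;
only correlations, not means, drive the network stages.

Each group's stream is spawned from the master seed via `SeedSequence`, so
one integer reproduces the full cohort byte-for-byte.

**What the generator does not emulate.** Real SUVR distributions are
mildly skewed, spatially autocorrelated beyond lobe blocks, and affected
by scanner site, partial-volume effects and registration error; group
covariance differences in patients are regional rewiring, not a uniform
attenuation. Passing tests therefore demonstrate that the pipeline
recovers planted covariance structure under clean conditions, not that any
particular clinical finding replicates; published node/edge counts from
restricted clinical cohorts are emitted in the same table formats for
users who can run the pipeline on such data, but are not reproduced by
simulation.

## Group comparison

Per region, a two-sample t-test between two groups; pooled-variance by
default (the classic reporting convention for this analysis family), Welch
via `variant="welch"`. Tests are two-sided with the direction of the mean
difference reported separately. Default alpha 0.01 with no multiplicity
correction; Bonferroni and Benjamini–Hochberg are available via
`correction=`. A region with zero variance in both groups has no defined
t-statistic; it is flagged `degenerate` and never reported significant.

## Numerical choices

- Pearson matrices come from `numpy.corrcoef`, symmetrized and clipped to
  [−1, 1] to remove rounding residue; the unit diagonal is set exactly.
  The test suite checks the result against a per-pair
  definition-of-covariance implementation at 1e−12.
- Zero-variance regions make the correlation undefined; the offending
  region names are raised, never silently NaN-filled.
- Matrices are serialized at 17 significant digits and re-read with
  round-trip float parsing, so write→read is bit-exact.
- Ratio tables mark zero-denominator cells `undefined` rather than
  infinity, since sparse groups can have empty lobe-pair bins.
- Grid thresholds are generated from integer multiples of 0.02 and
  rounded, avoiding accumulation error along the grid.

## Verification problem sizes

The shipped checks run the full pipeline at the study's group sizes.
Calibration quantities use: 200 random toy instances (≤ 10 regions, ≤ 30
subjects) for oracle equivalence; 50 random matrices for threshold
monotonicity; 200 null replicates (n = 45 vs 55, 90 regions) for t-test
type-I calibration, generated with an identity target correlation so the
binomial reference interval is exact; 20 cohorts for stage-ordering
recovery; and n = 2000 for planted-correlation recovery, where each
planted correlation value is estimated by averaging sample r over the
pairs sharing it (a single pair's sample correlation has an sd of ≈ 0.022
at n = 2000, so per-pair agreement tighter than that is not a meaningful
requirement).

## Known limitations

- Group-level networks only; no subject-level or longitudinal modelling.
- No graph metrics beyond node/edge/degree counts (no small-world indices,
  clustering or path length), no sparse inverse covariance or multivariate
  decomposition alternatives, and no permutation testing between group
  networks.
- The lobe table is a convention; analyses keyed on lobe pairs inherit it.
- Only the 90-region AAL parcellation is packaged; other bilateral,
  perfectly homologue-matched parcellations can be supplied as tables.
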