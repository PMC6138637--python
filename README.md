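# metaconn

Group-level **metabolic covariance networks** from regional FDG-PET SUVR
tables on the 90-region AAL parcellation.

In Alzheimer's disease research, regional glucose metabolism (FDG-PET) is
summarized per anatomical region as a standardized uptake value ratio
(SUVR, region mean SUV divided by whole-cerebellum mean SUV). Across the
subjects of a diagnostic group, pairs of regions whose SUVR values co-vary
are interpreted as metabolically connected. `metaconn` builds and compares
these networks for the four stages of the disease continuum — normal
controls (NC), stable MCI (sMCI), progressive MCI (pMCI), and AD — to
quantify how inter- and intra-hemispheric connectivity degrades with
disease stage.

The pipeline:

1. **SUVR matrix** — per group, an M×N data matrix (M subjects, N = 90 AAL
   regions), computed from raw SUV tables with the whole cerebellum as
   reference, or loaded directly.
2. **Correlation** — the N×N interregional Pearson matrix
   r_ij = corr(SUVR_i, SUVR_j) across subjects, plus the 45×45
   left-vs-right submatrix with homologue pairs on its diagonal.
3. **Binarization** — edge ⇔ r_ij ≥ τ, over the threshold grid
   τ ∈ {0.50, 0.52, …, 0.90} (21 values).
4. **Threshold selection** — the working τ is the *largest* grid value at
   which the NC network still contains all 90 nodes (degree ≥ 1); that
   single τ is applied to every group so counts are comparable.
5. **Edge accounting** — edges partitioned into intra-left, intra-right and
   inter-hemispheric classes, and by unordered lobe-category pair
   (frontal, temporal, parietal, occipital, subcortical, hippocampus,
   other), with cross-group ratio tables.
6. **Group comparison** — per-region two-sample t-tests (pooled or Welch,
   optional Bonferroni/Benjamini–Hochberg correction) between stage pairs.

Real PET cohorts of this kind are access-restricted, so the package ships a
synthetic cohort generator: multivariate-normal SUVR matrices with planted
block correlation structure (strong left–right homologue coupling,
within-lobe > between-lobe coupling) and stage-dependent attenuation of all
correlations, at the standard group sizes (100 NC / 45 sMCI / 55 pMCI /
100 AD). See `docs/methods.md` for the model and its limitations.

## Worked example

```sh
$ metaconn report --synthetic --seed 1 --out run1
selected tau: 0.76 (auto)
NC: nodes=90 edges=45
sMCI: nodes=48 edges=24
pMCI: nodes=6 edges=3
AD: nodes=0 edges=0
outputs + manifest in run1
```

The auto-selected threshold 0.76 is the highest grid value at which every
NC region keeps at least one edge. At that shared τ the simulated stages
lose nodes and edges monotonically (NC → sMCI → pMCI → AD), the planted
signature of progressive network breakdown. `run1/` then contains, per
group: the full and inter-hemispheric correlation matrices, edge lists,
BrainNet Viewer `.node`/`.edge` files, the t-test tables for the four
stage contrasts, the group summary (`summary_groups.csv`, below), lobe-pair
edge counts and ratios, and `manifest.json` with checksums of every output.

```
group,n_subjects,threshold,nodes,...,intra_edges,inter_edges,total_edges
NC,100,0.76,90,...,0,45,45
sMCI,45,0.76,48,...,0,24,24
pMCI,55,0.76,6,...,0,3,3
AD,100,0.76,0,...,0,0,0
```

The same analysis runs on real data by passing per-group tables
(`--nc FILE --smci FILE --pmci FILE --ad FILE`; CSV/TSV, one subject-id
column plus one column per AAL label, optionally a `Cerebellum_Reference`
SUV column). The library API (`metaconn.connectivity_report`,
`metaconn.group_ttest`, …) exposes every stage individually.

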