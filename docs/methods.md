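# Methods

This note documents the models, procedures, parameter choices and known
limitations behind `metapaseflow`. It is written for an analyst who wants
to know exactly what each number means and which design choices were open.

## Analysis model

### Input model and identification filtering

The pipeline's raw input is a long-format precursor table: one row per
(precursor, run) with a linear-scale normalized intensity and q-values at
both the precursor and protein-group level. Zero and empty intensity cells
both decode to *missing*: the downstream complete-case filters treat
"unquantified" and "absent" identically, so a zero carries no extra
information. Protein groups are opaque strings and are the quantification
unit — no razor-peptide re-inference is attempted, because the search
engine's grouping is consumed as given.

Filtering keeps rows with `precursor_q < 0.01` **and** `protein_group_q <
0.01`, strictly. The strict inequality matters only for rows exactly at
the threshold, but it is part of the contract and tested.

### Normalization

All normalization arithmetic is in log2; public matrices stay linear.

*Median normalization* shifts each run so its log2 median equals the mean
of all runs' pre-normalization medians, removing per-run loading/depth
differences.

*Quantile batch correction* maps each run's observed log2 values by rank
onto a reference distribution — the mean of order statistics across all
runs, computed on complete features. A run with a different number of
observed values is mapped by linear interpolation of the reference
quantiles; ties receive the average of their mapped values; missing values
stay missing. This choice exactly removes location–scale batch artifacts
(a planted pure location shift is removed to < 1e-9, which is asserted).
The correction function of batch-correction toolkits is not uniquely
defined ("quantile" can mean several related maps); reference-based
per-run quantile normalization was chosen because it makes runs comparable
across batches with a single, testable definition. A consequence worth
knowing: like every full-distribution normalization, it slightly attenuates
real fold changes carried by a non-negligible fraction of features (see
*Recovery experiment* below).

### MaxLFQ

For each feature (peptide = stripped sequence, or protein group), the
pairwise ratio between runs *j* and *k* is the median of log2 ratios over
precursors quantified in both, kept when at least `min_ratio_count`
(default 1) precursors are shared. Per-run log2 abundances minimize
Σ(b_k − b_j − r_jk)² over the ratio graph, solved independently per
connected component with a minimum-norm least-squares solve; each
component is then anchored so that the sum of its linear-scale estimates
equals the sum of the feature's raw precursor intensities over those runs
(sum preservation). Runs with no quantified precursor stay missing; an
isolated quantified run forms its own component and keeps its raw sum. On
every complete-data instance with ≤ 4 runs and ≤ 5 precursors the solution
agrees with an explicit normal-equations oracle to < 1e-8 relative.

### Taxon-level quantification

Per rank (superkingdom … species), in order:

1. drop peptides blank at the rank — the lineage table is an LCA product,
   so a blank means "not specific to any taxon at this rank";
2. keep taxa with ≥ `min_unique_peptides` (default 3) distinct sequences;
3. drop peptides not quantified in every run of the analysis scope;
4. re-apply the threshold (a taxon may fall below it after step 3 — the
   conservative order guarantees no taxon is ever reported from fewer
   peptides than the threshold);
5. taxon value per run = Σ log2(intensity) over its peptides.

The analysis scope is the run set of the matrix passed in; differential
matrices are built per condition, so "quantified in all samples" means all
samples of that condition's Pre/14D comparison. A `per_condition` mode
evaluates completeness within each condition of a combined matrix, letting
a peptide contribute to the conditions where it is complete; a taxon is
then retained only where it keeps the threshold in every condition so the
output stays complete-case. Host-lineage peptides are excluded from
microbial taxon matrices by default (the `origin` column carries the
distinction; host proteins are analyzed separately).

The summed-log2 scale means a planted per-peptide log2 fold change Δ
appears as (#peptides)·Δ at the taxon level; the per-peptide estimate used
in validation divides by the peptide count.

### Paired differential testing

For subject *i*, d_i = value(i, 14D) − value(i, Pre); t = mean(d)/(sd(d)/√n)
with df = n−1 and a two-sided p. Degenerate sd(d)=0: p = 1 when mean(d)=0,
else the smallest positive float with a `degenerate` flag — this keeps NaNs
out of the FDR step while preserving ranking. BH q-values are step-up
(`q_(i) = min_{j≥i} min(1, p_(j)·n/j)`), computed within one call (one rank
× one condition); NaN p-values propagate and are excluded from n.

The moderated variant shrinks per-feature variances toward a prior:
`s̃² = (d₀s₀² + d·s²)/(d₀+d)`, moderated t uses s̃ with df d+d₀. The prior
(d₀, s₀²) is fitted by method of moments to the scaled-F model
`s² ~ s₀²·F(d, d₀)` using the mean and squared CV of the observed
variances; when the observed spread is at or below the pure-sampling floor
(CV²·d ≤ 2) the prior is infinitely informative and all variances shrink
to their common mean — in that limit the moderated t equals the ordinary t
with (much) larger df, and with d₀ = 0 the ordinary test is recovered
exactly; both limits are asserted numerically. If d₀ ≤ 2 the mean relation
of the F distribution is ill-posed and s₀² falls back to the mean variance
(a crude but explicit approximation for extremely heavy-tailed variance
spreads).

### Pathway-level quantification

Proteins significant at raw p < 0.005 (strict; the prefilter uses raw, not
adjusted, p) in the paired protein test and carrying at least one K number
are kept. Linear intensities of significant proteins sharing a K number
are summed into one K-level intensity per run (missing when none is
quantified). Each K fans out to *all* of its pathways. Per (pathway, run):
value = log2(Σ observed member-K intensities / #observed member Ks) — the
denominator counts only K numbers quantified in that run, making the
statistic a per-run mean over observed members (the only reading under
which a per-sample count is non-redundant). Pathway values are tested with
the moderated paired t by default and BH within the call; significance
bands at q < 0.05 and q < 0.01 are reported.

Because the per-run mean passes a uniform fold through log2 unchanged, a
planted fold change applied to all of a pathway's proteins is recovered
exactly in the noise-free limit — asserted to 1e-9.

### Replicate-quality metrics

Completeness = fraction of runs quantified per feature. Overlap between
run identification sets is Jaccard (default) or intersection over the
smaller set — the normalization used in published overlap figures is often
unstated, so both are provided and neither claimed canonical. Pearson
correlations are computed on log2 intensities over mutually quantified
features (≥ 3 shared required, else NaN). CV = sd/mean per feature on the
**linear** scale (a CV of log values is not a CV), sample sd with n−1 as
conventional for technical replicates; the summary fraction uses the
CV < 0.2 threshold customary in workflow comparisons.

## Synthetic data generator

The generator emulates the paired mouse study the pipeline targets: three
conditions (Naive, SHAM, SNI) × four subjects × two timepoints (Pre, 14D),
24 runs in two batches (a subject's two samples share a batch, as one
acquisition block — so batch effects cancel in paired differences by
design).

Peptide log2 intensity = species baseline N(20, 2²) + protein offset
N(0, 1) + peptide ionization offset N(0, 1.5²) + subject intercept
N(0, 0.3²) + per-run depth N(0, 0.2²) + per-batch shift N(0, 0.3²) +
planted effect + noise N(0, σ²), then exponentiated. σ is derived from the
technical peptide CV (default 0.2, the same value the field uses as a
quality threshold — the deposited study reports no dispersion estimates,
so defaults are chosen for realism, not claimed to match any dataset):
σ_log2 = √ln(1+CV²)/ln 2 ≈ 0.29.

The default community has 40 species in a deterministic 8-rank hierarchy
(4 phyla … 20 genera), 8 proteins per species and 6 peptides per protein
(~1,990 microbial peptides; real gut metaproteomes identify tens of
thousands of peptides over hundreds of proteins per abundant species — the
ratio of peptides per species matters for taxon-level power, so the
simulation keeps it realistically high while staying desk-scale), plus a
single host (Metazoa) branch of 10 proteins with `origin="host"` and no K
numbers. A configurable fraction of peptide lineages (35% by default) is
blanked below phylum…genus to emulate LCA ambiguity. 60 K numbers map to
15 pathways, ~30% of Ks serving two pathways (the one-to-many fan-out is
essential and exercised). q-values are U(0, 0.009) for genuine precursors;
a 5% decoy fraction draws U(0.01, 0.5) and is removed by the q < 0.01
filter. Missingness is applied last: DIA-like = uniform 2% dropout;
DDA-like = logistic in log2 intensity (midpoint 17, slope 1.2), giving
intensity-dependent dropout that stochastically dominates the DIA setting,
as the acquisition-mode comparison requires. Everything is a deterministic
function of (config, seed).

Planted taxon effects shift every peptide of the taxon's species in the
chosen condition's 14D runs only; planted pathway effects shift every
protein annotated to any member K, so both the prefilter and the
aggregation see the signal. Planted references are validated against the
generated annotation structure before any sampling.

What the generator does **not** emulate: realistic peptide sequences or
digestion, retention time/ion mobility, correlated missingness between
peptides of one protein, compositional effects, overdispersed or
heavy-tailed noise, multi-protein groups, and shared peptides between
species. Passing tests therefore demonstrate correctness and calibration
under a well-specified generative model, not performance on any real
dataset.

## Validation experiment design

*Null calibration*: 50 simulations with no planted effects under default
conditions; full pipeline; raw p-values pooled over all three conditions
(~6,000 species-level taxa and ~2,250 pathways). Both families and their
pool must reject at α = 0.05 within 3 binomial SEs. The pathway test is
calibrated with the p < 0.005 prefilter disabled: under a global null the
prefilter passes ~0.5% of proteins and would starve the test rather than
calibrate it.

*Recovery experiment*: a +1.0 per-peptide log2 fold on one species in SNI,
50 simulations, full pipeline, species-rank testing within SNI. Reported:
the mean per-peptide estimate (bias ≈ −0.02) and the fraction of
simulations where the planted species clears q < 0.05 (≈ 0.9). The
experiment uses an 80-species community so the planted species carries
~1% of total signal, as a single species does in a real gut metaproteome;
at a much smaller scale the run-level normalizations visibly consume part
of a fold change carried by several percent of all features — an artifact
of simulation size, not of the method, and the reason the community size
is the one generator parameter the recovery experiment overrides.

*Noise-free pathway recovery*: all noise off; the planted pathway's mean
difference equals the planted value to machine precision.

*Determinism*: the full pipeline run twice from one seed must produce
byte-identical output trees; all text outputs use shortest round-trip
float formatting and sorted JSON keys to make this hold.

Problem sizes (50 seeds, ~2,000 peptides/simulation) were chosen so each
Monte-Carlo experiment completes in a few minutes on one core while
keeping ≥ 2,000 pooled null features.

## Numerical choices and degenerate inputs

- Least-squares solves use minimum-norm `lstsq` (gauge-fixed by the
  component anchor); the per-component anchor conserves the raw intensity
  sum to < 1e-9 relative.
- Quantile mapping uses a stable mergesort for rank assignment and
  averages tied values, making results invariant to row order.
- Lineage tables violating blank-consistency are repaired by truncation
  below the first blank, with a logged warning (third-party exports are
  not always consistent); empty annotation tables yield empty results, not
  errors.
- An empty q-filter result, a pathway with no significant K-carrying
  protein, and an overlap computation on an empty identification set all
  degrade to empty/zero outputs with warnings rather than exceptions.
- FASTA reduction treats the first whitespace-delimited header token as
  the accession and preserves duplicate accessions (with a warning) —
  their provenance is upstream of this package.

## Known limitations

- The moderated test's method-of-moments prior is less robust than a
  profile-likelihood fit when very few features are tested (< ~10); with
  the default pathway counts this is visible only as slight q-value
  conservatism.
- `per_condition` complete-case mode requires a taxon to pass the peptide
  threshold in every condition present, which is stricter than analyzing
  each condition separately.
- Quantile batch correction attenuates fold changes carried by a
  non-negligible fraction of features (see above); with realistically many
  features the attenuation is ~1–2% of the effect.
- Pathway aggregation treats K-number intensities as exchangeable;
  abundance differences between member orthologs are averaged away by
  construction.
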