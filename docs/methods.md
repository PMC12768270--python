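# Methods

This note documents the models, parameter choices and numerical decisions
behind `gutmap`, and what the synthetic benchmarks do and do not establish
about real data.

## Synthetic data model

The generator emulates a comparative adult-gut study design: S species
(default 5), each with 6–10 ordered AP segments (default 10, 8, 6, 7, 9)
and 3 replicates, profiled as bulk RNA-seq counts, with orthology linking
one primary gene per species per orthogroup.

**Archetypes.** Each orthogroup receives exactly one expression archetype,
shared across species:

- *block* — high plateau strictly anterior to the planted compartment
  boundary, then a steep logistic drop to the trough (5% of peak). Default
  15% of orthogroups.
- *gradient* — flat at the trough anterior to the boundary, then a monotone
  linear ramp across the posterior segments (ascending or descending,
  drawn once per gene and conserved). Default 15%.
- *module:k* — Gaussian bump at the module's relative AP center with
  relative width 0.15, i.e. spanning roughly 2–4 adjacent segments — the
  spatial extent of a multi-segment expression domain. The per-species
  center is jittered by the module's conservation jitter (relative sd,
  default 0.03), which is the knob controlling how "conserved" a module's
  position is. Five default modules sit at relative positions 0.05, 0.30,
  0.55, 0.75, 0.95 with 40 genes each.
- *terminal* — bumps at the first and/or last segment; each species
  independently draws anterior / posterior / both, so a terminal gene can
  mark opposite ends in different species.
- *null* — flat; all remaining orthogroups.

**Noise.** Counts are negative binomial with Var = μ + φμ²; gene-wise
dispersion φ is log-normal (median 0.05, log-sd 0.5, typical of bulk
RNA-seq). Means are the archetype shape times a gene-wise log-normal
baseline (median 200 counts, log-sd 1). Per-sample library sizes are
log-normal (sd 0.15), and each replicate carries a multiplicative batch
factor (log-sd 0.10) — giving the batch-removal stage real signal to
remove. The boundary sits at 40% of the tube (first posterior segment =
round(0.4·n), clipped to keep both compartments ≥ 2 segments).

**Sequences.** Each orthogroup descends from a random length-300 protein;
each species' primary orthologue mutates 10% of sites, and orthogroups
selected at `paralog_rate` (default 0.2) gain an extra paralog in one
random species mutated at 10% + 30%. Extra paralogs carry sequence but no
expression — they model gut-silent duplicates — so a mis-resolved
orthogroup shows up as dropout from the integrated matrix rather than as a
wrong profile.

**What the generator does not emulate:** read-level artifacts (mapping
bias, multi-mapping, gene length), correlated gene–gene noise,
composition effects in library normalization, lineage structure among
species, and partial gene loss. Passing the planted-truth benchmarks shows
the algorithms recover the planted structure under count noise, batch
effects and paralogy — not that they are robust to everything real data
can do.

## Preprocessing

Filtering keeps genes with ≥ 10 raw counts in at least as many samples as
there are replicates. Normalization is log₂(CPM+1); a sqrt(CPM)
alternative is available where a flatter mean–variance relationship is
wanted. Downstream analyses use rank correlations and z-scores, which are
insensitive to the exact monotone variance stabilizer, so no
dispersion-model-based transform is attempted.

Batch removal fits, per gene, value ~ intercept + segment + batch with
sum-to-zero-coded batch indicators, and subtracts the batch term —
exactly removing planted additive offsets while preserving segment effects
and gene means, and raising an error when batch is confounded with
segment. Replicates are collapsed to per-segment means after batch removal
(collapse point is a package choice; per-segment display columns are the
downstream unit). Row z-scores use sample sd (ddof = 1, configurable);
constant rows become zero and are flagged.

## R2E seriation

Effective rank counts eigenvalues above exp(−13) ≈ 2.26e−6 (the literal
natural-exponent reading; 1e−13 is available via the `threshold` argument
for callers who prefer a decimal cutoff). Iteration stops at rank ≤ 2 — not
== 2 — to pass through degenerate inputs; a constant row arising at any
iteration is an error naming the item. On banded synthetic data a handful
of iterations suffices (the suite asserts ≤ 10; observed ≤ 4–6).

The ellipse order uses the first two columns of U from SVD, unscaled:
scaling by singular values changes the ellipse's eccentricity but not the
angular order. The series starts immediately after the largest circular
gap between sorted angles. Direction is the one reproducibility decision an
interactive tool leaves open; here it is fixed by (a) an anchor item that
must land in the first half, else (b) the orientation whose first item id
is lexicographically smaller than its last.

Seriation-guided clustering merges only adjacent blocks along the order
(average linkage on 1 − correlation), so modules are contiguous by
construction.

## Compartment boundary

For each candidate boundary b (1-based rank of the first posterior
segment), the score is the mean within-compartment Spearman correlation
(off-diagonal pairs pooled over both compartments) minus the mean
cross-compartment correlation; the boundary is the argmax, ties to the
smallest b. Pooling both compartments — rather than scoring the anterior
side alone — makes the score exactly symmetric under reversal of the
segment order, a property the test suite enforces (boundary maps to
n − b + 2, labels swap), and provably maximal at the true split for
two-block equicorrelated data.

Compartment labels come from the decay fit rho(i,j) ≈ α − β·|i−j| within
each compartment: *block* if the 95% CI for β covers 0 or β < 0.02 per
segment, else *gradient*. Both the CI level and β_min are configurable;
the threshold is a package construction, since "graded" is qualitative in
the underlying biology.

## Orthology resolution

Smith–Waterman local alignment uses BLOSUM62 with gap opening 2 and
extension 0.1 under the convention that a gap of length L costs
2 + 0.1·L (implemented via Biopython's PairwiseAligner with
open_gap_score = −2.1, extend_gap_score = −0.1, and cross-checked against
an independent Gotoh DP in the tests). Raw local scores grow with
sequence length, so similarities are normalized by the geometric mean of
the two self-alignment scores; within an orthogroup this preserves the
ranking that resolution needs while making provenance scores comparable
across orthogroups (`normalize=False` recovers raw scores).

"Unbalanced representation" for the 80-gene soft filter is
operationalized as max / min-nonzero per-species gene count > 3.0
(configurable). The best ancestral orthologue maximizes mean similarity
to all *other* species' members; ties break lexicographically, and the
margin to the runner-up is recorded but not enforced.

## AP association and terminal markers

The trend test is OLS on an orthonormal polynomial basis of AP rank
(degree 3, reduced to n − 2 when a species has few segments) with an exact
F-test against the intercept-only model. It is deterministic,
parameter-light, affine-invariant in the profile, and exactly calibrated
under the null (the suite checks type-I error at 5% over 2000 null
profiles).

Power accounting matters here: with only 6–10 collapsed segment means and
a 3-df alternative, the critical F is large (F₀.₀₅(3,4) ≈ 6.6), so
single-profile power at strong noise is intrinsically modest. The
smooth-trend approaches this test stands in for are fitted on sample-level
observations, and the test accepts repeated AP ranks for exactly that use;
the quoted ≥ 80% power at noise sd 0.5 holds for replicate-resolved fits
(8 segments × 3 replicates). On collapsed integrated matrices the screen
compensates through the intersection rule: conserved = BH q < 0.05 within
species, in all species (an "at least m of S" relaxation is available).

Terminal classification uses the fitted profile: anterior/posterior if the
primary peak falls in the first/last tercile of ranks; *both* if a
secondary local maximum in the opposite tercile reaches ≥ 50% of the
primary amplitude above the profile mean (ratio configurable); else
internal. The cross-species terminal flag requires every species terminal
but not all pinned to the same single end.

## Module extraction and auto-k

Genes in the conserved set are correlated (Spearman, all species' segments
pooled, no species weighting), R2E-seriated, and cut into k contiguous
blocks. For automatic k, a contrast of within-module vs
between-adjacent-module correlation is unusable: distant modules are
*anticorrelated* after within-species z-scoring, so such contrasts are
maximized by coarse 2-way splits regardless of the true module count
(silhouette and merge-cost elbows fail the same way). Instead, k is chosen
as the BIC-optimal component count of a 1-D Gaussian mixture over pooled
per-gene AP peak positions — matching the definition of a module as a
positional cluster along the axis. Peaks are moving-average smoothed
(window 3) and refined by parabolic interpolation around the argmax;
without interpolation the 6–10-segment grid quantizes peak positions and
the mixture overfits the quantization. The partition itself remains
seriation-guided contiguous clustering; modules are reported
anterior→posterior.

Module placement maps each module's per-species peak segment to that
species' compartment and flags species whose compartment deviates from
the cross-species majority — the anteriorisation/shift calls.

## Sparse PLS-DA

The weight vector per component is the first left singular vector of
X_c Y_c (features × classes covariance), hard-thresholded to the top
`keepX` absolute entries and renormalized — keepX-style sparsity with sign
retention; X is deflated by regression on the component scores, making
score vectors orthogonal. In the unpenalized 2-class, 1-component limit
the direction equals the class-mean difference, which the tests verify
against the closed form. Cross-validation folds are species
(leave-one-species-out) because samples within a species share
preprocessing and are not exchangeable; with one species a seeded
stratified k-fold is used with a warning. The optimal sufficient set is
the smallest keepX within 0.02 balanced error of the grid minimum.

The pipeline's default grouping for marker discovery labels each
(species, segment) column by its compartment call; arbitrary imputed
groupings are supplied as a TSV.

## Determinism and problem sizes

A single seed drives three derived substreams (profiles, counts,
sequences); the run report contains content hashes of every artifact and
no timestamps, so identical config + seed gives byte-identical reports.
Benchmarks use deliberately compact sizes — 3 species × 8 segments,
200–300 orthogroups, 100–120-residue proteins for resolution tests
(300 residues where alignment accuracy is itself under test), 20–100
simulation replicates per claim — chosen to make the full suite and the
acceptance script comfortably reproducible on a laptop while keeping every
statistical check adequately powered.

## Known limitations

- The boundary search is strictly bipartite; tripartite or finer
  segmentations are out of scope.
- Orthology inference itself (and domain-based TF discovery) is consumed,
  not performed; TF flags enter as input and are only expanded to
  orthogroup level.
- The polynomial trend test is not a penalized spline GAM; with many
  segments and sharp profiles a spline with smoothness selection would be
  more flexible.
- Auto-k assumes modules are unimodal in AP position; overlapping or
  multimodal "modules" will be split or merged and should be inspected via
  the deviation flags and the seriation order.
- Sequence simulation uses i.i.d. substitutions without indels; alignment
  scoring is exercised on indel-bearing pairs only in the DP cross-checks.
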