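# gutmap

Comparative transcriptomics of the adult bilaterian gut's anteroposterior
(AP) organization.

Adult guts of distantly related bilaterians — fish, amphioxus, acorn worm,
sea urchin, annelid — can be dissected into an ordered series of segments
along the mouth-to-anus axis and profiled by bulk RNA-seq. `gutmap`
implements the comparative pipeline that turns such per-species segment ×
replicate count tables, plus an orthology table and proteomes, into:

1. **Compartments** — each species' gut splits into an anterior **block**
   (segments with uniformly high mutual transcriptome correlation) and a
   posterior **gradient** (correlation decaying with AP distance), separated
   by a boundary that anatomically corresponds to a transition sphincter.
2. **Conserved AP modules** — groups of orthologous genes whose expression
   peaks at matching relative AP positions in every species.
3. **Terminal markers** — genes peaking at a gut terminus, anterior in some
   species, posterior or both ends in others.
4. **Sparse discriminant marker sets** — minimal gene panels separating
   imputed segment-identity groups, via sparse PLS-DA.

The package is exercised end-to-end on a synthetic multi-species generator
with fully planted ground truth, so every stage is testable without any
download.

## The methods at the core

**R2E (Rank-2 Elliptical) seriation.** Given items with expression profiles,
compute the Pearson correlation matrix R⁰ between items, then iterate
Rᵏ⁺¹ = corr(rows of Rᵏ) until the effective rank (eigenvalues > e⁻¹³)
drops to 2. The left singular vectors of that matrix lie on an ellipse;
sorting items by their angle θᵢ = atan2(Uᵢ₂, Uᵢ₁) and cutting the circle at
the largest angular gap yields a linear order that solves the Robinson
seriation problem (similarity decaying monotonically away from the
diagonal). Direction is fixed by an anchor item or a deterministic
lexicographic rule, so runs are reproducible.

**Cross-species integration.** Per species: genes with < 10 counts in fewer
samples than there are replicates are dropped; counts become log₂(CPM+1);
replicate batch effects are removed by linear residualization (keeping
segment effects); replicates are averaged per segment; rows are z-scored
((x − mean)/sd within species). Orthogroups (OrthoFinder `Orthogroups.tsv`
dialect) larger than 120 genes — or larger than 80 with unbalanced
per-species representation — are discarded; 1-to-many orthology is resolved
to a **best ancestral orthologue**: the paralog with the highest mean
Smith–Waterman similarity (BLOSUM62, gap open 2, extend 0.1) to all other
species' members. Rows of the integrated matrix are orthogroups expressed
in every species; columns concatenate all species' segments.

**AP-association screen.** Per orthogroup and species, an orthogonal
polynomial (degree 3) of AP rank is fitted by OLS and tested against the
flat model with an exact F-test; Benjamini–Hochberg q-values are computed
within species, and orthogroups with q < 0.05 in *all* species form the
conserved AP-associated set.

**sPLS-DA.** Components w maximize cov(Xᵀw, Y) for one-hot class labels Y,
hard-thresholded to the top-`keepX` weights per component with deflation
between components; classification is by nearest centroid in score space,
and the optimal sufficient marker set is the smallest `keepX` whose
leave-one-species-out balanced CV error is within tolerance of the minimum.

## Worked example

Write a demo config and run the full pipeline (simulation → preprocessing →
integration → compartments → AP screen → modules → markers):

```yaml
# demo.yaml
seed: 42
outdir: run
simulate:
  n_species: 3
  segments_per_species: [8, 8, 8]
  replicates: 3
  n_orthogroups: 250
  module_spec:
    - [M1, 0.05, 0.15, 12, 0.03]   # id, AP center, width, n genes, jitter
    - [M2, 0.30, 0.15, 12, 0.03]
    - [M3, 0.55, 0.15, 12, 0.03]
    - [M4, 0.75, 0.15, 12, 0.03]
    - [M5, 0.95, 0.15, 12, 0.03]
  paralog_rate: 0.15
  seq_len: 100
markers:
  ncomp: 2
  keepx_grid: [5, 10, 25]
  tolerance: 0.02
  groups: compartment
```

```bash
gutmap run --config demo.yaml
```

prints (abridged):

```json
{
 "boundaries": {"sp1": 4, "sp2": 4, "sp3": 4},
 "conserved_size": 80,
 "modules_k": 8,
 "truth_metrics": {
  "boundary_mean_abs_error": 0.0,
  "conserved_null_rate": 0.0,
  "conserved_recall": 0.7796610169491526,
  "marker_signal_fraction": 0.8,
  "module_ari": 1.0,
  "terminal_recall": 0.8333333333333334
 }
}
```

Reading this: in all three simulated species the block/gradient boundary
was placed at segment 4, exactly where the generator planted it
(`boundary_mean_abs_error` 0.0). 80 orthogroups were AP-associated in every
species; 78% of the planted module genes were recovered among them while no
planted null gene leaked in. On the planted module genes the recovered
partition agrees perfectly with the planted membership (`module_ari` 1.0);
`modules_k` is 8 because the conserved set also contains planted block,
gradient and terminal genes, which occupy their own AP positions. 8 of the
10 discriminant markers chosen for the anterior/posterior split are planted
signal genes.

Individual stages are also exposed (`gutmap simulate`, `gutmap preprocess`,
`gutmap seriate`, `gutmap compartments`), and everything is importable as a
library (`gutmap.seriate.seriate`, `gutmap.discriminant.fit_splsda`, ...).

## Layout

```
src/gutmap/
  synthetic.py      multi-species generator with planted truth
  dataset.py        ExpressionDataset container + stage tags
  preprocess.py     filter / CPM / batch removal / collapse / z-score
  seriate.py        R2E seriation, constrained clustering, GAP bundles
  ortho.py          Orthogroups.tsv, similarity, resolution, integration
  compartments.py   block/gradient boundary detection
  apassoc.py        AP trend test, conserved screen, terminal markers
  modules_ap.py     module extraction and placement
  discriminant.py   sparse PLS-DA and keepX selection
  pipeline.py       end-to-end orchestration + run report
  cli.py            command-line interface
docs/methods.md     model and design notes
tests/              pytest suite (unit, property, acceptance)
```
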