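# Methods

`mlmescan` implements a digital-phenotyping pipeline for single-cell
expression data of preimplantation embryos: it identifies cells that
co-express markers of all three blastocyst lineages together with the core
pluripotency regulators (multi-lineage-markers-expressing, MLME, cells),
quantifies how such cells concentrate among telomerase-positive (TERT+)
cells and among cells with high gene-signature correlation scores, and
estimates when during embryogenesis they emerge.

## Positivity calling

A gene is "positive" in a cell when its expression value **strictly
exceeds** a threshold. Two rules are supported:

- `fixed_threshold` (default 0): any detected signal counts, the convention
  for discovery-style (qPCR-like) data;
- `population_median`: each gene's threshold is its median over **all**
  cells of the supplied matrix, the convention for FPKM-like validation
  data. A value tied with the median is negative. The realised per-gene
  medians are stored on the returned call matrix for provenance.

With all-distinct values over 2m cells the median rule marks exactly m cells
positive — a property test enforces this.

## HPAT phenotype segregation

The positivity triple of the three primate-specific lincRNAs HPAT21, HPAT2
and HPAT15 assigns each blastocyst cell a phenotype: single-positive HPAT21
(TE-like), double-positive HPAT15 (PE-like), HPAT2-positive double or
triple (epiblast-like / MLME-resembling), the all-negative null phenotype,
or `other` for the remaining combinations. `other` is a label, not an
error: the discovery data contained no such cells, but external data may.

## The digital MLME rule

A cell carries the MLME phenotype iff for each lineage L in {EPI, TE, PE}
at least `min_markers_per_lineage` (default 4) of L's panel markers are
positive, **and** every master regulator (default NANOG, POU5F1, SOX2) is
positive. Master regulators are required positives regardless of panel
membership; they count toward a lineage tally only when listed in that
lineage's marker list. Marker panels are user configuration (YAML/JSON) —
no species-specific panel ships as ground truth.

## Hypergeometric enrichment and the tabulated convention

Enrichment of MLME cells within a subset of n cells drawn from a background
of N cells (K of them MLME) is quantified with the hypergeometric
distribution, computed as exact log-space sums of point probabilities.
Three statistics are exposed:

- `upper`: P(X >= k), the enrichment tail — the statistical default;
- `lower`: P(X <= k), depletion. It is evaluated as the upper tail of the
  complement subset (P(X <= k) = P(X' >= K - k) over the other N - n
  cells), so a subset's enrichment p and its complement's depletion p are
  the *same* floating-point computation and agree bit-for-bit — exactly the
  identity visible in published prevalence tables, where the TERT+ and
  TERT- rows print identical p-values;
- `point`: the point probability P(X = k). **This is the quantity the
  published prevalence tables actually tabulate as "P value".** Every
  printed value in those tables — including the mouse TERT+ row, 0.06008626
  — is reproduced to printed precision by the point probability and by no
  tail convention we tried (upper, lower, mid-p, Fisher, binomial, normal
  approximation). A point probability is not a tail test and should not be
  read as one; `mlmescan` defaults to the upper tail for inference and
  reserves `point` for reproducing the tables.

Score-rank bands ("top 3/5/10%") are defined by cell counts
ceiling(n · x), which reproduces the printed band sizes 25/41/82 of 819.
Percentages are half-up rounded to one decimal, matching table formatting.
Both Fisher's exact test (two-sided by point-probability summation, the
dominant convention) and the hypergeometric statistics are checked against
exhaustive exact-rational enumeration oracles for all configurations with
N <= 30.

## Ratio signatures and correlation scores

A signature is the per-gene log2 ratio of mean expression between two cell
populations, with pseudocount 1.0 (configurable) guarding zeros. A cell's
score is the Pearson correlation between its log2(value + pseudocount)
profile, centred across the signature genes, and the signature weights;
Spearman is available behind a flag. The correlation flavour and cell-side
transform are genuine design choices: with ratio-valued weights and cutoffs
near 0.5, Pearson on the log scale is the natural reading, and the
`transform="raw"` flag preserves the alternative. Scores are undefined
(flagged, not NaN-propagated) for zero-variance profiles. Cutoffs are
strict (> 0.5 by default, with 0.4 and 0.55 presets). Signature refinement
keeps genes whose expression differs between high- and low-scoring cells by
a two-sided Mann-Whitney rank-sum test at alpha = 0.05 (Welch's t behind a
flag) and re-derives the weights between those two groups.

`select_top_scoring` returns the smallest k such that the top-k cells by
score contain at least one cell from every required stage (ties and the
k-th boundary broken by lexicographic cell id), flagging the result when a
required stage has no scored cells.

## Cross-dataset consensus and transcript origin

Differential expression (log2 mean ratio + rank-sum p) is computed
independently in two datasets; the consensus keeps shared genes significant
in both at alpha (default 0.05, no multiple-testing correction by default,
Benjamini-Hochberg behind a flag) with the same effect sign. Maternal /
embryonic transcript-origin labels are consumed as an input annotation,
never inferred; origin fractions are reported over labelled genes with
unknown counts surfaced.

## Spectral gene filter

Heatmap preparation transforms FPKM piecewise — log2(x) for x > 2, x/2 for
x <= 2 — and adds uniform jitter in (0, 1e-5), drawn once per matrix under
a seed, to break ties. Filtering then iteratively removes the gene with the
smallest contribution to the variance captured by the leading eigenvectors
accounting for 95% of total variance (gene-gene covariance, cells as
observations, no gene scaling since the transform already compresses
dynamic range). Two quantities in this procedure are underdetermined by its
verbal description and are documented design choices here:

- "contribution" is formalised as the eigenvalue-weighted squared loadings
  over the 95%-variance components (so contributions sum to the captured
  variance); unweighted squared loadings are flag-selectable;
- "entropy of the dataset" is the Shannon entropy (natural log) of the
  covariance eigenvalue spectrum normalised to sum 1 — the only entropy
  intrinsic to the same eigen-analysis; it lies in [0, ln(rank)].

The loop halts when a removal would change the entropy by at least the
threshold (10% default, 7% recommended for small datasets) relative to the
unfiltered matrix; the crossing gene is restored ("stop before exceeding").
Ties in contribution break to the lexicographically smallest gene id, so
removal order is deterministic given the matrix and jitter seed.

## Emergence timeline

If a fraction f of a stage's cells (pooled over embryos) carries the MLME
phenotype and an embryo at that stage comprises n cells, the probability
that an individual embryo contains at least one MLME cell is modelled as
p_emerge = 1 - (1 - f)^n, treating cells as independent (per-embryo
clustering is ignored; the estimator is a documented stand-in, as no closed
form is canonical for this quantity). f carries a 95% Wilson score
interval, clamped to exact 0/1 bounds at boundary counts.

## Synthetic data

The generator emulates the study conditions the pipeline targets and
nothing more: stage-structured embryos (E3-E7, 1,000 cells by default,
growing cells-per-embryo across stages), pre-lineage cells before E5 and
EPI/PE/TE-committed cells after, a planted MLME subpopulation (12% of cells
at every stage) expressing all three marker panels (12 markers each by
default) plus the master regulators, and TERT positivity at 0.66 for
planted MLME cells versus 0.51 otherwise (matching the ~54% TERT+ fraction
and its MLME skew in published counts). Expression is two-state
log-normal: "on" draws exp(N(3.0, 0.8)) (≈ 20 FPKM), "off" is an exact
zero with probability 0.95 and otherwise exp(N(-2.0, 0.5)). The zero
inflation of the off state is essential realism: real FPKM matrices are
mostly exact zeros for unexpressed genes, and without it the
population-median rule would mark roughly half the off-state cells positive
for any gene expressed in fewer than half the cells. Dropout (default 0.1)
zeroes on-state values last. Pre-lineage cells switch each marker on
independently with probability 0.2, giving the graded intermediate
co-expression that makes signature scoring non-trivial. A single global
seed drives everything, with per-stage sub-streams spawned deterministically
from it.

What the generator does **not** model: doublets, batch effects, library-size
variation, gene-gene correlation beyond the panel structure, aneuploidy, or
read-level noise. Passing recovery tests therefore show that the
implementation is faithful to its rules under clean two-state expression —
not that the rules themselves are robust on arbitrary real data.

## Problem sizes used in the test-suite and acceptance script

Simulation-based checks use 1,000 cells (recovery), 200 replicates of 1,000
cells (enrichment power/size), 100 random 10-gene x 20-cell matrices
(filter-oracle agreement) and 1,000 genes x 60 cells per dataset (consensus
recovery); exhaustive oracle comparisons cover every 2x2 table with N <= 30
and every hypergeometric configuration with N <= 30. These sizes give
binomial Monte-Carlo error well inside the asserted margins.

## Known limitations

- Positivity thresholds are global per matrix; no per-batch or per-embryo
  medians.
- The emergence model ignores within-embryo correlation of cell states
  (a beta-binomial flag is a natural extension, not implemented).
- Transcript-origin labels must be supplied; the package does not infer
  maternal/embryonic origin from expression dynamics.
- The spectral filter recomputes a full eigendecomposition per removal;
  fine for marker-panel-scale matrices, quadratic-cubic for genome-wide
  ones.
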