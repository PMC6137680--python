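# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Data model

All tables are tab-separated UTF-8 text with a header row. The central
containers are:

- `TransportNetwork` — a bipartite graph of transporter genes and
  (canonicalized) compound names. Each edge carries a *support* count:
  the number of distinct sources reporting that interaction. Compound
  FDA-approval flags and per-transporter family labels ride along.
- `OmicsBundle` — aligned cell-line × feature matrices: continuous
  expression on the RMA scale, binary alterations named `amp<GENE>` /
  `del<GENE>` / `var<GENE>`, a tissue label per line, and a gene → class
  map ({SLC, ABC, other}).
- `DrugResponseTable` — drug × cell-line AUC, oriented so larger = more
  resistant. Missing entries are allowed; a drug must have at least one
  measurement.

Cell lines present in only one matrix are dropped at load time with a
logged count; a line without a tissue annotation is kept as `"unknown"`
because tissue only enters one descriptive summary. Alignment is a strict
sorted intersection and is idempotent.

Networks serialize to GraphML and an edge-TSV losslessly (nodes, edges,
support, flags). SIF (`node<TAB>transports<TAB>node`) is also emitted for
graph viewers, but the format has no edge attributes, so support counts
read back from SIF as 1; lossless round-trips should use the other two
formats.

## Network curation and statistics

Raw edge tables (source, compound, transporter) are merged after resolving
compound aliases through a table-driven map (chains are followed; cycles
and empty canonical names are curation errors — canonicalization is
table-driven rather than a live compound-database call so runs are
reproducible offline). One edge survives per unique (transporter,
canonical compound); support = number of distinct sources.

Descriptive statistics: per-node degree tables (descending, ties
alphabetical); *exclusive substrates* of t (compounds whose entire
neighborhood is {t}); *exclusively shared* substrates of t₁,t₂
(neighborhood exactly {t₁,t₂}); *shared* substrates (plain intersection —
both readings of "share" are exposed because the looser one is what
pairwise substrate-overlap counts usually mean); the largest connected
component (ties broken by edge count, then lexicographically smallest
node set).

Family enrichment is a one-sided (over-representation only) hypergeometric
upper tail: for a family with K of M background genes and a tested set of
N transporters containing k family members, p = P(X ≥ k),
X ~ Hypergeom(M, K, N), Benjamini–Hochberg adjusted across families and
flagged at FDR ≤ 0.05. The background defaults to the full annotated
SLC+ABC list supplied with the family map; there is no single canonical
choice of background, and it is an explicit argument.

## Expression landscape

A gene is *expressed* in a line when its RMA value is ≥ 3.5; the
comparison is inclusive at the boundary for determinism. Prevalence
summaries are row/column sums of the boolean mask. Genes split into a
*common* set (expressed in ≥ 900 of ~1000 lines), a *specific* set
(< 100) and the intermediate rest; when the panel is not ~1000 lines the
thresholds scale proportionally (0.9 and 0.1 of the panel), so the classes
keep their meaning on small synthetic panels.

Per gene, the median and maximum expression over lines are reported with
the tissue of the line attaining the maximum (first occurrence on ties).
Tissue Z-scores are computed from per-tissue means (unweighted by tissue
size): per gene, z_t = (m_t − mean(m)) / sd(m) across tissues with the
population (n-denominator) standard deviation. Fewer than two tissues is
an error; a gene with identical tissue means gets an all-zero row and a
warning.

## Genomic alteration matrix

Per gene three binary features are derived from call tables:

- amplification — more than two copies of at least one allele
  (strictly > 2, so (2,2) is not amplified);
- deletion — at least one allele entirely missing (min copies = 0);
- variant — a retained nonsynonymous SNV. Synonymous and "other"
  consequences are dropped. Deleteriousness verdicts from SIFT, PolyPhen2
  and FATHMM arrive pre-tabulated ({del, tol, NA}); missing verdicts are
  abstentions. The default rule keeps a variant when **any** available
  predictor calls it deleterious (reading the exclusion as "drop when no
  predictor calls it deleterious"); `rule="all"` implements the stricter
  reading. A variant with no verdict at all is dropped under either rule.

Aggregation per (line, gene) is OR across records: one qualifying record
sets the feature to 1. Records for genes outside the requested panel are
ignored with a logged count.

## Regularized regression

Features are standardized to mean 0 and population sd 1; zero-variance
columns pass through as all-zero and are flagged (they can never enter a
model). Responses are not standardized; coefficients are reported on the
standardized-X scale, which leaves sign analysis untouched.

The penalty path is λ_max · r^(i/(n−1)), i = 0..n−1 (log-spaced,
descending, default n = 100), with

    λ_max = max_j |x_jᵀ(y − ȳ)| / (n·α),

the smallest penalty at which every coefficient is exactly zero. The
floor ratio r defaults to 0.01 when n_samples < n_features and 1e-4
otherwise. α = 0 has no finite λ_max and raises.

The objective `(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` is
minimized by scikit-learn's coordinate descent, whose parameterization
matches it exactly; λ = 0 is solved directly by least squares. Solver
tolerances: single fits use a dual-gap tolerance of 1e-8 (the unit tests
verify agreement with the OLS, ridge and soft-threshold closed forms to
1e-5); warm-started path fits default to 1e-4. During cross-validated λ
selection the per-fold path refits use a looser 1e-3 tolerance with an
iteration cap, because the only fits it loosens are the grossly overfit
deep-tail models that never win the held-out-MSE comparison; the λ
ultimately selected is refitted tightly.

λ selection recomputes the path on each training partition (model-specific
penalties) and picks the λ with the smallest mean held-out squared error
over an independent inner 5-fold split; ties resolve to the larger
(sparser) λ, and a 1-standard-error rule is available behind
`lambda_rule="1se"`. Folds are seeded shuffled partitions with sizes
differing by at most one; repeat r uses seed + r, and within the
elastic-net pipeline run (r, f) derives its inner-CV seed as
master + 1000·r + f so every model run is independently reproducible.
Cell lines with a missing response for a drug are dropped for that drug
before fold splitting; drugs with fewer than 20 usable lines are skipped.

## LASSO path-frequency ranking

Per training partition the full λ path is fitted with α = 1; each
feature's *path frequency* is the number of path points with |coef| >
1e-10. Features are ranked per fit by descending frequency with midranks
on ties (midranks conserve the rank sum, which the tests exploit as an
exact invariant), and ranks are averaged over all repeats × folds
(reference conditions: 50 × 10). The final order is ascending average
rank, ties broken by larger mean path frequency, then alphabetically.
Zero-variance features are excluded from fitting and pinned to the worst
ranks. The top predictor's direction is the sign of its coefficient in a
full-data fit at the cross-validated λ: positive = resistance, negative =
sensitivity; an exactly zero coefficient is reported as undetermined.

## Elastic-net stability selection

Per drug, n_repeats × n_folds (reference 100 × 5 = 500) models are fitted
at α = 0.5. Each run standardizes its training partition, selects λ by
inner CV, fits, predicts the held-out lines and scores the concordance
index. Concordance follows the standard convention: pairs tied in the
observed response are excluded; tied predictions earn half credit; an
all-tied observed vector has no comparable pairs and the run's CI is
recorded as missing. A run's coefficients are normalized by the run's
absolute maximum (an all-zero model keeps all-zero weights).

Aggregation over runs: frequency = share of runs with a nonzero
coefficient (threshold 1e-10 at the selected λ); mean weight = average of
normalized weights over **all** runs, zeros included, so that frequency
and magnitude jointly damp unstable features (averaging over selected
runs only is available via the aggregation table's columns). Direction is
resistance for positive mean weight, sensitivity for negative. Ranking is
by descending frequency, ties by |mean weight|, then alphabetical;
never-selected features carry no rank. Drug selection applies a strict
CI > 0.65 bar; both the mean-CI and median-CI aggregates are computed and
kept in the output, since the two conventions coexist in practice, with
mean as the default.

## Synthetic data generator

The generator emulates the structure the analyses assume, at the scale of
the real panel it mirrors (defaults: 1,000 cell lines; 417 transporter
genes, 371 SLC + 46 ABC; 13 tissues):

- **Bimodal expression prevalence.** Each gene draws a prevalence class —
  common (default fraction 0.31), specific (0.34), intermediate — and a
  per-line expression probability uniform in a class band ((0.97, 1),
  (0, 0.05), (0.15, 0.85)). Expressed entries come from N(6.5, 1.0²) and
  silent entries from N(2.0, 0.5²) on the RMA scale, straddling the 3.5
  cutoff with realistic separation. The class fractions correspond to the
  ~130-gene common and ~140-gene specific sets of a 417-gene panel.
- **Tissue structure.** Lines draw a tissue uniformly; per tissue, a
  random 5% of genes act as markers with a +1.5 mean shift in that
  tissue.
- **Alterations.** Independent Bernoulli(0.05) entries per amp/del/var
  feature.
- **Drug response.** AUC = intercept + Σ_f coef_f·x_f + N(0, noise_sd²),
  with expression features standardized before the planted coefficients
  act (so effect sizes are comparable across features and match the
  regression's standardized scale) and binary features entering as 0/1.
  Negative coefficients plant sensitivity, positive resistance; an
  optional uniform missingness rate (default 0) exercises
  missing-response handling. Pure-noise "null" drugs are generated
  separately for calibration.
- **Network fixtures.** Bipartite graphs with zipf-like preferential
  transporter weights guaranteeing a hub, a degree-one compound and an
  exclusively shared pair, with random support counts, FDA flags and
  family labels. The generator emits a truth table (degrees, exclusive
  and shared sets, components) computed by plain dict/BFS bookkeeping,
  independent of the curation code it later checks.

What the generator does **not** emulate: dose–response curve shapes (AUC
is generated directly), gene–gene co-expression structure, tissue-specific
drug response, linkage between alterations and expression, and measurement
batch effects. Passing recovery tests therefore demonstrate that the
pipeline's statistics behave correctly under its own modeling assumptions
— linear sparse effects with independent Gaussian noise — not that those
assumptions hold in any particular real screen.

## Validation experiments and problem sizes

The recovery experiments plant effects on intermediate-prevalence genes
(expressed in 20–80% of lines): a gene silent or expressed almost
everywhere carries almost no between-line variance, so planting there
would probe the generator rather than the pipeline.

- LASSO ranking: one planted effect (|coef| = 2, noise sd 0.5) on 200
  lines × 300 genes, 10 repeats × 10 folds, 20 replicates; success is
  final rank 1 with the correct direction.
- Elastic net: a −2/+2 pair on 200 lines × 120 transporter genes, 20
  repeats × 5 folds, 20 replicates; success is both features in the top
  two frequency ranks with correct signs and mean CI above the 0.65 bar.
- Null calibration: signal-free drugs under the same configuration; the
  mean CI across replicates must sit within 0.5 ± 0.05.

These sizes keep the full suite to minutes on a single CPU while leaving
the per-model procedure (inner-CV λ selection, 100-value paths) exactly as
specified at reference scale. The analysis scripts use a 300-line ×
200-gene study and 10-repeat cross-validation for the same reason; all
stages accept the reference-scale settings unchanged.

## Known limitations

- SIF export is lossy (no support counts); use GraphML or edge-TSV for
  round-trips.
- The enrichment background must be supplied; results depend on that
  choice.
- `build_alteration_matrix` expects (major, minor) allele counts;
  total-copy-only data can only support a degraded deletion rule (total
  = 0) and should be converted upstream.
- The concordance index is O(n²) per fold; fine for panels of a few
  thousand lines, not for biobank-scale cohorts.
- Path-frequency ranking and stability frequencies depend on the λ grid
  (length and floor); the defaults follow the standard glmnet-style
  conventions, and changing them changes the absolute frequencies, though
  rankings are in practice stable.
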