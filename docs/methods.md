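# Methods

This note documents the statistical model behind each stage, the
conventions chosen where more than one was defensible, what the synthetic
generator does and does not emulate, and the numerical details that affect
reproducibility.

## Abundance and differential testing

Gene abundance is TPM-style length-normalized relative abundance:
`TPM_fs = (c_fs/L_f)·10⁶ / Σ_g(c_gs/L_g)`.  Columns sum to 10⁶ by
construction (validated to 10⁻⁹ relative tolerance), and multiplying one
sample's counts by a constant leaves its TPM column unchanged — sequencing
depth cancels.  TPM is **compositional**: statements about change are
always relative to the whole community (see "Scoring recovery" below).

The two-group differential layer is Welch's unequal-variance t-test on
`log₂(TPM+1)`, BH-adjusted, significant at `q < 0.05`.  This is a
deliberately simple, well-calibrated test chosen so the layer is
self-contained and pluggable (`differential_abundance(test=...)` accepts
any row-wise p-value function); it is not a negative-binomial GLM and does
not shrink dispersions.  Conventions: the pseudocount is 1 TPM (bounded
influence of zeros at this scale); features with zero variance in both
groups get `p := 1` when means are equal and `p := 0` otherwise; p-values
are two-sided and a direction (increased/decreased, treatment relative to
control) is assigned only when `q < α`.  Under a global null the layer's
empirical FDR measured by simulation is ≤ 0.05–0.06 at nominal 0.05.

Gene-group averages (e.g. "the urease gene group") are the unweighted
arithmetic mean, over the group's member genes, of each gene's mean TPM
across a sample group — so a published per-gene table reproduces its own
"average" row exactly.

## Marker genes

The marker catalog maps each of the five Ni-dependent enzymes to its KO
ids (urease K01428–K01430 + K03188–K03190; ACS/CODH K00192/K00196/K00198;
[NiFe]-hydrogenase maturation K04651–K04656; glyoxalase I K01759; lactate
racemase K22373).  The bundled reference *sequences* are deterministic
synthetic stand-ins suitable for simulation and testing only; real
annotation should load a curated FASTA set via
`MarkerCatalog.from_manifest`.

Pairwise comparison uses the best-scoring local alignment (match +1,
mismatch −1, gap open −2, gap extend −0.5).  Identity = matches / aligned
columns (gap columns included); coverage = aligned query span / query
length.  Because the best local alignment is not always unique, the
aligner is run in a canonical orientation (longer sequence as target,
lexicographic tie-break), which makes identity exactly symmetric; coverage
remains query-relative and is intentionally asymmetric.  Any reasonable
scoring scheme separates the decision thresholds at the divergences that
matter here; the scheme above is fixed for determinism.

Non-redundant clustering is greedy and incremental, longest sequence
first (ties broken lexicographically by id): a sequence joins the first
representative with identity ≥ 0.90 over an alignment covering ≥ 0.90 of
the shorter sequence, otherwise it founds a cluster.  Coverage is measured
on the shorter sequence for clustering (the usual NR-catalog convention)
but on the query for marker retrieval.  Marker retrieval is KO-gated: only
genes whose KO belongs to a catalog enzyme are aligned, against that
enzyme's references only, and retained iff best identity > 0.85 **and**
coverage > 0.90 — both strict, exactly as the thresholds are stated.
Identity/coverage are nucleotide-level here; the choice of level and of
the coverage denominator are declared conventions.

## Community construction

Bin QC keeps completeness > 60%, contamination < 10%, strain
heterogeneity < 10% (strict inequalities; boundary values are excluded).
Bins sharing a species label are summed into a `SpeciesAggregate`: KO set
as the union over member scaffolds' genes, abundance as the per-sample sum
of member-scaffold TPM, completeness as the arithmetic mean of member-bin
completeness.  Bins labelled `unclassified` survive QC but are excluded
from aggregation (avoiding a spurious mega-species); a scaffold claimed by
bins of two *different* species is an error, while duplicates within a
species count once.

The marker community is the subset of aggregates owning at least one
scaffold with a retained marker hit, annotated with the union of enzymes
found on their scaffolds.  Species-level differential abundance is
computed on the aggregate per-sample TPM sums with the same test as the
gene layer; the partition is upregulated / downregulated (q < α with the
corresponding mean ordering) / unchanged, and `q = α` exactly is
unchanged.  Marker-coverage fractions (how much of an enzyme's total
abundance the QC bins capture) are per sample, with zero-total samples
excluded from the reported min–max range with a warning.

## Pathways

A pathway definition is an ordered list of sub-pathways; each sub-pathway
lists pathway enzyme genes (PEGs); each PEG is one enzymatic step with a
set of interchangeable KOs.  A PEG is detected in a species iff at least
one of its KOs is present.  The bundled SCFA-generation reconstruction has
10 sub-pathways (starch, glycolysis, cellulose, hemicellulose and pectin
degradation; propionate, butyrate, acetate and formate generation; lactate
metabolism) with 62 distinct PEG codes, plus auxiliary fatty-acid,
nitrogen and sulfur pathways.  Steps shared between sub-pathways (codes
27–32, 44, 46) repeat their code; validation requires that a repeated code
always carries the same KO set.  The KO roster per step is a curated,
editable stand-in (stated in the file header); the layout, not the exact
roster, is what downstream code depends on.

Pathway completeness = detected PEGs / average bin completeness, with
completeness as a fraction in (0, 1] — so the statistic is at least the
raw PEG count and reduces to it for complete genomes.  This normalization
deliberately *credits* a partially recovered genome for enzymes its bins
likely missed.  Two conventions were genuinely open and are configurable:
the counting unit (whole PEGs, default, vs member KOs — `count="ko"`) and
the completeness units (`completeness_units` in the pipeline config;
percentages on disk are divided by 100).  Population comparison is one-way
ANOVA per sub-pathway on per-species statistics, BH across sub-pathways;
a sub-pathway where any population has fewer than two species is flagged
untestable and excluded from the adjustment; all-identical values give
`F = 0, p = 1`.

Enrichment: for each (sub-)pathway and direction,
`p = P(X ≥ k), X ~ Hypergeom(N, K, n)` with N the KOs having a
differential result (detected KOs, not the whole KO universe), K the
significant KOs in that direction, n the pathway KOs present, k the
overlap; one-sided upper tail, BH jointly across pathways × directions.
The tail matches exhaustive enumeration to < 10⁻¹² for all N ≤ 30.

## Ecology

Shannon diversity is reported in nats; Simpson as Gini–Simpson `1 − Σp²`
(the common ecology-package default; the raw concentration `Σp²` is
available via `variant="lambda"`).

CCA follows ter Braak: chi-square standardized matrix, row-weighted
projection onto the constraint space, eigen-decomposition of the fitted
matrix (delegated to scikit-bio's implementation; eigenvalues verified
against a dense-matrix oracle in the tests).  Axis signs are arbitrary.
Degenerate tables whose rows are proportional have zero inertia and return
no axes; collinear constraints are rejected naming the dependent column.
Both flavors of sample scores are exposed: weighted-average (WA) scores,
used by envfit and typical for plotting, and linear-combination (LC)
scores, which are the constrained configuration itself and the natural
object for gradient-recovery claims (with a noise-free planted gradient,
LC axis-1 correlates ~1.0 with it, while WA scores retain residual
sampling noise and typically correlate 0.83–0.97).

envfit regresses an environmental vector on the first two site-score axes
(two axes because that is what constrained ordination plots show; the
count is configurable) and reports R² with a permutation p-value using the
add-one estimator, default 999 permutations, bit-reproducible under a
seed.  `p ≥ 1/(n_perm+1)` always.  NMDS is intentionally not implemented:
its stress-minimization is a visualization heuristic with no testable
claims here, and CCA carries all the quantitative ones.

Fermentation summaries report group mean ± SEM; total SCFA is the
per-sample sum of acetate, propionate and butyrate, and the L/D lactate
ratio is computed per sample and then averaged.  Mean-of-ratios was chosen
over ratio-of-means because only the former is consistent with published
group tables in this domain (on a 6-sample fixture with L/D means
0.61/0.40, mean-of-ratios is 1.58 while ratio-of-means is 1.525); samples
with zero D-lactate are excluded from the ratio with a warning.

## Synthetic data

The generator emulates the study design the pipeline targets: two diet
groups of 6 samples, a community of species whose genomes are KO sets
(each species drawing 40–80% of the bundled pathway-KO universe plus
filler KOs), one gene per (species, KO) with lengths 300–1500 bp,
scaffolds of 1–5 genes, and negative-binomial counts with
`mean = baseline × fold × length/1000 × depth` and variance `µ + αµ²`
(α = 0.05 by default, baselines lognormal(3, 0.7)).  Per-sample depth
factors are lognormal(0, 0.1) precisely so that raw counts are *not*
comparable across samples and TPM normalization is genuinely exercised.
Planted marker genes diverge 8% from their catalog reference — inside the
85%-identity retrieval gate but far enough that independently mutated
copies of the same reference stay below the 90% clustering threshold, so
each planted species keeps its own marker.  Bins realize a drawn
completeness fraction of one species' scaffolds (rounding down) plus
contaminants drawn from other species' unbinned scaffolds; recorded
quality metrics equal the realized fractions exactly (an optional Gaussian
perturbation models estimation error).  The environment table couples one
variable linearly to the projection of sample composition on a loading
vector, with Gaussian noise; the remaining variables are independent noise
around rumen-typical values.

What the generator does **not** emulate: read-level error and assembly
artifacts, strain mixtures, phylogenetic correlation among genomes,
horizontal transfer, taxonomy-assignment error (bin labels are truthful
unless perturbed), and overdispersion heterogeneity across genes.  Passing
tests therefore demonstrate correctness of the statistics and the
recoverability of planted structure under the stated model — not
robustness to upstream assembly/binning failure modes.

**Scoring recovery.**  Because TPM is relative, a planted absolute
fold-change `f_s` manifests as `f_s / F`, where
`F = Σᵢnᵢbᵢfᵢ / Σᵢnᵢbᵢ` is the community-wide shift (gene counts n,
baselines b; gene lengths cancel).  Ground truth for the population
partition is therefore `SyntheticTruth.expected_relative_directions()`:
when two species rise 8-fold, every unperturbed species is genuinely
expected to fall in relative abundance, and the pipeline is scored for
detecting exactly that.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately small configurations —
communities of 6–12 species (≈400–800 genes, 12 samples), 20-seed
replication for recovery rates, 50 seeds × ~400 features for null FDR
calibration, 99–999 permutations for envfit — sizes chosen so the full
suite runs in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted margins.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical seeds give
byte-identical outputs, including written TSVs (floats printed with six
significant digits; numeric comparisons in tests always use tolerances,
never printed strings).  TSV (UTF-8, header row, `.` decimal) is the
interchange dialect throughout, matching the ecosystem the inputs come
from.

## Known limitations

- The differential layer is a t-test on transformed relative abundances;
  with very low counts or few samples a count-model GLM has more power.
- NR clustering is all-vs-representatives alignment — appropriate for the
  catalog sizes handled here, not a substitute for indexed heuristic
  search at millions of genes.
- The bundled pathway KO rosters are curated stand-ins; analyses of real
  data should review and edit them.
- Compositional effects are handled by interpreting results relative to
  the community (no centered log-ratio or similar transform is applied).
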