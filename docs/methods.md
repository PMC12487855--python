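# Methods

## Screen phenotype model

Counts are converted to relative abundance with a pseudocount before any
ratio: element *i* in a sample contributes (cᵢ + pc) / (T + pc·n), with
T the raw column total, n the number of elements and pc = 1 by default.
Applying the pseudocount on this scale (rather than to raw counts) keeps
ratios invariant to sequencing depth; pc = 0 is allowed when every count
is positive. Replicates of one condition are summed into a single
pseudo-sample before the ratio that defines the γ/τ/ρ point estimates;
replicate-resolved ratios feed only the Wald test. With a shared
pseudocount the identity raw-ρ = raw-τ − raw-γ holds per element to
machine precision, and the test suite asserts it at 1e-12.

Centering subtracts the median log₂ ratio of the non-targeting controls
(NTCs), so the NTC median is exactly zero afterwards; division by the
arm's population doublings puts all three phenotypes on a per-doubling
scale (γ by the vehicle-arm doublings, τ and ρ by the drug-arm
doublings, defaults 10 and 5). Standardized phenotypes divide by the
NTC phenotype standard deviation (sample SD, ddof = 1), making the NTC
distribution unit-scale by construction.

Gene scores are the mean of the top-k (default 3) elements ranked by
absolute phenotype with sign preserved; genes with fewer elements use
all of them, and ties in absolute value at the cut are broken by element
id so the score is deterministic. Ranking by absolute value slightly
inflates the magnitude of strong effects (order-statistic selection,
≈0.5σ of the per-element noise for 3-of-5 selection), which stays within
the recovery tolerances the tests enforce at the simulated depths.

Gene-level significance is a two-sided Mann-Whitney U test of a gene's
element phenotypes against the full NTC phenotype distribution — exact
when the pooled sample is tie-free with ≤12 observations, otherwise the
normal approximation with continuity and tie corrections. The
per-element Wald test across replicates uses z = mean / (s/√n) with a
normal reference; elements with zero replicate variance fall back to the
median NTC replicate SD as a variance floor. Both paths are reported
because drug-modifier screens differ in design: few-replicate
genome-wide screens are typically scored by the rank test against NTCs,
while multi-replicate designs support the per-element Wald test. FDR is
Benjamini–Hochberg (statsmodels implementation; the test suite checks it
against the step-up formula with cumulative minimum on random vectors).

Hits at q < α (default 0.05) split by score sign: negative = sensitizing
(or required for growth, for γ), positive = resistance. An exactly-zero
significant score is reported as indeterminate rather than assigned a
direction.

## Cross-screen integration

Conservation is an intersection call: a gene pair passes iff q < α with
concordant sign in both screens. Discordant-sign pairs are excluded
from hit lists but kept in the provenance table, which carries both
screens' scores and q-values for every pair considered. The default
ortholog mapping is case-insensitive symbol identity (SHOC2 ↔ Shoc2) —
adequate for symbol-matched human/mouse catalogs — and an explicit
two-column map overrides it; conflicting duplicates in an explicit map
are an error rather than silently resolved. The consensus growth
signature is the set of genes required for growth (γ q < α, score < 0)
in both screens, ordered by mean score across the two screens. No
meta-analytic pooling is performed: intersection is deliberately
conservative and matches how conserved hits are usually reported.

## Module scores and state assignment

Module scores follow the bin-matched-control convention: genes are
ranked by mean expression across cells (stable sort) and split into
n_bins = 25 near-equal bins; each signature gene draws n_ctrl = 100
control genes from its own bin (with replacement when the bin is
smaller); a cell's score is its mean expression over signature genes
minus its mean over the pooled control draw. Because both terms are
means over fixed gene sets of the same cell's row, adding a constant to
a whole row cancels algebraically; in floating point the residual is
round-off (asserted < 1e-12). Binning by rank also makes the bin
assignment — and hence the control draw under a fixed seed — invariant
to per-cell shifts, since shifting one row adds the same constant to
every gene mean.

State assignment is the argmax of the four state scores with the fixed
tie-break order MES-like, AC-like, OPC-like, NPC-like; the
two-dimensional hierarchy placement sometimes drawn alongside these
scores is visualization, not classification, and is not implemented.
A cell is cycling when max(G1/S, G2/M score) exceeds a threshold,
default 0.1 — exposed as a parameter since conventions differ. Group
comparisons of any per-cell score use the same rank-sum engine as the
screen half, so the two halves cannot diverge in test mechanics.
Expression is assumed log-normalized; the package performs no
normalization, batch correction, clustering or CNA inference.

## Synthetic data generators

The screen generator is a Gamma–Poisson (negative binomial) model over
an exponentially growing library. Element abundance starts at
LogNormal(0, 0.5) (library skew); after d doublings in condition c its
expected relative abundance is a·2^(d·(1 + k·φ)) with φ the gene's
per-doubling growth effect in vehicle, growth plus drug effect under
drug, 0 for NTCs, and k the knockdown efficiency. Proportions are
renormalized per sample and counts drawn NB with mean
depth·n_elements·proportion and variance mean + dispersion·mean²
(default dispersion 0.05, typical of library-prep overdispersion;
0 gives Poisson). Default doublings are 10 (vehicle) and 5 (drug),
the asymmetry characteristic of an effective drug arm; default depth
500 reads/element. Dual-guide cassettes are modeled as single
elements. Note that with overdispersion the per-sample total has
variance well above the Poisson total, so "column sum ≈ depth·n" holds
with the NB band, not √total; the tests use the analytic band at
dispersion 0.05 and the √total band at dispersion 0.

The cell generator works directly on log-normalized-scale values:
baseline |Normal(0, noise_sd)| per gene per cell (noise_sd 0.5), plus
effect_size (default 1.0 log2 units) on the cell's true-state module
genes, on one randomly chosen cell-cycle module for the planted cycling
fraction (default 20%), and optionally on extra signature genes per
state. It deliberately omits UMI sampling, doublets, ambient RNA and
batch structure — every in-scope scoring operation consumes normalized
expression, so these layers would only add nuisance realism. Passing
recovery tests therefore demonstrates correctness of the scoring
machinery under clean additive signal, not robustness to the full noise
anatomy of droplet data.

## Numerical and design choices

- Ratios, centering and scores are float64 throughout; medians use the
  even-count midpoint convention.
- The Mann-Whitney exact/asymptotic switch is at pooled n = 12, tie-free;
  the test suite proves equality with full enumeration for every
  tie-free rank pattern with pooled n ≤ 10.
- Downsampling is an exact multivariate-hypergeometric draw per column
  (without replacement), so target depth is hit exactly and entries
  never exceed their inputs; a mandatory seed is recorded in the run
  manifest.
- Elements missing from a sample are treated as count 0, not dropped;
  elements absent from the library are excluded and reported.
- Per-stage seeds in the CLI pipeline derive from one global seed via
  SeedSequence([global_seed, stage_index]).
- Problem sizes in the tests and the acceptance script (hundreds to a
  thousand genes, five guides per gene, a few hundred NTCs, 800-cell
  populations) are chosen as the smallest scales at which the planted
  effects, calibration bands and error bounds are statistically
  meaningful; they are scaled-down analogs of genome-wide screens
  (tens of thousands of elements) and full tumor datasets.

## Known limitations

- The Wald test assumes approximately normal replicate ratios and a
  normal (not t) reference; with 2–3 replicates its p-values are
  anti-conservative for heavy-tailed noise. The Mann-Whitney path is
  the primary gene-level test.
- Case-insensitive symbol identity is a crude ortholog map; genuine
  one-to-many orthology requires an explicit mapping file.
- The top-k gene score is not an unbiased effect estimator (selection
  bias noted above); it is a ranking statistic, as is conventional.
- The cycling threshold (0.1) is a convention, not a fitted quantity;
  operating characteristics at other noise levels should be checked
  with the generator before reuse.
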