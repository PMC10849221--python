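# Methods

`ribopred` predicts protein expression of bacterial genes from their mRNA
sequence.  It chains four models: an initiation-rate energetics model of the
ribosome binding site, a per-codon elongation-rate model, a stochastic
exclusion-process simulation of ribosome traffic, and a supervised
regression stage that learns a better translation-rate predictor
("New_TR") and screens sequence/protein features for additional predictive
power.  This note documents each model, its assumptions, the tunable
parameters, and the choices made where the design was genuinely open.

## Coordinates

Throughout the package, +1 is the first nucleotide of the start codon and
−1 the nucleotide immediately upstream; there is no position 0, and windows
include both endpoints.  This matches the usual way ribosome-binding-site
windows ("−12 to −7", "+1 to +30") are quoted in the literature.

## Sequence ingestion and filters

CDSs are accepted as protein-coding when they (a) begin with ATG, CTG, GTG
or TTG, (b) have length a positive multiple of 3, (c) contain no internal
stop codon and (d) end in a stop codon.  Rule (d) is implied rather than
universal in annotation pipelines; it is enforced here because the stop
codon identity is itself a model feature.  Rejections carry machine-readable
reasons (`BAD_START`, `BAD_LENGTH`, `INTERNAL_STOP`, `NO_TERMINAL_STOP`).
Non-ATG initiator codons translate to Met (bacterial initiator-tRNA
convention); this matters for the N-end feature.  Genes without a 5'-UTR
annotation are retained with UTR-dependent features marked missing, as a
single-gene operon.

## Expression preparation

mRNA replicate columns are averaged within culture conditions, condition
columns are quantile-normalized (within each column the k-th smallest value
is replaced by the mean of the k-th smallest values across columns; ties
receive the mean of the reference values their ranks span — the "average
ties" dialect), and the per-gene mRNA level is the arithmetic mean over
normalized conditions.  Protein abundance (PA) is a single integrated
column.  Genes with zero PA or zero mRNA are removed; PA/mRNA is the exact
ratio.  Order of operations (aggregate replicates first, then normalize
conditions) is a choice; normalizing replicates first differs negligibly
for balanced designs.

## Initiation rate

The initiation rate is an Arrhenius-type function of the total interaction
energy of the ribosome binding site:

    alpha = A_scale * exp(-dG_total / RT),        RT = 0.6156 kcal/mol (37 C)

    dG_total = dG_duplex + dG_spacing + w_unfold * dG_unfold

* `dG_duplex`: best hybridization of the 16S rRNA anti-Shine-Dalgarno tail
  (3'-UCCUCC-5') against every 6-nt placement inside the −20..−5 search
  window, with per-pair pseudo-energies G:C −3.0, A:U −2.0, G:U −1.0
  kcal/mol (a match-count surrogate for a nearest-neighbour duplex model).
* `dG_spacing`: 0.1 kcal/mol × (spacing − 5)², where spacing is the number
  of nucleotides between the SD 3' end and the start codon.  Quadratic
  penalties around a ~5-nt optimum are the standard way aligned spacing is
  modelled.
* `dG_unfold`: the cost of opening mRNA structure around the start codon,
  −MFE of the −35..+35 window (clipped to the available sequence), at
  coupling `w_unfold = 0.1`.  The sub-unitary coupling reflects that the
  pair-count pseudo-energy overstates the structure the 30S subunit must
  actually open; at 0.1 the resulting rates fall into the two observed
  clusters — roughly 0.01–1 s⁻¹ for strong-SD genes and 10⁻⁸–10⁻³ s⁻¹
  for SD-less, structured ones.
* `A_scale` is fixed by the convention that a perfect consensus SD
  (AGGAGG) at optimal spacing in an unstructured context initiates at
  1 s⁻¹.

Genes whose UTR does not cover the −20..−5 search window are discarded with
reason `RBS_TOO_SHORT` before any model fitting.  All constants live in
`InitiationParams` and can be overridden.

## Elongation rates

Per-codon dwell times default to 1/(w + 0.25) scaled to a mean of 0.05 s
over the 61 sense codons, where w is the codon's relative tAI adaptiveness
(below).  The floor keeps the per-codon speed range within the ~5-fold
spread that ribosome-profiling dwell estimates show; without it, codons
decoded only through the near-forbidden wobble channel (s = 0.9999) would
be four orders of magnitude slow and distort the scaling.  A user-supplied
dwell table (e.g. from ribosome profiling) replaces the default directly.
Hop rate of codon i is 1/dwell(i); the gene-aggregate elongation rate is
the harmonic-mean speed L / Σ dwell (codons/s), which is the physically
meaningful average for sequential traversal.  With the default table,
gene-level elongation rates vary by only ~30% across genes — consistent
with the narrow spread reported for genome-wide elongation-rate estimates.

## TASEP simulation

Ribosome traffic is an open-boundary totally asymmetric simple exclusion
process with extended particles, simulated by exact (rejection-free)
kinetic Monte Carlo:

* lattice: the L sense codons of the CDS; ribosome footprint ℓ = 10 codons
  (configurable; a literature-standard value);
* initiation at rate α when sites 1..ℓ are vacant;
* a ribosome whose leading edge is at site i hops to i+1 at the elongation
  rate of its A-site codon (a(i) = i − ℓ + 1, clipped to the lattice) if
  the next site is vacant; the leading edge may slide past the lattice end;
* termination at rate β = 10 s⁻¹ (non-limiting by default) when the A-site
  reaches the last codon, freeing all ℓ sites.

Hard-core exclusion (gap ≥ ℓ between leading edges) is enforced everywhere,
including the overhang region.  Statistics are collected only inside the
measurement window (defaults: burn-in 10·L/mean(k), measurement
50·L/mean(k)); the translation rate is terminations per measured second.
Collisions are reported as the expected number of blocked hop attempts
(the time integral of the total blocked rate), which is the rejection-free
estimator of the attempt count.  A split-half flux comparison warns (not
fails) when the two halves differ by more than 3 combined standard errors.
Identical seeds give bit-identical trajectories.

For lattices of ~10 sites the full master equation is solved exactly
(`exact_steady_state`) by enumerating all admissible configurations and
solving for the stationary distribution; the simulator is validated against
this oracle and against the analytic low-density current α(1−α) and the
extended-particle maximal current 1/(1+√ℓ)².

## Sequence and protein features

* **Type**: first gene of its operon (position 1) vs internal.
* **uAUG**: upstream ATGs are scanned in the −12..−1 window (start
  positions −12..−3, so the triplet lies wholly in the UTR).  An uATG whose
  offset to the main start is a multiple of 3 is in frame; in-frame takes
  precedence when both occur.  The 12-nt window is the default because the
  upstream-AUG analyses this feature reproduces were run at −12; a
  `window_len` override is provided.
* **CAI**: Sharp–Li relative adaptiveness — per amino acid,
  w(codon) = count/max-synonym-count over a reference CDS set (default:
  the input set itself; a highly-expressed reference can be supplied),
  zero counts replaced by 0.5 pseudo-occurrences, initiator and stop
  codons excluded; CAI is the geometric mean of w over body codons.
* **tAI**: absolute adaptiveness W(codon) = Σ (1−s)·copies over the
  anticodons that decode the codon (Watson-Crick plus the standard wobble
  channel for each codon-family third base), with the standard s-value
  set; packaged tRNA gene-copy numbers follow the E. coli K-12 genomic
  census and are overridable.  Relative w = W/max W with zeros replaced by
  the geometric mean of nonzero values; tAI is the geometric mean over
  body codons.
* **Folding energy**: windows anchored on the start codon, screened by a
  missing-data rule — a candidate window whose missing fraction (UTRs too
  short to cover it) exceeds 15% is dropped entirely, never imputed.  The
  surviving canonical feature is the +1..+30 window, which every valid CDS
  covers.  Backends: Nussinov base-pair maximization (minimum hairpin loop
  3, −1.0 kcal/mol per pair) as the deterministic default, or ViennaRNA's
  thermodynamic MFE when its python bindings are importable.
* **Length**: protein length in amino acids (nucleotide length differs by
  a factor 3, leaving rank correlations unchanged).
* **N-end class**: the classified residue is residue 2 when methionine
  aminopeptidase would excise the initiator Met (residue 2 ∈
  {A,C,G,P,S,T,V}), else the retained Met.  L,F,W,Y,R,K → half-life under
  2 minutes; Pro → excluded (kept as a third categorical level rather than
  dropping the genes); all else → over 10 hours.
* **Instability index**: Guruprasad II = (10/L)·Σ DIWV(xᵢ,xᵢ₊₁) with the
  standard 20×20 dipeptide weight table.

Categorical features are one-hot encoded with the most frequent level as
the reference.  A positional nucleotide frequency matrix (default −15..+15)
is available for composition analyses; covered rows sum to 1.

## Learning stage

`TranslationRateModel` follows the model/results pattern: the model is
built from a gene-indexed design and a positive response, `fit()` returns a
results object with per-gene predictions, the split, Spearman scores and a
`summary()`.  Six regressor families are supported (OLS, Ridge, Lasso,
Elastic Net, Random Forest, RBF-kernel SVR), all with library defaults and
a fixed seed.  Inputs are z-scored on training statistics; the initiation
rate is log10-transformed first (it spans ~8 decades); the response is
log10-transformed and z-scored on training statistics (essential for the
epsilon-insensitive SVR loss; a monotone transform, so Spearman evaluation
against the raw response is unaffected).  The split is a deterministic
80:20 partition (train = round(0.8·n)).  New_TR is this model fitted on
{log10 initiation rate, elongation rate} only, predicted for every gene;
PA and PA/mRNA get separate fits.

The subset search combines New_TR with every subset of the ten optional
features (1024 models over sizes 0..10), all under one shared split so
test-split Spearman scores are comparable; categorical features enter as
whole one-hot blocks; ties break lexicographically; per-size winners are
re-evaluated on the full dataset.  Full-dataset predictions are computed
lazily so the search prices each candidate at one fit plus one test-split
prediction.

Group comparisons for categorical features use the pooled-variance
two-tailed Student's t-test (Welch by flag).

## Synthetic data generator

The generator emulates the structure the pipeline assumes: operons with
geometrically distributed sizes (mean 2.5), 20–40-nt A-rich UTRs carrying
a consensus AGGAGG at spacing 5–7 nt with probability `sd_strength`
(default 0.8), CDSs of 60–900 nt with synonymous-codon choice tilted
toward high-adaptiveness codons (P ∝ exp(2·w)), start codons at the
empirical E. coli frequencies (ATG 89.8%) and stop codons likewise (TAA
69.7%).  Every emitted record passes the protein-coding filters by
construction.

Expression has two modes.  In the default *planted* mode, log10 PA is a
linear combination of standardized feature encodings plus Gaussian noise;
the default effects put coefficient 1.0 on each mechanistic rate (log10
initiation rate, elongation rate) and 0.2 on Type, Start, Stop and
Length, with noise 0.10 log10 units, so the rates carry ~92% of the signal
variance and the four sequence features remain individually detectable —
the configuration under which learned-rate recovery is analytically
checkable.  mRNA is log-normal with configurable correlation to PA
(default 0.6), expanded into 2 conditions × 3 replicates with small
condition and replicate log-normal noise.  The *mechanistic* mode instead
routes expression through the TASEP simulator (PA ∝ mRNA × simulated
flux), for end-to-end integration tests.

What the generator does **not** emulate: real genomic codon correlations,
operon-level polarity, measurement-specific microarray biases, or any
direct mechanistic coupling between the planted categorical effects and
translation physics.  Tests passing on generated data therefore validate
the pipeline's correctness and recovery behaviour, not the biological
accuracy of any particular feature's effect size on real data.

## Problem sizes and numerics

Validation experiments run at these sizes: master-equation comparisons on
6-site lattices (64 states) over a 3×3 (α,β) grid; analytic-limit checks at
L = 200 (low density) and L = 400 (footprint 10); parameter-recovery on a
~2000-gene generated dataset with 20 pipeline seeds; the full 1024-model
search combinatorics with the linear family.  Simulation windows are
chosen so Monte-Carlo standard errors are a few per mille of the measured
current.  Degenerate inputs fail fast: constant design columns, zero
pooled variance, empty joins and invalid windows raise errors rather than
propagating silently.

## Known limitations

* The initiation energetics is a documented surrogate with calibrated
  constants, not a nearest-neighbour thermodynamic model; absolute α
  values are meaningful only relatively.
* The packaged tRNA copy table is a census-style default; strain-specific
  tables should be supplied for quantitative tAI work.
* Quantile normalization is exactly idempotent only for tie-free columns
  (ties re-average reference values on the second pass at or below float
  tolerance of the first).
* No hyperparameter search: all regressors run at library defaults, as the
  comparison design intends.
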