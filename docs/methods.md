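# Methods

`sortscreen` analyses pooled shRNA screens read out by FACS sorting of a
reporter phenotype followed by barcode sequencing of the sorted fractions.
This note documents the statistical model, the synthetic-screen generator, the
numerical conventions, and the design choices made where more than one
reasonable option existed.

## The screen and its statistic

Each cell in the screened population carries (at most) one lentiviral shRNA
construct, identified by a unique DNA barcode. Knockdown of a gene that
normally helps silence the reporter de-represses it, so cells carrying such
constructs drift into the high-reporter-intensity tail. FACS collects two
pools per biological replicate: the brightest ~10% of cells (*high* fraction)
and a simultaneously sampled unselected *input* fraction of the same size.
Barcode amplicons from each pool are sequenced, giving a construct × sample
integer count matrix.

The enrichment statistic is computed per construct:

1. **Quantile normalization** of all sample columns jointly to the rank-mean
   reference distribution: after normalization every column's sorted values
   equal the across-column mean of sorted values. Ties within a column
   receive the mean of the reference values over their tied rank span, which
   is deterministic and row-order independent. With ties present the
   procedure is only approximately idempotent (the collapsed spans perturb a
   second pass's reference); on tie-free data it is exactly idempotent.
2. **Per-replicate log2 fold change**
   `lfc_ir = log2(high_ir + c) − log2(input_ir + c)` with pseudocount
   `c = 0.5` (the standard half-count correction; configurable). Replicates
   are paired by construction — each infection yields both fractions.
3. **One-sample two-sided Student's t-test** of the R replicate lfc values
   against 0 (df = R − 1, default R = 3). An unpaired two-sample variant is
   available behind a flag but is not the default. Degenerate case: if all
   replicate values coincide (to within float noise), P := 0 when the common
   value is non-zero and P := 1 when it is zero; a zero t statistic gives
   P = 1. This avoids NaN propagation.
4. **Primary selection**: constructs with mean log2-fc > 0.3 **and**
   P < 0.01, both strict. A gene enters the primary set when at least one of
   its constructs passes; which constructs passed is recorded per gene. No
   multiple-testing correction is applied at this stage — the selection
   deliberately uses loose raw-P criteria; BH-adjusted q-values are emitted
   alongside for information only.

All thresholds in the package use strict inequalities, matching the ">" / "<"
convention of the cut-offs throughout; boundary values (lfc = 0.3,
P = 0.01, log2-cpm = 3, DEG |lfc| = 1, occupancy = 0.4) are rejected.

## Candidate filtering

The primary gene set is narrowed in two stages, each a pure function with
recorded provenance:

* **Component filter** — keep genes whose cellular-component annotation
  intersects an editable list of nuclear/cytosolic terms
  (`sortscreen/data/component_terms.yaml`). Genes with *no* component
  annotation are dropped (the filter keeps only positively annotated genes)
  and logged separately. The exact term selection of any given GO/PANTHER
  release is unrecoverable, hence the list ships as configuration.
* **Expression filter** — keep genes whose mean log2-cpm across the supplied
  expression datasets (e.g. an F9 and an ESC dataset) is strictly above 3.
  With a single dataset the mean degenerates to that value; a gene missing
  from any named dataset fails the filter.

Reporter-gene selection is the related cross of three tables: DEG log2-fc > 4
and log2-cpm > 2 upon induction, and PRC2 promoter-occupancy median score
> 0.4, ranked by expression.

## Validation statistics

* **DEG thresholding**: up = {log2-fc > 1, P < 0.01}, down symmetric.
* **Module bias**: Pearson chi-square (df = 1, no Yates correction by
  default — a flag enables it) on the 2×2 table (PRC vs Myc or Core module
  membership) × (DEG vs non-DEG). Because real-data P-values can underflow
  float64 (p < 1e-300), `log10_p` is always reported from the chi-square log
  survival function. The contingency orientation is fixed as rows = module,
  columns = DEG status.
* **Term fold enrichment**: fold = (k/n)/(K/N) against a background
  universe, hypergeometric upper-tail P, ranked by fold descending, k = 0
  terms omitted.
* **Metagene profiles**: coverage is ingested from plain 4-column bedGraph
  (piecewise-constant; gaps count as zero) and integrated exactly via a
  cumulative-mass interpolant. Default layout: 2 kb flanks in 50 fixed-width
  bins each plus 100 length-rescaled gene-body bins. Each track's bin means
  are depth-normalized to per-million of total track mass, then
  log2((chip + c)/(input + c)) with c = 0.1 (1 read per 10 million);
  minus-strand regions are reversed so bin 0 is always the 5' flank.
  Uniform rescaling of either whole track therefore cancels exactly.
  Regions extending beyond a track's covered span are skipped with a
  warning; a run in which every region is skipped is an error. The flank
  width and bin counts are declared defaults, not inferred values.

## The synthetic screen generator

The generator exists so every downstream stage is testable with known ground
truth. It emulates:

* a library of ~4,600 genes × 5–7 constructs (≈27,500 constructs per
  module), with log-normal construct abundances truncated — by resampling,
  not clipping, to avoid a point mass at the bounds — to a max/min ratio
  ≤ 100;
* exactly one construct per cell (the screen's MOI of 0.2–0.3 is designed to
  make multiple infection negligible, so it is not modelled);
* a log-intensity model `x ~ Normal(mu0 + delta_g * e_j, tau)`: `delta_g` is
  the gene's full-knockdown de-repression shift (0 for non-modifiers,
  default 1.5·tau for planted modifiers) and `e_j ~ Uniform(0.3, 0.9)` the
  construct's knockdown efficacy, so within one modifier gene some
  constructs are weak — single-construct false negatives are an expected
  feature of the data, which is why gene selection requires only one passing
  construct. The intensity distribution is log-normal (normal in log
  space); this is the simplest model with an analytic gate-tail oracle:
  a construct with effective shift d is enriched in a top-q gate by
  `Phibar((z_q·tau − d)/tau) / q`;
* gating on the *empirical* pooled (1 − gate_fraction) intensity quantile
  (default top 10%), with the input fraction drawn as a simple random sample
  (multivariate hypergeometric) of 10% of all cells after pooling;
* multinomial sequencing of each fraction at a configurable depth (default
  2×10^7 reads per fraction, matching the screen's scale), so column sums
  equal the read depth exactly;
* three biological replicates, each an independent infection (multinomial
  cell assignment) and sort.

Defaults the generator does **not** take from any published value, chosen
once as field-realistic: the truth rate `fraction_modifiers = 0.01` (a real
screen's truth rate is unknowable), the effect-size distribution (fixed
1.5·tau with uniform efficacies), the abundance dispersion sigma = 0.8
(spanning most of the allowed 100-fold range), and `n_cells = 2×10^7` per
replicate (≈700 cells per construct at full library size; the physical
screen sorts ~2×10^8, which is configurable but unnecessary for inference
at these read depths). What the generator deliberately omits: puromycin
selection dynamics, cell-density reporter silencing, staining losses,
photobleaching, PCR amplification bias and sequencing error. Passing tests
therefore demonstrate correctness of the *analysis* under a clean generative
model of sorting and sequencing noise, not robustness to those artifacts.

Simulation problem sizes used in the test suite and acceptance script were
chosen as desk-scale study conditions: 10,000 constructs / 2×10^6 cells /
10^6 reads per fraction for null calibration, 12,000 constructs / 4×10^6
cells / 10^6 reads for planted-modifier recovery, and 10^6 cells for the
gate-tail oracle (with the focal construct diluted to 0.2% abundance so the
pooled empirical gate threshold matches the closed form's null-threshold
assumption to well within Monte-Carlo error).

## Barcode counting

Reads carry the barcode at a fixed configurable offset (two-round PCR yields
fixed-position barcodes); no anchor search, UMI handling or quality trimming
is performed. Default matching is exact (`max_mismatch = 0`) — screening
barcodes are designed for exact matching and this is the reproducible
default; a 1-mismatch mode resolves reads via precomputed Hamming-1
neighborhoods, and `max_mismatch ≥ 2` falls back to a vectorized scan of the
whole library (slow, provided for completeness). Reads tied between
constructs at the best distance are ambiguous and never counted — counts
stay integral; matched + unmatched + ambiguous always equals the number of
records.

## Numerical and reproducibility conventions

* All randomness flows from a single integer seed through
  `numpy.random.default_rng` / `SeedSequence`; the entire simulation is
  bit-reproducible given the seed, and library generation, effect
  assignment, screening and FASTQ emission use distinct seed streams so
  adding one stage never perturbs another.
* Counts are exact integers end to end; normalized values are float64.
* Quantile normalization is applied jointly across all 2R sample columns of
  one screen module, not per replicate; separately screened modules are
  processed separately.
* Pipeline runs write a manifest (config snapshot, input SHA-256 checksums,
  per-stage counts, timestamps) atomically at run end; failures leave the
  partial outputs plus a `FAILED` marker naming the stage.

## Known limitations

* The t-test on R = 3 log-ratios of multinomial counts is only approximately
  calibrated; on a 10,000-construct null screen the empirical type-I rate at
  P < 0.01 lands near 0.01 (the test suite accepts [0.003, 0.03]).
* Quantile normalization guarantees that the across-construct mean log2-fc
  is exactly zero per replicate (both columns share one value multiset), so
  global intensity drift between fractions is removed by construction — a
  screen in which *most* constructs are true modifiers would violate this
  assumption, as it does for any global normalization.
* No variance-moderated (empirical-Bayes) construct test and no gene-level
  aggregate statistic beyond the ≥1-passing-construct rule are provided.
* Replicating published candidate counts from real data requires the
  original annotation versions; the component-term list is editable
  configuration for exactly that reason.
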