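# Methods

## Coordinate model

Annotations use 1-based inclusive coordinates on a circular molecule,
the convention of published mitogenome tables; converters to 0-based
half-open are provided for BED export. A feature with `end < start`
spans the origin and its length is `L − start + 1 + end`. The spacer
between consecutive features is `next.start − prev.end − 1`, taken
across the origin for the last→first junction; negative values are
overlaps. Features are not forced to tile the circle: published tables
sometimes leave terminal nucleotides unannotated (the 17,506 bp study
genome's last feature ends at 17,505), and the model preserves that
verbatim rather than "repairing" printed data.

The gene vocabulary has 39 tokens: 13 protein-coding genes, 22 tRNAs
(single-letter icons; L1/L2 and S1/S2 disambiguate the two leucine and
serine isoacceptors; the ambiguous Lys|Asn tRNA is carried as K and
treated as tRNA-Lys for completeness checks), two rRNAs, the control
region (CR) and the short extra non-coding region O between tRNA-Asn
and tRNA-Cys. Strand is H/L; in gene orders an L-strand gene is a
`-`-prefixed token.

## Composition and codon usage

Percentages and skews use only unambiguous A/C/G/T in the denominator.
All codon work uses the vertebrate mitochondrial code (translation
table 2): AGA/AGG are stops, TGA is Trp, ATA is Met — hence Trp and Met
are two-codon families and Arg is a four-codon family here, whatever
the standard-code intuition says. RSCU is the observed codon count
divided by the mean count of its synonymous family, so each observed
family's RSCU sums to the family size; fully unobserved families are
reported as 0 and flagged rather than left undefined. A CDS whose
length is not a codon multiple ends in an incomplete stop (T-- or TA-),
which is classified as such and never counted as a codon. Annotation-
reported oddities (an AGT "stop", a TAA anticodon for tRNA-Gln) are
carried through as data, not validated. Per-gene composition across
genomes averages percentages per gene and computes skews from the mean
percentages, matching how published per-gene summary tables are built.

## Distances, diversity, Ka/Ks, saturation

* **K2P.** Transitions (A↔G, C↔T) and transversions are counted with
  pairwise deletion of sites gapped or ambiguous in either sequence;
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q). A non-positive log argument raises a
  distinct saturation signal; the distance matrix records such cells as
  NaN with a warning instead of aborting.
* **π.** Nei's unweighted nucleotide diversity: the mean over sequence
  pairs of differences per compared site, evaluated in sliding windows
  (defaults window 200, step 20 alignment columns — configurable, since
  published figures rarely state them). A window with no comparable
  sites is reported as undefined, not zero.
* **Ka/Ks.** Nei–Gojobori (1986): per-codon fractional synonymous site
  counts (mutations creating a stop count as nonsynonymous, so S + N =
  3 × codons), averaged over both sequences; observed differences at
  multi-hit codons are averaged over all substitution orderings,
  skipping pathways through stops (falling back to counting through
  them only if every ordering is blocked); pS and pN are Jukes–Cantor
  corrected. ω = Ka/Ks is flagged undefined when Ks = 0 and such pairs
  are excluded from summaries with their count reported. When either
  sequence of a pair ends in a stop codon the terminal codon column is
  dropped from both. `on_stop="skip"` drops internal-stop codon columns
  (used by the pipeline on noisy inputs); the default is an error.
* **Saturation.** Iss = mean per-column Shannon entropy divided by the
  entropy of the observed base frequencies (the full-saturation
  expectation). The critical value is the 5th percentile of Iss over
  seeded i.i.d. full-saturation simulations of the same alignment
  shape. This is a deliberately simple Monte-Carlo proxy and is **not**
  numerically identical to DAMBE's regression-calibrated Iss.c; it
  shares the decision rule (Iss < Iss.c ⇒ usable signal) and is
  validated behaviourally: identical alignments give Iss = 0, random
  alignments exceed the critical value, low-divergence simulated
  alignments fall below it.
* **NJ.** scikit-bio's neighbor joining behind a thin wrapper that
  validates symmetry and clamps negative branch lengths to zero with a
  warning. It is plumbing for distance-based sanity checks, not a
  substitute for model-based tree inference, which is out of scope.

## Gene-order rearrangement inference

Orders are signed circular permutations. Canonicalization rotates to an
anchor gene (COX1 by default — present and positionally stable in all
three Rana patterns; configurable) after complementing the whole order
if the anchor is on the L strand; classification groups identical
canonical forms and reports frequencies to the nearest percent.
Pattern equality requires identical signs; the three Rana patterns
differ in position only. An `ncr_masked` option drops the O token
before comparison, for records that do not annotate the extra
non-coding region.

**TDRL.** Duplicating a contiguous block in tandem and deleting one
copy of each gene leaves the copy-1 survivors (in ancestral order)
followed by the copy-2 survivors (ditto). A derived arrangement is
therefore reachable iff, reading the derived block as ancestral
positions, there is at most one descent; the witness retention splits
at that descent (leftmost-greedy: the longest ascending prefix is
copy 1). Outside the block the gene order must be unchanged and the
block must stay contiguous in the same circular gap. `infer_min_tdrl`
scans all circular blocks in increasing length and returns every
feasible block at the first feasible length (ties sorted by canonical
start); identical orders give one empty scenario, unexplainable pairs
an empty list. The characterization is continuously cross-checked
against `brute_force_tdrl_oracle`, which enumerates all 2^|block|
retentions (capped at 14 genes).

For the Rana patterns this machinery reproduces the published
scenario: one TDRL of the block from tRNA-His to the control region
turns the ancestral pattern into the dominant one (the inferred
*minimal* block, L1..CR, is a subset of the narrative ND4→CR region;
both are reported, since whether ND4 is inside the duplication or its
boundary anchor is not decidable from the derived order), and a
single-gene transposition of ND5 to behind the control region turns
the dominant pattern into the rare third one. The ND4→CR region of the
ancestral pattern contains 6 tRNAs, 4 protein-coding genes and the
control region. `scenario_report` prefers a transposition when one
exists (the simpler event), otherwise reports minimal TDRLs; only
single-event explanations are searched, per the parsimony argument —
multi-event reconstruction is out of scope.

## Synthetic data

Generators are pure functions of their spec; the default seed is
20211037 (the type voucher number of the first study specimen).

* `make_genome` tiles the circle with abutting features using the study
  genome's gene lengths in any of the three patterns (extra length is
  absorbed by the control region), draws non-coding sequence i.i.d.
  from the study genome's base frequencies (A 24.33 %, C 30.74 %,
  G 15.81 %, T 29.12 %), and fills PCGs with ATG-initiated stop-free
  codon runs ending in TAA or an incomplete T--/TA- stop where the
  template length requires one.
* `evolve_pair` uses the exact finite-time K80 substitution
  probabilities at expected divergence d with transition/transversion
  rate ratio κ (default 4, a typical mitochondrial value), sites
  i.i.d. — a per-site closed form rather than a full CTMC simulation,
  adequate for the d ≤ 0.8 regimes used here. Observed P and Q converge
  to the analytic expectations (checked at 50 kb within 2 %).
* `evolve_cds` draws Poisson(t·L) uniform proposal substitutions;
  stop-creating proposals are rejected, nonsynonymous ones accepted
  with probability ω, synonymous ones always — so the nonsynonymous/
  synonymous rate ratio is ω by construction, and NG86 estimates
  recover it (ω ∈ {0.05, 0.2, 1.0} at 1,000 codons over 50 seeds,
  within sampling error plus a ≤10 % systematic allowance for
  multiple-hit and stop-boundary effects).
* `random_tdrl` / `random_transposition` perturb an order with a
  recorded ground-truth event; round-trips through `tdrl_feasible` and
  `infer_transposition` are property-tested.

What the generator does **not** emulate: indels, rate heterogeneity
across sites and genes, strand-asymmetric mutation pressure, realistic
control-region structure, and phylogenetic (tree-shaped) correlation
among more than two taxa. Passing recovery tests therefore demonstrates
estimator correctness under the stated models, not robustness to every
feature of real mitogenome data.

## Problem sizes and determinism

The test suite and the acceptance script are sized for interactive
runs: K2P recovery uses 10 kb × 100 replicate pairs per divergence
(0.02/0.08/0.17), ω recovery 1,000 codons × 50 replicates, the
TDRL-versus-oracle property ≥500 random instances with orders ≤10 and
blocks ≤8, and saturation simulations 10-30 replicates in tests (100 by
default in the pipeline). Every stochastic routine takes an explicit
seed; the acceptance script derives all sub-seeds from its `--seed`
argument, and reruns are byte-identical.

## Known limitations

* The saturation critical value is a simulation proxy (above), so its
  absolute numbers are not comparable with DAMBE output.
* GenBank import is best-effort name mapping into the fixed vocabulary;
  nonstandard qualifiers may drop features (reported, not guessed).
* The pipeline's distance/π/Ka-Ks stages require equal per-gene lengths
  across genomes (pre-aligned inputs or synthetic data); it does not
  build alignments.
* Published-table fixtures carry their source's internal
  inconsistencies (e.g. a genome length one base past the last
  feature); the package reports recomputed values rather than
  reconciling them.
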