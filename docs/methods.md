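# Methods

## The designed pool

The pool is the measurement instrument: a compact library of short RNAs
that collectively contain every short sequence many times, so that the
binding preference of a protein can be read out as differential
enrichment over k-mers rather than over individual probes.

**de Bruijn construction.** The backbone is a cyclic de Bruijn sequence
of order 11 over {A,C,G,U} (length 4^11 = 4,194,304), in which every
11-mer occurs exactly once and hence every 9-mer exactly 16 times and
every 7-mer exactly 256 times. The published instrument does not record
how its sequence was constructed, so `rbpkit` builds one from first
principles: an Eulerian circuit on the graph whose nodes are 10-mers and
whose four out-edges per node append one base, traversed with Hierholzer's
algorithm using a seeded random edge order at every node. The result is a
deterministic function of `(order, seed)`; two runs with the same seed
are byte-identical. Orders above 12 are refused with a capacity error
rather than attempting a multi-hundred-megabyte allocation.

**Chopping.** The cycle is tiled into probes by a seeded schedule of
(length, step) pairs with lengths in 30–41 and step = length − 10. The
step bound is the load-bearing constraint: consecutive windows then
overlap by 10 nt, so every 11-mer window of the cycle — including those
spanning the cycle origin — lands inside at least one probe, which
preserves every 9-mer occurrence across the probe set (each 9-mer
occurrence sits inside the 11-window starting at its first base). One
full pass of this schedule yields ≈ 164,000 probes; a second,
evenly-strided and offset tiling contributes the remainder and is
truncated so the total is exactly 241,399, the published pool size.
Requesting a count below the first tiling's size or above first tiling +
cycle length raises a design error naming the achievable range.

**Set A / Set B split.** Probes are assigned alternately to the two
sets; because consecutive probes cover overlapping stretches of the
cycle, this splits each 7-mer's occurrences nearly evenly. Violations of
the per-set floor (155 occurrences of each scored 7-mer in each set, for
the full design) are then repaired greedily: a deficient (set, 7-mer)
pair pulls a probe containing that 7-mer from the other set, but only if
the move leaves none of the donor set's own 7-mer counts below the
floor, so repair is monotone and terminates. If the floor cannot be
reached the split fails loudly, listing the violating 7-mers — very
tight floors on very small pools (e.g. an order-8 cycle with a per-set
floor when some 7-mers occur only a handful of times) are genuinely hard
for a no-regression greedy and are reported rather than approximated.
In practice the full design lands with a margin (minimum per-set count
≈ 170–185 across seeds) and the repair phase is almost idle.

**Scoring universe.** The two 7-mers corresponding to the SapI/BspQI
restriction site used in template generation (GCUCUUC and CGAGAAG on the
RNA side) are excluded from the scored set of 7-mers, leaving 16,382.
Exclusion is from the *universe*, not from the sequences: probes may
still contain them. DNA templates are the φ2.5 T7 promoter
(`TAATACGACTCACTATT`) + an AGA or AGG initiator + the U→T
transliteration of the probe; the prefix never enters RNA-side analysis.

**What is not reproduced.** The original pool was additionally modified
to reduce secondary structure and cross-hybridization by an unpublished
procedure; this package does not attempt to reproduce it (the generated
pool satisfies the stated coverage properties but is not
sequence-identical to the commercial array). A coarse hairpin screen
(`max_selfcomp_stem`, longest self-complementary run) is provided as an
optional hook and is disabled by default. Microarray physical layout,
spot replication, and dye chemistry are out of scope.

## The intensity simulator

The simulator emulates the *statistical* structure of a pulldown-array
experiment, not its chemistry:

    intensity = exp(N(background_mu, background_sigma))
              + gain · occupancy · exp(N(0, noise_sigma))

- **Occupancy** is the sum over probe windows of the per-window PWM
  probability (for a consensus motif, `mismatch_penalty^mismatches` per
  window). A sum rather than a max keeps occupancy linear in site count,
  the behavior of equilibrium binding far from saturation.
- **Noise** is multiplicative log-normal on both terms, respecting the
  positivity of fluorescence.
- Defaults place the experiment in a "strong signal" regime: background
  median 100 intensity units (`background_mu = ln 100`,
  `background_sigma = 0.25`), `gain = 1000` (≈ 10× background for one
  perfect site), `noise_sigma = 0.3`, `mismatch_penalty = 0.25`. Nothing
  in the assay literature pins these values; they are declared defaults,
  chosen once to give clearly-passing but not noise-free experiments,
  and all are configurable.

Failure modes: `nonspecific` (gain 0), `artifact` (a fixed bonus to
every probe containing a chosen artifact k-mer), and `split_discordant`
(different motifs planted in Set A and Set B probes — reproducible
within a set, irreproducible between sets). The training-collection
generator labels an experiment "pass" exactly when its mode is
`specific`; passes draw motif length 4–8, sharpness, and gain from a
seeded sampler, and fails cycle through the three failure modes.

**What passing tests do and do not show.** The simulator has no spatial
artifacts, no scanner saturation, no dye effects, and its background is
exchangeable across probes. Recovery and classifier results on synthetic
data therefore validate the *computational* pipeline — that the scoring
recovers a signal that is present and the classifier separates the
encoded failure modes — not the wet-lab robustness of the assay.

**A known property of the relative Z-score.** With everything else
fixed, raising the gain raises the planted 7-mer's Z throughout the
regime from zero signal to the strong-signal default. At gains well
beyond that regime the relationship inverts: probes carrying 1–2
mismatch sites also saturate, the robust scale (MAD) of the whole 7-mer
score distribution grows faster than the top score, and the planted
7-mer's *relative* Z declines even as its absolute enrichment grows.
This is inherent to any distribution-standardized score, not a defect of
the implementation; the monotonicity property is asserted over the
working regime (gain 0–1000).

## 7-mer scoring

The normalization/score recipe is fixed as: natural-log transform
(zeros clipped to half the smallest positive intensity), median
centering (output median exactly 0 on the log scale), flagged spots
dropped. Each scored 7-mer receives the trimmed mean — 2.5% per tail,
`floor(n·0.025)` observations cut from each end — of the normalized
intensities of the probes containing it. A probe contributes once per
7-mer regardless of how often it contains it, because the probe's
intensity is a single measurement. Z-scores standardize robustly:
Z = (score − median) / (1.4826 · MAD) over the universe, so median(Z) = 0
and the robust scale is 1 whenever MAD > 0; a zero MAD falls back to the
standard deviation, and a zero SD yields all-zero Z. All constants
(trim fraction, consistency factor) are arguments.

The merged-set table is recomputed from the union of probes, never
averaged from the per-set tables. The Bonferroni helper reports
`min(1, n_tests · Φ̄(z))`; at Z = 5 with 16,382 tests this is ≈ 0.0047,
below the 0.005 significance bound quoted for the assay.

Degenerate and adversarial inputs: a universe 7-mer with no supporting
probe in the requested subset is an error naming the mismatch (it means
the pool and universe do not belong together), all-excluded profiles are
an error, and permuting probe order changes nothing.

## Motif derivation and comparison

The top ten 7-mers by Z (ties broken lexicographically) are stacked
ungapped: each is aligned to the top 7-mer at the offset within ±3
maximizing position-wise identity (ties prefer the smaller |offset|,
then the negative one), weighted by max(Z, 0) so anti-enriched 7-mers
never contribute, pseudocounted at 0.01 per cell, and flanking columns
with information content below 0.1 bits are trimmed (if every column is
uninformative the central seven are kept, so a well-formed PFM is always
returned). Information content per column is 2 + Σ p log₂ p bits against
a uniform background.

Motif–motif similarity is the mean per-column Pearson correlation of
probability 4-vectors at the best ungapped offset with ≥ 4 overlapping
columns. Exactly-uniform columns have zero variance and are defined to
contribute correlation 0. The empirical p-value counts column-shuffled
nulls (1,000 by default) scoring at least as high; each orientation's
null permutations are drawn from an identically-seeded generator, which
makes the reported p-value exactly symmetric in its arguments. This
in-repo metric replaces an external motif-comparison tool; the QC
classifier consumes only the scalar, and the choice of metric is
recorded in the model metadata.

## The QC classifier

Features (83 dimensions with the default 26 artifact k-mers): A/B
Z-score Pearson r; top-ten overlap; the ten top Z-scores of each set;
skewness and kurtosis (Fisher) of each set's Z distribution; the highest
merged-set Z; for each artifact k-mer, the number of top-ten 7-mers of
each set containing it as a substring (52 features) plus their grand
sum; the information content of each set's motif; and the motif–motif
similarity. The artifact k-mer list shipped in `rbpkit.qc.ARTIFACT_KMERS`
is a placeholder — G-rich runs, GA-rich repeats, homopolymers, UG
repeats, and SapI-site fragments, lengths 4–7 — because no canonical
list is published; supply a curated list for real data.

Training: a class-balanced holdout (default 40 experiments, 20 per
class) is removed before anything else. Features are z-scaled with
training statistics only (constant features dropped with a warning), and
the L1 regularization strength is selected by seeded stratified 5-fold
cross-validation over a log-spaced grid (10⁻³–10³, 13 points),
maximizing mean validation AUROC with ties going to the stronger
regularization. A grid search is used instead of a Bayesian search so
the procedure is deterministic and dependency-light; only the selection
criterion is contractual. AUROC is computed by the Mann–Whitney rank
statistic with midranks, which the tests verify against trapezoidal ROC
integration.

Triage maps the logistic probability with a closed band: ≤ 0.35 fail,
≥ 0.65 pass, otherwise uncertain (manual review). Replicate resolution
is deliberately conservative: only unanimous pass or unanimous fail
resolves automatically; any disagreement or any uncertain call is
flagged for manual review.

On the synthetic 229-pass / 242-fail collection the trained model
reaches holdout AUROC 1.0 with ~13 nonzero weights, led by the A/B
correlation, top-ten overlap, Set-B skewness, and the artifact count sum
— the features a human reviewer uses. This says the encoded failure
modes are separable, not that real experiments are this easy.

## eCLIP k-mer analysis

Peak preparation follows the coordinate conventions of strand-specific
CLIP libraries: BED intervals are 0-based half-open; "upstream" is the
5′ direction of the annotated strand, so minus-strand sequences are
extracted as the reverse complement with upstream on the high-coordinate
side. Each peak is extended 20 nt upstream (the crosslink site sits at
the peak's 5′ edge); the matched negative is the same-length window
whose start lies 300 nt upstream of the extended peak; both carry 50-nt
context flanks intended for RNA folding and later removal. Windows
running off a chromosome end drop the whole peak (positive and negative)
with a count reported. Downstream motif-model training itself is out of
scope; this module writes its input FASTA pairs and a settings manifest.

5-mer profiles count all overlapping windows (windows containing
ambiguous bases are skipped; windows never span sequence boundaries) and
normalize to frequencies — frequencies rather than raw counts are the
default so experiments with different peak counts are comparable, and
Pearson correlation of frequencies is what the clustering consumes.
Experiments with fewer than 1,000 peaks are excluded before clustering
to limit noise. Agglomeration uses centroid linkage on distance 1 − r
(verified in the tests against an independent Lance–Williams
implementation); the dendrogram exports to Newick and the heatmap is
leaf-ordered. The IUPAC rank utility ranks *observed* 5-mers by
frequency (lexicographic tie-break) and reports the 1-based rank of the
first 5-mer matching any length-5 window of the IUPAC pattern, with
`None` meaning the motif is absent from the observed 5-mers.

## Problem sizes used in the tests

The unit and acceptance tests run the full order-11 pool build once
(≈ 20 s) and otherwise use a simulation-scale design — an order-9 cycle
tiled into 15,000 probes with a per-set floor of 5 — on which one
simulated experiment scores in well under a second. The
planted-recovery and null-correlation properties use 100 seeded
replicates each; classifier validation uses the full 229/242 collection
with the 40-experiment holdout. These sizes were chosen so the entire
pipeline is exercised end-to-end at full statistical fidelity while a
complete test run stays in the minutes range.

## Known limitations

- The generated pool is coverage-equivalent, not sequence-identical, to
  the commercial array design (the published structure-minimization
  step is unreproducible from public information).
- The artifact k-mer list is a labeled placeholder.
- The simulator omits spatial/scanner/dye effects; see above for what
  synthetic validation does and does not establish.
- The greedy set-split repair can fail (loudly) on very small pools with
  tight per-set floors; it is not an exact feasibility solver.
- Two-channel dye-swap reconciliation and structure-aware scoring are
  out of scope.
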