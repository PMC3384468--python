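# Methods

## Quantities and model

GC3 of a CDS is the fraction of third-codon positions carrying G or C,
computed over unambiguous bases only: N positions are dropped from both
numerator and denominator, so a sequence's composition is never biased by
ambiguity codes. Terminal stop codons count like any codon (the effect is
O(1/n_codons) and no exclusion rule is standard). GC over the whole
sequence is defined the same way. Dataset and class summaries report the
arithmetic mean and the sample standard deviation (n−1 denominator); a
single-gene summary reports sd 0 with a degeneracy flag.

CDS validation is policy-driven: `strict` (default) rejects lengths not
divisible by 3 so that synthetic and curated inputs fail loudly; `truncate`
drops the trailing partial codon with a warning, accommodating occasional
annotation artifacts in real CDS exports.

## KOG catalog and filters

The 25-class KOG catalog, its Blue/Black/Red/poorly-characterized grouping
and the human reference dataset's per-class gene counts, mean GC3 and sd
are shipped as frozen reference data (the KOG classification is frozen
upstream). Filtering applies, in order: (i) genes assigned to more than
one class, (ii) the poorly-characterized classes R and S, (iii) classes
whose post-(i,ii) count is strictly below `min_class_size` (default 100 —
a class of exactly 100 genes survives). The order follows the narrative
convention of this analysis; the filter report records counts per rule and
exposes the R/S share under both the raw and the post-multi-class
denominator, since the two are equally defensible. Filtering is
idempotent. After the standard filters 20 classes remain (Blue 5, Black 7,
Red 8); that count is the default Bonferroni family size in the butterfly
analysis.

The shipped reference counts sum to 16108 while the table they derive from
also prints a grand total of 16118; the per-class entries are taken as
authoritative, and all shares (e.g. ~19% removed as R+S, 22% Blue) are
computed against the per-class sum.

## Orthology

Orthologs are called as best reciprocal hits: (a, b) is a pair iff b is
a's top-scoring forward hit, a is b's top-scoring reverse hit, and both
e-values are below `evalue_max` (default 1e-05). Ordering is (score
descending, e-value ascending); a query whose top (score, e-value) is
attained by two subjects has no unique best hit and is conservatively
dropped, which makes the output a partial matching by construction and
exactly transposable when the two directions are swapped.

The builtin scorer translates CDS (standard code; internal stops are
errors), indexes subjects by exact length-5 words, and runs Smith-Waterman
(BLOSUM62, gap open 11 / extend 1) only on pairs sharing at least one word
— the standard seeded-search heuristic; unseeded pairs and scores below 30
produce no hit. Scores are mapped to a pseudo-e-value by the
Karlin-Altschul form E = K·m·n·N·exp(−λS) with the gapped BLOSUM62
constants (λ = 0.267, K = 0.041). This transform is monotone in the score
and is used only for threshold filtering; it is not a calibrated
significance, and real analyses should import 12-column tabular output
from a dedicated search tool, for which a reader is provided.

## Category statistics

Pairwise category comparisons use the two-sided Mann-Whitney test, with
direction read post hoc from sample means; the exact null distribution is
used when min(n, m) ≤ 8 and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections. No
multiple-testing correction is applied across the three pairwise tests
(the Bonferroni correction belongs to the butterfly family only); this is
flagged in the output. Verdicts: `PATTERN` (all three significant, means
ordered Blue < Black < Red), `PARTIAL` (Red significantly above both, Black
vs Blue not significant — the marsupial/monotreme-like structure), `NONE`
otherwise.

Statistical power matters when interpreting verdict rates: with category
separations of 0.02 in mean GC3, sd 0.15 and 1200 genes per category, each
adjacent comparison has ≈ 0.9 power at α = 0.05, so the joint probability
of a full `PATTERN` verdict is only ≈ 0.8. Separations of ≥ 0.03 at that
sample size, or the full reference-size genome (≈ 13 000 genes), put the
joint recovery near 1.

ΔGC3 is GC3(reference) − GC3(target) per ortholog pair, grouped by the
reference gene's category; per-category means and standard errors are
reported and Red-vs-Black / Red-vs-Blue distributions compared by the same
rank test. An all-identical delta set (e.g. self-comparison) is flagged
degenerate and not tested. Coding/non-coding correlations (GC3 vs intron
or flank GC) report Pearson and Spearman coefficients with p-values over
complete rows.

## Ternary (de Finetti) analysis

The plotted objects are functional classes, so the Low/Medium/High split
uses the range of *class-mean* GC3 within each genome (a gene-level range
would compress every class mean into the middle interval). The range is
divided into three equal-width intervals, half-open [a, b) with the last
closed; a class mean exactly on an interior boundary goes to the upper
interval — a deterministic, documented convention. Each category's point
is its class count per interval normalized to 1.

Confinement of Red toward the High corner is summarized by
S = mean over genomes of (p_high − p_low) of the Red point — the simplest
statistic monotone in "confined to the High side", antisymmetric under
mirroring to the Low corner. An alternative, the mean Euclidean distance
of the Red point from the Low vertex, is available behind the `stat`
option. Significance: category labels are shuffled over classes
independently within each genome (category sizes and the multiset of
interval assignments preserved), and p = (1 + #{S_perm ≥ S_obs}) /
(n_perm + 1) — the add-one estimator is valid under finite permutations
and never returns 0, so p ≥ 1/(n_perm + 1). Default n_perm = 1000. Under
exchangeable labels the test is calibrated: 500 replicates of 200
permutations reject at α = 0.05 at the nominal rate within Monte-Carlo
error (the permutation distribution is discrete, but with ≈ 14 genomes the
averaged statistic has fine enough support that conservativeness from ties
is negligible).

## Butterfly analysis

Each class's gene-level GC3 values are tested against the genome mean with
a one-sample two-sided t-test, the genome mean treated as a constant: the
class "is compared with the genome", whose mean is computed over all
available CDS (falling back to the KOG subset with a warning when the full
set is absent) and is estimated from one-to-two orders of magnitude more
genes than any class. Bonferroni multiplies raw p by the number of
retained classes (capped at 1). Zero-variance classes report direction
only; classes with fewer than 2 genes are excluded with a warning. Entries
are sorted ascending by deviation — negatives left, positives right, the
butterfly shape. Recurrence across genomes reports, per class, the
percentage of genomes where the class is on the positive side and where it
is significantly higher.

## Band association

The four band types are fixed metadata ordered by increasing GC
(L1+ < L1- < H3- < H3+); band calling is out of scope and the gene→band
map is an input. Two normalizations are emitted: the class-internal
profile (fractions of a class's genes per band) and the per-band
composition (a class's share of a band's genes). The Z-tests use the
latter — a class's frequency *within* a band — with the pooled
two-proportion statistic and no continuity correction (intended counts are
large; a warning is emitted when any χ² expected count is below 5). The
category × {H3-, H3+} association uses Pearson χ² with df = 2. The group
comparison partitions classes by butterfly sign and tests one-tailed
whether the positive group's share of H3+ genes exceeds its share of L1+
genes.

## Synthetic data

Generators are pure functions of (parameters, seed). Per-gene GC3 targets
are drawn Normal(μ, σ) per class, truncated to [0.02, 0.98] to keep
construction away from all-GC/all-AT third positions, and realized
*exactly*: a sequence gets round(target·n_codons) G/C third positions, so
composition tests are sharp and all noise is in the Normal draw. Codons
are built from uniformly drawn sense-compatible prefixes; third bases are
restricted per prefix so no stop codon can arise. Default CDS length is
150 codons (a typical protein length scale; long enough that GC3
quantization, ±1/300, is negligible against σ ≈ 0.15).

Ortholog divergence applies i.i.d. substitutions at a given rate
(codon re-drawn if a stop would arise), then optionally re-balances third
positions so that GC3(reference) − GC3(copy) matches a planted
per-category Δ. Band maps draw from a four-way categorical whose weight
for band j ∈ {0..3} is exp(slope·(gc3 − center)·j): the log-odds between
adjacent bands is linear in GC3, slope 0 is uniform, and center defaults
to the median GC3 so both tails populate both extremes.

What the generator does *not* emulate: codon-usage and amino-acid
composition structure, indels, paralog families, within-class spatial
autocorrelation, and the correlation of GC3 with flanking/intron GC.
Passing tests therefore demonstrate that the statistical machinery
recovers planted compositional structure of realistic magnitude — not that
real genomes exhibit it; published dataset-level numbers (e.g. a human
genome GC3 of 58.5%, specific significant class sets) require the real
CDS sets and annotations and are treated as documented expectations
rather than test gates.

## Known limitations

- The builtin search scorer's pseudo-e-value is a monotone transform, not
  a calibrated tail probability; threshold semantics only.
- The permutation test treats class interval assignments as fixed,
  ignoring the sampling error of class means near interval boundaries.
- The hierarchy verdict's joint power (above) makes `PARTIAL`/`NONE`
  verdicts at small effect sizes partly a sample-size statement.
- The band analysis takes the band map as ground truth; misassignment
  noise propagates directly into the tests.
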