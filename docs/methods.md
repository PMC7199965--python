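# Methods

This note documents the models, parameter choices and numerical decisions
behind `pirdisco`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open (BED convention); SAM and
GTF inputs are converted on ingest so interval arithmetic never needs an
off-by-one correction. Only primary, mapped alignments are kept
(secondary/supplementary/unmapped records are dropped); multi-mapped reads
are therefore counted once, at their primary location. Read sequences are
stored read-strand oriented, so position 1 of a sequence is always the
biological 5′ base; the 5′ end of a minus-strand read is its highest
genomic coordinate (end − 1).

## Filtering cascade

Two pure functions: a length filter retaining 24 ≤ RL ≤ 34 (inclusive
bounds, the piRNA length band), and a strand-specific subtraction that
removes any read sharing ≥ 1 bp with a same-strand annotation whose class
is a non-piRNA ncRNA (miRNA, tRNA, rRNA, snoRNA, other_ncRNA). The 1-bp
rule matches `bedtools intersect -s` default semantics; a minimum-overlap
parameter is exposed for stricter settings. Opposite-strand overlap never
removes a read — antisense degradation of an ncRNA is not evidence that a
read is that ncRNA. Both filters are idempotent and order-independent, and
the composed cascade is verified against a brute-force set definition.

## Quantification and expressed sets

A read is assigned to the same-strand piRNA locus with the largest overlap;
ties go to the lexicographically smallest feature id, making counting
deterministic. An alternative htseq-like `drop_ambiguous` mode discards
reads overlapping more than one locus. CPM uses the post-filter library
size (assigned + unassigned filtered reads) by default; assigned-only is
selectable.

A locus is expressed in a stage iff its mean **raw** count across that
stage's replicates is ≥ 3 (the threshold is applied to raw counts, not
CPM). The catalog is the union over stages; a pooled-threshold variant
(mean over all samples) is also provided since both readings of "average
count among replicates" are defensible.

## Differential expression

The model family is the standard negative-binomial count framework,
implemented from scratch rather than wrapped:

- size factors by median-of-ratios: `f_j = median_i(c_ij / geomean_i)`
  over features with no zero count;
- per-feature dispersion by the method of moments on normalized counts,
  `α = max(0, (s² − μ̄)/μ̄²)`, with s² the pooled within-condition variance
  and μ̄ the grand mean; α = 0 degenerates to Poisson;
- `log2FC = log2((mean_B + ε)/(mean_A + ε))` with ε = 0.5 stabilizing zero
  means (configurable); the ε makes log2FC invariant to uniform depth
  scaling only up to O(ε/μ) — negligible at the default means;
- a Wald statistic log2FC / SE via the delta method,
  `Var(log2(m+ε)) ≈ Var(m)/((m+ε)² ln²2)` with `Var(m) = (m + αm²)/n`,
  referred to a **t distribution with n_A + n_B − 2 df**. With three
  replicates per condition and a moment dispersion estimate, the normal
  reference is anticonservative; the t reference calibrates the type-I
  error to ~0.04 at the 0.05 level in the null simulations.
- Benjamini–Hochberg adjustment (statsmodels) across tested features;
  features all-zero in both conditions are reported untested.
- Calls require all three of |log2FC| ≥ 1, raw p < 0.05 and padj < 0.1;
  both the raw-p and the FDR threshold are applied because volcano-style
  thresholds and FDR thresholds answer different questions and the
  defaults keep both.

Exact numerical agreement with any published DE package is a non-goal;
the acceptance surface is distributional: type-I error within [0.03,
0.07], empirical FDR ≤ 0.15 at padj < 0.1 with a moment estimator, and
recovery of planted 4-fold effects within ±0.3 on the log2 scale.

## Soft clustering

Replicates are collapsed to stage means of log2(CPM+1) and z-scored per
feature (n−1 denominator); flat features (sd < 1e−8) are dropped and
reported. Clustering is classical fuzzy c-means: memberships
`u_ik = 1/Σ_j (d_ik/d_ij)^(2/(m−1))`, centers the u^m-weighted means,
iterated until the largest center shift < 1e−6 (max 1000 iterations).
Defaults c = 8, m = 1.15. A feature exactly on a center receives
membership 1 there.

Initialization matters at m close to 1: pure random restarts frequently
converge to local optima that merge two adjacent trajectory shapes. The
first candidate therefore polishes a k-means solution (scikit-learn,
10 inits); four additional random spread-seeded restarts follow, and the
lowest-objective solution wins. The objective is non-increasing within
every run, and identical seeds give bit-identical results. c is a
parameter, not estimated; a minimum-centroid-distance diagnostic over
c ∈ {2..12} is available to justify the choice.

## Biogenesis signatures

Base composition is tallied per 5′-anchored position over reads carrying
sequences, with T reported as U; position p uses reads with RL ≥ p.

The ping-pong statistic counts, per contig, all (plus-read, minus-read)
pairs by 5′–5′ overlap `s = q − p + 1` (p the plus 5′, q the minus 5′),
for s ∈ 1..20. Enumeration is by multiplicity of distinct 5′ positions,
exactly equivalent to the quadratic all-pairs count (verified against that
oracle). `z10 = (h(10) − mean_{s≠10} h)/sd_{s≠10} h` (n−1 sd), reported as
undefined — never 0 — when the background has fewer than two distinct
values. The off-10 bins are products of 5′-stack multiplicities and are
right-skewed under the null, so single-run z10 occasionally exceeds 2 with
no planted signal; discrimination checks therefore average z10 over 10
seeds (a planted signal yields z10 in the hundreds or more, so the
positive condition is unambiguous per run).

Coverage meta-profiles: per-locus same-strand base depth divided by
(library size/10⁶), rescaled to a fixed 100-point grid in 5′→3′ locus
orientation, averaged over loci.

## Genomic context

Gene intersection uses ≥ 1 bp overlap; sense means piRNA strand equals
gene strand. The shuffle null relocates every locus to a uniform random
start on its original contig (length- and strand-preserving, fully inside
the contig; overlaps among shuffled loci allowed), 1500 times by default;
contig preservation keeps the chromosome composition of the catalog fixed,
which is itself a reported property. Whole-genome placement
(length-weighted contig choice) is selectable. Fold enrichment is
log2(observed/null mean) with the +1/(n+1)-corrected empirical p; an
observed count of 0 is reported as a −inf sentinel with p = 1. Host-gene
coverage uses interval-union semantics (each base counted once), sense and
antisense separately; per-gene tallies count sense piRNAs only.
Overrepresentation is the hypergeometric upper tail P[X ≥ k] per gene set
(intersected with the universe first) with BH across sets; the universe
defaults to the supplied gene models and must be explicit otherwise.

## The synthetic experiment

The generator emulates a 3-stage (PSC → MPC → CPC), 3-replicate small
RNA-seq experiment on a toy genome (three nuclear contigs + one chrM-like
contig, ~316 kb total):

- **piRNA loci**: 300 non-overlapping loci of 30–40 bp. Reads share the
  locus 5′ end with 3′-length variation uniform in 24–34 nt — piRNA 5′
  ends are precisely defined in vivo, and this is what keeps the planted
  ping-pong geometry sharp. The 5′ base is drawn with P(U) = `u5_bias`
  (default 0.8) exactly, so the empirical 5′U frequency is an unbiased
  estimator of the planted bias.
- **Counts**: locus i in a sample of stage t draws
  NB(mean = baseline_i × template_{c(i)}[t], variance = μ + αμ²), α = 0.05,
  baselines log-uniform on [20, 200]. The eight templates use on/off/mid
  multipliers {1, 0.1, 0.01}: monotone up/down, three single-stage and
  three two-stage patterns. The near-binary design makes per-stage
  expression a well-posed recovery question (expected means sit far from
  the threshold 3 except for a thin boundary layer) while keeping the
  eight shapes maximally separated after z-scoring (max pairwise
  correlation 0.866).
- **Hosting**: half the nuclear loci sit fully inside protein-coding or
  lncRNA gene bodies in sense orientation; 30 loci sit inside chrM
  tRNA/rRNA bodies. chrM tRNA/rRNA genes appear in the gene models but
  **not** in the ncRNA exclusion BED — the mitochondrial leak-through
  scenario.
- **Background**: 40 miRNA loci (reads 20–23 nt, 5′-anchored) that the
  length filter removes; degradation fragments 18–40 nt uniform over gene
  and ncRNA bodies at 2 fragments/kb/sample, boosted 20× on chrM (heavy
  mitochondrial turnover), with 10% of fragments antisense (spurious
  second-strand material). Antisense degradation is what gives the
  ping-pong overlap histogram a populated null background.
- **Ping-pong partners**: with probability `pingpong_fraction` (default 0)
  a piRNA read gains an antisense partner whose 5′ end overlaps the
  read's 5′ end by exactly 10 nt; partner sequences are genomic
  reverse-complements (the statistic is purely positional).

One `numpy` generator seeded from `config.seed` drives every draw;
identical configs produce byte-identical outputs, including the full
pipeline output tree.

**What the generator does not model**: sequencing error, quality scores,
adapter remnants, mappability/multi-mapping structure, exon–intron
structure (genes are bodies), overlapping gene models, and any realistic
degradation sequence bias (fragments are uniform — a stand-in, since no
quantitative degradation model is established). Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to artifacts real libraries may contain.

## Study-condition sizes used in tests

Recovery and calibration checks run at desk scale, chosen to keep the
whole suite around a minute while leaving the statistics well-posed:
expressed-set recovery on the default 300-locus experiment
(sensitivity/precision micro-averaged over the three stage sets — per-stage
values can dip slightly below 0.95 because chrM degradation deliberately
contaminates mitochondrial locus counts and NB noise flips loci whose
expected mean sits near 3; both are designed features of the conditions);
DE calibration on 2000 features × 20 seeds; clustering recovery on 400
trajectories at noise sd 0.2; ping-pong on a dense 30 kb + chrM condition
with degradation at 40 fragments/kb so the null histogram is populated;
enrichment nulls on a 200 kb genome with 20 kb of each gene class (expected
intersection counts large enough that the log-ratio's small-sample bias is
negligible) and 1500 shuffles for the forced-placement check
(log2FE = log2(1/f) = 3 at gene fraction f = 1/8).
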