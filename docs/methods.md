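# Methods

## The analysis model

The package treats near-splice pathogenicity as a three-legged inference
problem, each leg with its own data and null model:

1. **Standing variation (MAPS).** Under neutrality, a class's singleton
   proportion is determined by local sequence context: mutable contexts
   recur and look common. The calibration regresses context-level singleton
   proportions of synonymous variants on trinucleotide mutability by
   weighted least squares (weights = context variant counts, intercept
   included) and predicts a per-variant expected singleton probability,
   clipped to [0, 1]. MAPS is the mean observed-minus-predicted singleton
   indicator. Because the calibration is a weighted regression with
   intercept, the calibration class's MAPS is identically zero — a property
   the tests pin to 1e-10. The error bar is the normal approximation
   1.96·√(p̂(1−p̂)/N) on the raw proportion; this matches the plotted-error-
   bar convention of cohort studies but understates uncertainty when the
   calibration set is small relative to the class (see Limitations).
   Class contrasts use a one-sided bootstrap (resample both classes B times,
   count Δ ≤ 0, add-one smoothing so p ∈ [1/(B+1), 1]).

2. **De novo burden.** Expected counts are 2 · n_trios · rate · f(depth)
   per (position, alt), summed over any cell. The coverage factor uses the
   natural logarithm: f(d) = 0.119 + 0.204·ln d on 1 ≤ d < 50 reaches 0.917
   just below the cutoff and is continuous with the flat branch at d = 1
   (a base-10 logarithm would leave an implausible 0.47 → 1.0 jump at 50×).
   Boundary conventions: d = 1 uses the logarithmic branch, d = 50 the
   uncorrected branch. The burden test is the exact two-sided Poisson test —
   the sum of probabilities of all counts no more likely than the observed
   one, with a 1e-10 relative tolerance guarding floating-point ties —
   pinned against a pmf-recurrence enumeration oracle to 1e-12.
   All (class × gene set) cells are Benjamini–Hochberg adjusted in a single
   family. PPV = (observed − expected)/observed is clamped at 0 and reported
   as missing when observed = 0, where the ratio is undefined.

3. **Score calibration.** Severities (for motif scores, the percent
   reduction 100·(ref − alt)/|ref|) are sorted ascending, ties broken by
   site key, and assigned greedily to 20 brackets: bracket b closes once
   cumulative mutability reaches b/20 of the total, the boundary item
   staying in the lower bracket. This makes per-bracket mutability sums
   equal to within one maximal single-site rate and the assignment fully
   deterministic. The de novo AUC walks brackets from most to least
   pathogenic with x-steps of 1/20, anchors the cumulative curve at (0, 0)
   and integrates by trapezoid; a rectangular variant is exposed because the
   two differ by up to 1/40 and neither convention is canonical. Cross-tool
   comparisons restrict to mutations scored by every compared tool.

Gene sets come from a dominant/recessive developmental-disorder gene list;
genes on both lists are treated as recessive. pLI sextiles rank exons by
their gene's pLI with ties broken by gene id, and split into groups whose
sizes differ by at most one; sextile ratios carry exact (Garwood) Poisson
intervals. The diagnostic split (canonical vs noncanonical diagnoses) uses
the Wilson score interval with continuity correction, matching R's
one-sample `prop.test`, verified against frozen R values to 1e-6.

## Splice-relative coordinates

Coordinates are 1-based inclusive (GTF convention) throughout. The label
vocabulary has 57 labels: 25 intronic acceptor, 11 exonic acceptor, 11
exonic donor, 10 intronic donor; "acc" is the first and "don" the last base
of the exon. A genomic position receiving two distinct labels — within a
short exon (14–21 bp, where the exonic windows overlap) or across exons —
is dropped entirely rather than resolved by priority. Exons shared between
transcripts are deduplicated by (chrom, start, end, strand) with tags
unioned before filtering; both the per-transcript and deduplicated exon
counts are observable (`parse_gtf_exons` vs `select_exons`). Strand
handling is validated by a round-trip property: annotating a minus-strand
exon equals annotating the reverse-complemented locus as plus strand.

## What the synthetic cohort emulates

The generator is the package's stand-in for a managed-access trio cohort; it
reproduces the statistical structure the estimators consume, not genomic
realism:

- **Genome.** 120 genes (default), 4–7 exons of 60–150 bp, introns of
  60–150 bp, on both strands of two contigs. Every intron is GT..AG on the
  transcript strand, with a consensus-biased donor run (don+5 G in 80% of
  introns) and a pyrimidine-rich tract (85% C/T) at acc-3, acc-5..acc-17;
  genes are flanked by virtual acceptor/donor context so first and last
  exons behave like internal ones. Decoy gene models (level 3, 13-bp exon,
  NOVEL status, non-coding) exercise the filters. Intron length must be
  ≥ 36 bp so adjacent exons' intronic windows cannot collide, unless an
  overlap test case is explicitly requested.
- **Mutation rates.** A bundled synthetic 64×3 triplet table, log-uniform
  over [1e-9, 1e-7] with strand-complement symmetry enforced; a published
  table in the same TSV format can be swapped in.
- **Cohort variants.** P(site polymorphic) grows with √(relative
  mutability) (capped), scaled so the default yields ~17,000 variants.
  The neutral singleton proportion is a decreasing affine function of
  mutability (0.65 down to 0.35 across the rate range); allele counts are
  geometric with success probability equal to the target singleton
  proportion, so AC − 1 is geometric and P(AC = 1) is exact by
  construction. Selection inflates the singleton probability toward 1 by a
  per-class coefficient (defaults: stop-gained and CSS 0.30, don+5 0.20,
  missense 0.10, PolyPy PyPu 0.08, other PolyPy 0.02, synonymous 0);
  deleterious variants are additionally purged from pLI > 0.9 genes.
  Exonic-window variants receive a coding consequence (synonymous /
  missense / stop-gained at 0.65/0.28/0.07) from a seeded draw, emulating
  an external consequence annotator. Six percent of variants receive
  FS ≥ 10 or a non-PASS filter.
- **De novo mutations.** Counts per (position, alt) are Poisson with mean
  expected × fold(class, gene set); default folds mirror the dominant-gene
  enrichment pattern (CSS 20, don+5 9.29, PolyPy PyPu 3.46) with recessive
  and non-DD cells at the null. Cohort sizes default to 7833 trios and
  13,750 carrier parents.
- **Side tables.** pLI ~ Beta(0.25, 0.25) (U-shaped, like the real
  distribution); 15% of genes dominant, 15% recessive; per-exon coverage
  mixes 85% well-covered (15–100×) with tails below 15× and below 1× so
  both correction branches run; per-tool scores are monotone transforms of
  a latent per-change deleteriousness (class coefficient + N(0, 0.02)
  jitter) plus Gaussian noise expressed as a fraction of each tool's range,
  with configurable per-tool coverage.

Each artifact draws from its own RNG stream derived from the master seed by
a fixed label, so outputs are byte-identical across runs and adding a
generator never shifts another's stream.

**What it does not emulate** — and hence what passing tests do not show
about real data: haplotype structure and linkage, indels, multi-allelic
sites, X-linked inheritance, realistic exon/intron length distributions,
branchpoints and splicing enhancers/silencers, correlated errors between
scoring tools, and any real relationship between sequence and splicing
outcome. The synthetic cohort demonstrates that the estimators recover
known parameters under their own model assumptions, not that those
assumptions hold in any particular cohort.

## Problem sizes

The default 120-gene genome (~20,000 annotated positions, ~17,000 cohort
variants) was chosen as the smallest simulation whose per-class variant
counts give the Monte-Carlo acceptance checks the statistical power their
thresholds presuppose — the real cohorts these analyses target are two to
three orders of magnitude larger — while keeping the 100-seed calibration
loops and the 500-cohort type-I-error sweep in the low tens of seconds.
Parameter-recovery checks that need large expected de novo counts scale the
expectation table rather than the genome.

## Known limitations

- The Wald/normal CI on MAPS ignores calibration-model uncertainty; with a
  calibration class not much larger than the test class, empirical coverage
  of |MAPS| < CI95 under the null runs near 90%, not 95%.
- The exact Poisson test is conservative at small expectations (discrete
  support), so null FDR-significant fractions sit well below the nominal
  5%.
- PPV inherits the noise of the fold estimate; at observed counts below ~10
  it is better read as a direction than a number.
- The clinical-database comparison takes significance strings at face value
  (token matching on pathogenic/likely pathogenic, excluding conflicting
  records) and uses submission counts as an allele-count proxy; both are
  crude.
- The depth-correction coefficients (0.119, 0.204) are consumed as given
  constants; re-estimating them from synonymous de novo mutations is out of
  scope.
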