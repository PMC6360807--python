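# splicesel

Quantifying selection and pathogenicity at canonical and noncanonical
splice-site positions.

Single-nucleotide variants at the canonical GT/AG splice dinucleotides (CSS)
are routinely flagged as damaging, but the surrounding positions — the
extended donor (notably donor+5), the last base of the exon, and the
polypyrimidine tract upstream of the acceptor — also disrupt splicing, and
standard annotation pipelines largely ignore them. `splicesel` implements the
statistical machinery for measuring how much disease burden these
noncanonical positions carry, aimed at statistical geneticists and
rare-disease analysts working with cohort variant tables and trio de novo
calls. Because the real cohorts of this kind are managed-access, the package
ships a first-class synthetic-data module that generates seeded toy genomes
and cohorts with the statistical structure the analyses assume, so the whole
pipeline is testable end to end on a laptop.

## What it computes

**Splice-relative annotation.** Exons from a GENCODE-dialect GTF are
filtered stringently (protein-coding gene and transcript, KNOWN status, not
annotation level 3, principal/CCDS tags, ≥ 14 bp, median coverage ≥ 15× at
both splice sites in every capture set). Each surviving exon contributes a
labelled window: acc-25..acc-1 (intronic), acc..acc+10 (exonic),
don-10..don (exonic) and don+1..don+10 (intronic), with positions carrying
two labels dropped. The polypyrimidine tract is acc-3 plus acc-5..acc-17;
PyPu denotes a transcript-strand pyrimidine→purine change inside it.

**MAPS** (mutability-adjusted proportion of singletons). For a variant class
with singleton indicators s_i and trinucleotide mutabilities μ_i,

    MAPS = (1/N) Σ s_i − (1/N) Σ p̂(μ_i),

where p̂ is a weighted least-squares line fitted to context-level singleton
proportions of synonymous variants. MAPS > 0 means an excess of rare
variation, i.e. purifying selection. Class contrasts are tested by a
1000-iteration bootstrap; depletion from high-pLI (> 0.9) genes gives an
orthogonal constraint signal.

**De novo burden.** The null expectation at a site over n trios is
2 · n · μ(context, alt) · f(d), with the coverage ascertainment factor
f(d) = 0.119 for d < 1, min(1, 0.119 + 0.204 ln d) for 1 ≤ d < 50, and 1
otherwise. Observed counts per (class, gene set) are tested with the exact
two-sided Poisson test, Benjamini–Hochberg corrected in one family, and
summarised as fold enrichment and PPV = (observed − expected)/observed —
the estimated fraction of observed mutations that are pathogenic
(PPV = 1 − 1/fold).

**Score calibration.** Arbitrary per-(position, alt) pathogenicity score
tables are split into 20 brackets of equal cumulative mutation rate
(bracket 20 = most pathogenic; motif scores enter as the percent reduction
100·(ref − alt)/|ref|), then summarised by MAPS per bracket and by the AUC
of the cumulative de novo curve, with or without the CSS positions.

**Database comparison.** Pathogenic/likely-pathogenic records from a flat
clinical-database extract are matched to the splice positions, exonic
protein-altering records removed, and the canonical:noncanonical ratio —
raw and submission-weighted — compared with the cohort-derived diagnostic
split by Fisher's exact test.

## Worked example

`examples/` holds one short script per capability. `02_maps_selection.py`
simulates the default cohort (120 genes, 13,750 carrier parents), filters it
(PASS, FS < 10), calibrates on synonymous variants and prints:

```
class            n      MAPS    +/-95%   pLI>0.9
synonymous       4036    0.0000   0.0154     0.221
missense         1685    0.0412   0.0235     0.209
stop_gained       438    0.1489   0.0432     0.178
CSS              1153    0.1455   0.0268     0.184
don+5             261    0.0857   0.0577     0.188
polypy_PyPu      2222    0.0430   0.0205     0.210
polypy_other     1855   -0.0012   0.0227     0.217

bootstrap P (PyPu > other PolyPy changes): 0.001998
```

Synonymous MAPS is 0 by construction (it is the calibration class); the
canonical dinucleotides and stop-gained variants show the strongest
singleton excess, donor+5 sits between missense and stop-gained, and within
the polypyrimidine tract only pyrimidine→purine changes are under visible
selection — the pattern the simulation's selection coefficients encode, and
the package's estimators recover. The high-pLI column shows the mirror
image: the most selected classes are the most depleted from constrained
genes. `03_dnm_burden.py` prints the burden table (the simulated CSS cell in
dominant genes recovers a ~30-fold enrichment, exact Poisson P ≈ 8×10⁻⁷,
PPV 0.97) and the 73%/27% diagnostic split with its confidence interval;
`04_score_calibration.py` compares five simulated score tools by bracket
MAPS (Spearman ρ = 0.80 for a noise-free tool) and de novo AUC (≈ 0.75,
dropping to ≈ 0.67 when CSS positions are excluded).

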