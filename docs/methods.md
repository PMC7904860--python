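# Methods

## The measurement model

The assay chemistry the package models detects a methylated cytosine
through three steps: (i) 5hmC is glucosylated and thereby hidden from
the enzyme, so only true 5mC is visible; (ii) MspJI binds ᵐCNNR (a
methylated C followed two bases later by a purine on the same strand)
and cuts both strands 16 bp downstream of the methylated cytosine,
leaving a 4-nt 5′ overhang; (iii) a double-stranded adapter carrying a
T7 promoter, sequencing adapter, 3-nt UMI and 8-nt cell barcode is
ligated at the cut, so sequencing starts at the cut and proceeds back
toward the methylated cytosine. A read therefore maps **antisense** to
the strand that carried the 5mC, with its 5′ genomic end at the cut
coordinate, and the caller inverts this geometry exactly:

* minus-strand read with 5′ end p → plus-strand 5mC candidate at p − 16;
* plus-strand read with 5′ end p → minus-strand 5mC candidate at p + 16.

A candidate is accepted only if the reference carries a cytosine at
that position on that strand; everything else increments an
off-geometry counter (zero on simulated data, a data-quality readout on
real data). The offset is a single shared constant (`util.CUT_OFFSET`)
used by both the simulator and the caller, and the agreement of the two
is enforced by a round-trip test rather than by construction. Only the
exact 16-bp offset is used — no ±window — trading recall for precision;
the 4-nt overhang is carried as an annotation only, since it matters
for ligation, not for coordinate arithmetic.

## Methylome model in the simulator

Each CpG dyad has a *parental* strand, drawn once per (chromosome,
allele, cell): semiconservative replication means the strand that
retained the old DNA is the same along a whole chromosome copy, which
is exactly why maintenance loss produces chromosome-scale strand bias
rather than site-level salt-and-pepper. The parental cytosine is
methylated with probability `m_parent`; given a methylated parent the
daughter-strand cytosine is methylated with probability `e_maint` (the
DNMT1 efficiency axis: 1 = perfect maintenance, 0 = knockout). CpA
cytosines are methylated independently per strand with probability
`d_cpa` — non-CpG methylation is deposited de novo and not copied, so
it is intrinsically strand-asymmetric. Finally each methylated site is
converted to 5hmC with probability `h_frac`; those sites are invisible
to the digest.

Defaults describe a serum-mES-like condition: `m_parent = 0.8` (bulk
CpG methylation of serum ES cells), `e_maint = 0.95` (efficient but
imperfect maintenance), `d_cpa = 0.02`, `h_frac = 0.05`, `capture_eff =
0.5`, `dup_rate = 1.0` amplification duplicates per molecule, and a
0.5 % strain-SNP rate for hybrid-cross genomes. Tests and the
acceptance script override these where a specific condition is the
point (e.g. `e_maint = 1` for the maintenance null, `e_maint = 0` for
the knockout contrast, `capture_eff = 1, dup_rate = 0` for round-trip
exactness).

What the generator deliberately does **not** emulate: sequencing
errors and indels (alignment is out of scope — the simulator emits
truth SAM directly), enzyme kinetics and the double-site digestion
requirement, fragment-size selection, and amplification bias beyond
duplicate counts. Consequently, green tests demonstrate the
correctness of the coordinate inversions, counting statistics and
estimators — not robustness to mapping artefacts or coverage bias in
real libraries.

Duplicates share UMI, position and sequence exactly, which isolates the
deduplication contract: one call per distinct (cell, chromosome,
position, strand, UMI). With a 3-nt UMI the space is only 64 deep, so
two distinct molecules at the same coordinate (e.g. the two alleles of
a SNP-free region) collide with probability 1/64 and are merged; this
is a property of the assay design, not of the implementation, and is
why UMIs are never error-corrected.

## Strand-bias statistics

`f = n₊/(n₊+n₋)` per (cell, region, allele, context), where a region is
a chromosome or a fixed-size 0-based half-open bin (last partial bin
kept). Regions with fewer than `min_sites` (default 50) total sites are
masked but reported, so matrices keep their shape. The test against
the symmetric null is the binomial G-test with χ²₁ asymptotics; for
totals below 25 the asymptotics are poor and an exact two-sided
binomial test is used instead. The G statistic is evaluated with the
larger count first so that p(a, b) ≡ p(b, a) to the last bit. p-values
are floored at 1e-300 to stay in (0, 1]. No multiplicity correction is
applied by default (records are flagged at raw α = 0.05); a
Benjamini–Hochberg helper is provided.

The null rejection rate of the asymptotic G-test at n = 200 and
α = 0.05 is 0.056 rather than 0.050 — binomial discreteness — which is
also why the null p-value distribution has a KS distance of ≈ 0.06 from
uniform (the largest CDF jump is the pmf at the mode). Calibration
tests bound these quantities rather than pretending the statistic is
continuous.

Per-cell plus/minus Pearson correlations are computed between the
per-region plus- and minus-strand *counts*; at least three usable
regions are required, and regions with zero total are excluded. Note
this statistic needs genuine between-region variation in total counts
(in real genomes, chromosome length) to be informative — with
equal-sized regions both vectors are pure noise around a common mean.
Simulated genomes for correlation analyses therefore use unequal
chromosome lengths.

## Heterogeneity analyses

Cells × regions matrices hold f with missingness (masked or absent
records → NaN); cells with fewer than `min_regions` (default 3)
observed regions are dropped. For k-means, missing entries are imputed
with 0.5, the maintenance expectation — a neutral value that shrinks
incomplete cells toward the unbiased population.

Clustering runs on the **deviation** representation |f − 0.5| by
default. Which strand of a chromosome retained the methylation after a
division is an arbitrary label — the two daughter cells inherit
complementary patterns — so cells that lost maintenance form a single
population in the magnitude of their bias but occupy scattered corners
of the raw-f hypercube. On raw f, k-means provably cannot group them
(the within-class distances exceed the between-class ones); on
|f − 0.5| the unimodal and bimodal populations are two compact balls.
The raw representation remains available (`features="bias"`). k is
chosen by mean silhouette over a candidate range (default 2–5), with
best-of-`n_restarts` k-means per k and a fixed seed; a degenerate
matrix (all cells identical) reports k = 1.

Sister-cell detection computes pairwise Pearson r over shared unmasked
regions (≥ 3) and reports a pair iff r ≤ `r_threshold` (default −0.8)
*and* the two cells are mutually each other's most-negative partner;
remaining conflicts are resolved greedily by ascending r, so the output
is a matching. The false-pair rate under the null is governed by the
region count: with 19 chromosome-level regions, noise essentially never
reaches r ≤ −0.8 (probability ≈ 3 × 10⁻⁵ per pair), while with 5
regions it would be common — anti-correlation screening is a
karyotype-scale analysis.

## Hairpin-bisulfite dyad analysis

Hairpin ligation joins the two strands covalently, so one read pair
reports both cytosines of a CpG dyad: (M,M) symmetric, one M hemi,
(U,U) unmethylated. The maintenance fraction is
`n_sym / (n_sym + n_hemi)` — symmetric among methylated — which equals
`e_maint` in expectation under the model above regardless of
`m_parent`; the all-dyads denominator is also reported. Bisulfite
read-out flips each strand's state independently with probability
`conv_err` (failed or over-conversion), mixing the three classes
through a known 3×3 confusion matrix A(ε). The corrector solves the
method-of-moments equation observed = A · true for the true class
frequencies, clips to [0, 1] (with a warning when clipping fires), and
attaches a seeded multinomial-bootstrap percentile CI (default 1000
resamples), widened if necessary to contain the point estimate. With
`conv_err = 0` the correction is the identity. `conv_err` must be
below 0.5, where the confusion matrix becomes singular.

## Numerical and interface conventions

Coordinates are 0-based half-open in memory and 1-based in every TSV
written (declared in each file's comment header). All randomness flows
through `numpy.random.default_rng` seeded from explicit integers;
identical seeds reproduce outputs byte-for-byte, which the pipeline
surfaces as SHA-256 hashes in its provenance manifest. Pipeline
configs reject unknown keys and are re-written, fully resolved, beside
the outputs.

Problem sizes used by the test suite and acceptance script — 5–19
chromosomes of 1.2–24 kb, cohorts of 4–50 cells, 10⁴ null bins, 10⁵
hairpin dyads — are chosen so each statistical check has the power its
tolerance implies (e.g. ≥ 2000 methylated CpG dyads per chromosome for
the maintenance-null median, 4-Monte-Carlo-sd bands elsewhere) while a
full run stays in the minutes range on a laptop.

## Known limitations

* Real read demultiplexing tolerates barcode errors only within
  Hamming distance 1 and requires uniqueness; degraded barcodes are
  discarded, not rescued.
* Allele assignment is per call, requiring consistent SNP evidence
  across its supporting reads; conflicting evidence yields `unknown`
  rather than a majority vote, which is conservative under UMI
  collisions.
* No computational 5hmC subtraction: incomplete glucosylation in real
  data would appear as (a small amount of) false 5mC.
* The hairpin module consumes dyad observations (or the simulator's
  pairs); parsing raw hairpin FASTQs — linker search, MspI anchoring,
  bisulfite alignment — is upstream of this package.
* Binned analyses assume uniform mappability; there is no smoothing or
  segmentation across bins.
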