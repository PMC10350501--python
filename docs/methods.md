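# Methods

## Genetic model of the simulated population

Individuals are pairs of haplotypes per chromosome, coded 1 (donor allele) or
0 (recurrent allele) at each marker.  Meiosis follows Haldane's
no-interference model: the crossover count per chromosome is Poisson with
mean equal to the map length in Morgans (`length_bp / 1e6 × cM_per_Mb / 100`)
and breakpoints are uniform along the chromosome.  The crossing scheme is
fixed — P1×P2 → F1, two backcrosses to the recurrent parent, one selfing —
and every BC₂F₂ offspring descends from its own independently simulated
BC1F1/BC2F1 ancestors.  Under this pedigree the donor-allele dosage at an
unlinked marker is distributed (13/16, 1/8, 1/16) over {0, 1, 2}, giving the
expected donor-allele frequency of 0.125 that the tests verify by exhaustive
enumeration.

The default recombination rate is 1 cM/Mb (configurable).  The default toy
genome — 3 chromosomes × 2 Mb with 400 SNP markers each — keeps full-pipeline
tests well under a minute; its deliberate consequence is that each toy
chromosome spans only ~2 cM, so markers within a chromosome are nearly fully
linked and a detected region typically covers the whole chromosome.  That is
the correct behaviour at this scale, not a bug: at genome scale the same
machinery produces sub-chromosomal regions.

## Trait model

Each individual's trait vector is `base_means + dosage(QTL) × effects + ε`,
with ε multivariate normal.  Defaults emulate stressed (150 mmol NaCl)
seedlings: the seven trait means/SDs and the full 7×7 Pearson correlation
structure are taken from a published BC₂F₂ salt-stress phenotyping study of
cotton (SL 21.31±3.46 cm, RL 26.94±4.03 cm, SFW 7.35±3.67 g, RFW 3.42±1.71 g,
SDW 0.88±0.46 g, RDW 0.25±0.12 g, CHL 36.75±6.28 SPAD; e.g. r(SFW,SDW)=0.929,
r(SFW,RFW)=0.723).  The matrix is positive definite as published and is used
as-is.  Negative draws of length/weight traits are truncated at zero; CHL is
untruncated.  Replicate measurements add independent noise with SD equal to
5% of each trait's across-line SD — small relative to line variance, which
matches the convention of averaging replicates before analysis.

The default planted QTL adds one phenotypic SD per donor-allele copy to SFW,
SDW and RFW (a large-effect locus; the bulk-separation tests use 2 SD to
represent an unambiguously large effect).  What the generator does **not**
emulate: genotype × environment interaction, dominance or epistasis,
polygenic background, allopolyploid homoeologous mapping artifacts, and the
two-reference alignment design (both bulks share one coordinate system).
Passing tests therefore demonstrate the statistical machinery under a clean
additive single-locus model, not robustness to those real-data complications.

## Bulk sequencing model

At each marker the bulk's true donor-allele frequency is mean(dosage)/2 over
its members.  Total depth is Poisson with the configured mean (default 40×;
a gamma-Poisson option adds overdispersion), and the donor-allele depth is
binomial at the error-adjusted frequency `f(1−e) + (1−f)e`, a symmetric
allele-flip error with default e = 0.001 (a typical post-filter Illumina
substitution rate).  Parents are emitted as fixed opposite homozygotes under
the same depth/error model.

## Read cleaning

Steps, in order: adapter removal (leftmost exact match of the adapter — or a
≥5-bp terminal prefix of it — at the 3′ end; the simplest reproducible rule),
5′ trim of bases below Q20 or N, 3′ trim below Q3 or N, truncation at the
first 4-base window with mean quality < 20 (scanning 5′→3′), drop at N
fraction ≥ 10%, drop when more than 40% of bases are below Q15, drop below
30 bp.  After window truncation the 3′ rule is re-applied to any newly
exposed tail; without this, a read could end in a sub-Q3 base that a second
pass would trim, and cleaning would not be idempotent.  Idempotence and the
contiguous-substring property are enforced by property tests.  The
low-quality-fraction rule is read as a whole-read drop rule; boundary
conventions are "drop when N fraction ≥ 0.10" and "drop when Q<15 fraction
> 0.40".  Phred+33 only.

## Scan statistics

SNP-index, ΔSNP-index and site filtering are as in the README.  Orientation
is fixed: "Mut" is the donor allele, so index 1 means pure donor signal in a
bulk and a positive Δ means donor-allele enrichment in the resistant bulk.
Sites are kept when the parents are opposite homozygotes (depths re-oriented
when the donor carries the reference allele) and both bulks have total depth
≥ 10.  Windows are 1 Mb sliding by 5 kb, half-open internally, 1-based
inclusive in reports; chromosome-end partial windows are retained and
flagged; windows with fewer than 5 sites are masked so single-site windows
cannot drive calls.

Null thresholds use a depth-conditional Monte-Carlo null for an unselected
BC₂F₂ bulk pair: a segregating site descends from a selfed heterozygous
BC2F1, so each bulk member's dosage is 1:2:1 and the bulk allele frequency is
Binomial(2n, ½)/2n for bulk size n (default 30); each bulk's donor read count
is binomial at the window's rounded mean depth.  |Δ| quantiles at 95/99/99.9%
are estimated from 10,000 replicates per depth pair and made monotone
non-increasing in total depth by isotonic regression, which removes
Monte-Carlo jitter.  Windows exceeding their threshold are merged into
regions when overlapping or within one step; region length in Mb is rounded
half-up to 2 decimals (decimal, not binary, rounding — 1.935 → 1.94).

Because window means average out read noise while the genotype-sampling
component is shared among linked sites, single-site thresholds applied to
window means are conservative; the calibration test confirms the realized
windowwise false-positive rate at the 95% level is below nominal.

## Numerical and design choices

- Ti/Tv ratios and Mb lengths round half-up via `decimal` (binary-float
  `round()` disagrees at printed ties).
- Multiallelic VCF records are decomposed into per-alt biallelic rows on
  ingest so transition+transversion and het+hom bookkeeping identities hold
  exactly; "homozygosity number" counts homozygous-alt genotypes only.
- Impact classes (HIGH/MODERATE/LOW/MODIFIER) are consumed from `IMPACT=` or
  SnpEff-style `ANN=` INFO fields, never computed.
- Bulk selection aggregates the three selection traits as the mean of
  per-trait z-scores (a deterministic composite; the realized per-trait
  ranges of each bulk are reported alongside), with ties broken by line ID.
- Skewness/kurtosis are the bias-adjusted (SPSS-convention) estimators;
  correlation p-values are one-tailed in the observed direction.
- Degenerate inputs: zero-total-depth sites are skipped with a reason code;
  zero-variance traits yield NaN correlations; constant vectors yield NaN
  skewness/kurtosis; zero-depth windows get no threshold and stay masked.
- Determinism: every stage seed is derived from one global seed via
  `SeedSequence`; gzip outputs zero the mtime header so identical runs are
  byte-identical (asserted on manifest digests).

## Problem sizes used in tests

Statistical acceptance checks run at 2,000 lines × 20 seeds for locus
recovery, 200 lines × 20 seeds for null calibration, 10,000 lines for the
pedigree frequency check, and 10,000–200,000 Monte-Carlo replicates for
threshold validation — sizes chosen so the full suite completes in a few
minutes while leaving sampling error well inside the asserted tolerances.

## Known limitations

- The null model conditions on a segregating site (heterozygous BC2F1
  ancestor); it does not model the mixture with monomorphic sites, linkage
  between windows, or selection-induced correlation outside the QTL region.
- Thresholds are keyed to rounded per-window mean depths, not per-site depth
  profiles.
- Read cleaning is single-end only; no paired-end synchronization, adapter
  discovery, or quality recalibration.
- The simulator emits a variant table directly; it does not simulate
  alignment (no SAM/BAM), mapping bias, or reference-genome divergence.
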