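# Methods

This note records the models, defaults and design choices behind
`retroscan`, in the order the pipeline runs.

## Signal model

A 3′ transduction from a single full-length L1 source element is observable
in short-read data only because the last stretch of the element (here 669 bp,
the "unique tail") is uniquely mappable while the L1 body is not. The
package's entire detection path is built on that asymmetry: a read mapping
inside the unique tail whose mate maps elsewhere is evidence that tail
sequence exists at a second genomic location.

Truncated insertions in this class retain the element's 3′ end, so both
junctions of an insertion are flanked by uniquely mappable transduced
sequence. The expected number of informative discordant pairs per carried
insertion is therefore modeled as

    E[pairs] = depth · vaf · (F − 2R) / (2R)

where F is mean fragment length, R read length and vaf the fraction of cells
carrying the event: physical (fragment) coverage is depth·F/(2R), half of the
carrier-haplotype fragments straddle a junction with one full read on each
side, and there are two junctions. At the defaults (40×, F = 400, R = 100)
this gives 40·vaf pairs, drawn Poisson. The practical floor for reliable
calling with the ≥ 3-pair rule is vaf ≈ 0.3 (mean 12 supporting pairs;
P(< 3) ≈ 5·10⁻⁴).

## Synthetic cohorts

`synthetic_data` simulates at the *alignment* level — mapped coordinates,
strands, MAPQ — not reads. Upstream alignment and its error modes
(mappability bias, base errors, split reads, PCR duplicates) are outside the
model, so passing tests demonstrate correctness of the calling logic under
the stated signal model, not robustness to alignment artifacts. Donor
genomes are coordinate arithmetic over insertion records; literal junction
sequence (5′ truncation offset, poly(A) tail, optional 3′-end inversion) is
rendered only by `junction_sequences`/`write_junction_fasta` for worked
examples.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| coverage_depth | 40× | deep-coverage WGS design the pipeline targets |
| read_length | 100 bp | standard paired-end short reads |
| fragment length | 400 ± 50 bp | makes the 500 bp breakpoint flank meaningful; unreported in the design emulated, chosen as a typical short-insert library |
| source element | 6 kb, tail 669 bp | full-length L1 anatomy with a uniquely mappable 3′ region |
| poly(A) tail | 30 bp | a tail is part of the event anatomy; its length is unreported, 30 bp is typical |
| noise pairs | Poisson(30)/sample genome-wide, Poisson(1) tail-anchored | scattered mismapping background; low enough that 3 noise pairs rarely co-cluster within 1 kb on a megabase genome, which is what makes the support threshold meaningful |
| genotype markers | ~1.25 kb spacing | genotyping-array density; termination needs two opposing homozygotes < 2 kb apart, so spacing must be below 2 kb |

Coverage is simulated per bin as Poisson(depth·multiplier·length)/length,
with bins split at the unique-tail boundaries; the tail multiplier is
1 + Σ vaf/2 over carried insertions (one extra haploid copy per event).
Tumor purity is folded into vaf; there is no separate purity knob. A single
heterozygous germline event therefore gives an expected tail ratio of 1.5
(3 tail copies over a diploid background), verified in the tests by
averaging over 100 seeds.

Determinism: every consumer-facing generator is seeded with
`default_rng([seed, sha256(seed:label)])`, so a fixed configuration is
byte-identical across runs and stages can be regenerated independently.

## Detection

The caller applies the count-based rule directly: source-anchored pairs
(exactly one mate in the source interval, both mates ≥ MAPQ floor), distal
mates single-linkage clustered per (sample, tissue, chromosome) with a 1 kb
window, clusters with ≥ 3 pairs promoted to calls. The 1 kb window is ≈ 2×
fragment length, so mates from one event always co-cluster while events
> 1 kb apart stay separate. Clustering is order-independent (sort by
position, tie-break by pair id) and is tested against an exhaustive
transitive-closure oracle.

The tumor/normal threshold asymmetry (tumor MAPQ ≥ 20 and ≥ 3 pairs; normal
no MAPQ floor and ≥ 2 pairs) deliberately over-calls the normal: the
normal call set exists only to subtract germline signal, so sensitivity is
everything and specificity is irrelevant there. Whether the final
count-based rule should also impose a tumor MAPQ floor is ambiguous in the
design being emulated; the default applies it to tumor tissue only,
mirroring the asymmetry. Somatic filtering expands each normal-call target
by 500 bp and labels intersecting tumor calls germline — retained, not
discarded, because the cohort's germline polymorphisms (carrier lists,
frequencies) come from exactly those calls, merged across samples at 1 kb
tolerance.

## Target statistics

Targets are classified at the call interval's midpoint: exon beats intron
when overlapping genes disagree; the base at an exon start belongs to the
exon and the base at its exclusive end does not (half-open arithmetic).

The intron-preference test is the uncorrected two-cell goodness-of-fit
chi-square (df = 1). Yates' correction is deliberately not applied. The null
intronic fraction is a required input: inside the pipeline it defaults to the
synthetic reference's true intronic genome fraction; `invert_intron_chi2`
recovers the null fraction implied by a reported (counts, χ²) pair — at
51/83 intronic and χ² = 54.2 it is 0.26, with upper-tail p = 1.8×10⁻¹³.

The recurrence permutation test redraws the genic/intergenic split per event
(K ~ Binomial(n_events, p_gene)) rather than fixing the genic count; both
readings give p ≈ 0.025 at the cohort configuration, and the redrawn split
follows the stated reassignment scheme. The intergenic probability is
1 − p_gene = 39% (a stated "59%" alternative cannot hold; probabilities must
sum to one, and 61% matches the observed 51/83 genic fraction). Gene
identity is irrelevant under uniform placement, so the gene universe is a
count, not a list. The implementation is vectorized (chunked draw matrix,
row sort, adjacent-duplicate scan; unused slots padded with distinct
negative sentinels) and runs 10⁶ permutations in ≈ 2 s; the closed-form
collision probability, computed in log space, serves as its independent
oracle and agrees within 3 Monte-Carlo standard deviations across
configurations.

## Copy number

The statistic is length-weighted mean depth in the tail region over
length-weighted mean depth of the whole chromosome, making it invariant to
global depth rescaling of a sample. Group comparison is Welch's t-test
(unequal variances) — the safer default where only "t-test" is specified,
and immaterial at the simulated effect sizes — reporting t, p and the 95% CI
of the mean difference. When run as a pipeline, group membership (carrier vs
non-carrier) is derived from the detection module's calls, not from truth
files. Note that with one extra heterozygous copy the expected ratio gain is
0.5 at vaf = 1; impure or subclonal tumors shift it downward, which is why
vaf is exposed, and no claim is made about matching any particular observed
gain.

## Haplotype analysis

Opposing homozygotes ({0,2} at one marker) are a pairwise notion, so shared
haplotypes are computed per sample pair and the carrier/other comparison
uses all within-group pairs; this is one defensible reading of a group-level
"shared haplotype" analysis, and the alternative (per-sample extents against
a carrier consensus) is not implemented. Termination requires *two*
opposing-homozygote sites strictly closer than max_gap = 2000 bp (an
isolated opposing site is tolerated as a probable genotyping error); the
boundary is the inner marker of the terminating pair, so the reported shared
region excludes both incompatible sites. Missing calls never oppose and
never terminate. Strict (<) inequality is used for the gap; the choice is
unreported in the design being emulated and is fixed here by test. Removal
of close relatives is an input contract (the caller supplies unrelated
samples); no kinship inference is attempted.

**Known limitation — pairwise dependence.** Pairwise extent lengths that
share a sample are positively correlated, and the Welch t-test treats them
as independent. With 4 carriers the carrier group holds only 6 highly
inter-correlated pairs, so the test is anti-conservative: on null data
(no founder haplotype, 4 vs 85 samples, dense markers) the empirical
rejection rate at α = 0.05 is ≈ 9% rather than 5% (measured over 500
replicates; the corresponding acceptance test records this as a failure by
design rather than hiding it). Power is unaffected in practice: a planted
2 Mb founder haplotype is detected (p < 0.05, carriers longer) in ≥ 90% of
seeded runs and its interval is recovered to ≥ 90% by the intersection of
carrier-pair extents. A permutation of group labels over pairs would repair
calibration and is the natural extension.

## Pipeline and problem sizes

`run_pipeline` wires the stages over a simulated cohort and writes a
manifest (config echo, derived seeds, filter-chain counts, all statistics);
re-running the same config reproduces every output byte-identically. The
test and acceptance suites run on deliberately small problems — toy genomes
of 1.5–5 Mb, cohorts of 3–8 samples for detection, 30–89 samples for the
group tests, 2,000–8,000 markers for haplotypes — sizes chosen so the full
suite completes in a few minutes while keeping every Monte-Carlo margin
(binomial noise on rejection rates, Poisson noise on support counts) small
relative to the asserted thresholds.

## Out of scope

Read-level error models and base qualities, mappability bias, split-read
signals and breakpoint refinement, target-site duplications, CNV
segmentation/GC correction, phasing and IBD HMMs, kinship estimation, and
any upstream alignment/recalibration machinery.
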