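# Methods

## Scope and data model

All coordinates are 0-based half-open on the transcript; GFF3 I/O converts
to and from the 1-based closed convention. Metagene position 0 is the first
nucleotide of the start (or stop) codon. Transcript biotypes come from a
supplied two-column table (transcript id, biotype), never from sequence.
Only transcript-space models are supported: no spliced genome coordinates,
no isoform collapsing, and residual reads that a genome-mapping step would
rescue are treated as unmapped and excluded from every downstream
statistic.

## Read processing

Adaptor trimming truncates at the leftmost full adaptor occurrence
(`CTGTAGGCACCATCAAT` by default), falling back to the longest 3′-suffix
match of at least 3 nt — the conventional minimum-overlap behavior of
adaptor trimmers; untrimmed reads are kept whole, and reads shorter than
18 nt after trimming are discarded. Mapping is hierarchical over the
category order rRNA, tRNA, snRNA, snoRNA, miRNA, lncRNA, mRNA: a read is
assigned to the first category with a coding-strand hit at Hamming
distance ≤ 1, and within a category the tie-break is exact-over-1-mismatch,
then smallest transcript id, then leftmost position, so every read gets
exactly one location. The implementation is an exact/1-mismatch substring
search over in-memory indexes; it is intended for desk-scale references
(hundreds of transcripts), not for genome-scale alignment.

## P-site calibration and metagene profiles

Per read length L, the offset from the 5′ end to the P site is the mode of
`cds_start − 5′ end` over reads spanning a start codon, restricted to the
biologically plausible 10–14 nt range; ties break toward the smaller
offset, and lengths with fewer than 50 usable reads (configurable) are
excluded. Offsets are estimated per replicate. P sites falling outside the
transcript are dropped, not clipped. Metagene windows default to
[−48, +33] around starts and [−33, +48] around stops; both are parameters,
since the appropriate span depends on UTR lengths. Frame fractions are
computed over CDS P sites only.

## Occupancy statistics

Region percentages assign each P site (a single nucleotide) to
UTR5/CDS/UTR3; this differs from whole-read counting by at most one read
length at region boundaries. Cross-stage comparisons use two-sided Welch
t-tests on per-replicate percentages (α = 0.05). The start-codon fraction
is reported against two denominators — all mRNA P sites, and P sites
inside the start-anchored window — because both are informative and they
differ by roughly a factor of five. Start-codon-enriched genes require
strictly >10% of the gene's P sites on the start codon and strictly >30
start-codon P sites; the denominator is all P sites on the transcript.
The Kozak-context test compares nucleotide counts per position (window
−10..+10, no position 0) between enriched and background genes with a 4×2
chi-squared test, flagging positions with any expected cell < 1 as
low-powered but still reporting them; the background set is the expressed
mRNAs (ribo rpkm > 5 in the baseline stage) minus the enriched set. The
consensus string shows the enriched set's modal nucleotide at significant
or invariant positions and `n` elsewhere. The pausing index uses frame-0
CDS P sites only; stop-codon entries are measured with the P site on the
stop codon itself.

## Differential translation

Size factors are median-of-ratios over features with nonzero counts in all
samples; they are defined up to a common scale, so only factor ratios are
meaningful. Dispersions are per-feature method-of-moments estimates pooled
over the design groups with unbiased within-group variances, floored at
1e-8, then shrunk 50% toward the mean dispersion of features in the same
expression decile — a deliberately simple stabilizer in place of
empirical-Bayes machinery, and the main reason p-values will not match a
reference DESeq2 run digit for digit. GLMs are negative-binomial with log
link and size-factor offsets, fitted by IRLS (≤100 iterations, deviance
tolerance 1e-8); non-converged features are reported with p = NA and
excluded from the BH denominator. The TE test removes the
assay:condition interaction in the reduced model (χ²(1) LRT); pairwise
stage comparisons within one assay use the Wald test on the stage
coefficient. "Two-fold change" for TE applies to the interaction (TE
ratio) coefficient. The five-stage course is analyzed as consecutive
pairwise contrasts, each fitted separately. On seeded interaction-null
simulations (2000 features, 3 replicates, dispersions 0.02–0.2) the raw
p < 0.05 rate sits near the nominal 5% (the test suite asserts the
0.03–0.07 band), and planted log₂ TE shifts of 2 at dispersion 0.05 are
recovered within ±0.3 with power above 0.8.

## uORFs, lncRNAs, peptides

An ORF runs from an AUG through the last nucleotide of its first in-frame
stop; the length in bp includes the stop codon, so the ">60 bp (20 aa)"
rule keeps a 63-bp ORF encoding 20 amino acids and drops a 60-bp one.
Every qualifying AUG yields its own ORF — no longest-only collapsing;
nested and overlapping uORFs are counted independently. Non-AUG starts are
not considered. uORF prediction is restricted to the 5′-UTR subsequence,
which automatically excludes ORFs crossing the CDS start. The uORF/mORF
shift test keeps genes whose uORF and CDS both exceed rpkm 5 in every
replicate of both stages, tests each region with the NB Wald contrast, and
flags genes whose two adjusted p-values are below 0.05 with strictly
opposite fold-change signs; when a gene has several qualifying uORFs the
longest enters the test. lncRNA TE analysis applies the same rpkm filter
in both assays, then the interaction LRT; the ORF-bearing subset is
cross-referenced. Peptide evidence is exact substring containment of an
observed peptide (≥7 aa) in a predicted ORF peptide, with isoleucine and
leucine kept distinct — no spectral search or PSM-level FDR is emulated.

## The synthetic generator

The generator is the package's test bed: it produces references and reads
with the statistical structure the analysis assumes, and a truth table
recording every read's source, P site, length, frame and region, plus all
planted gene-level parameters.

Stage presets encode the germination time course: footprint length
mixtures over 27/28/29 nt with the 28-nt class dominant early and the
29-nt class dominant late; per-length P-site offsets {27: 12, 28: 12,
29: 13} (the printed extremity position fixes −12 for the dominant
lengths; exact per-length values are generator parameters); frame-error
rates of 0.08 (dry) / 0.05 (imbibed); region weights of
3.57/92.30/4.13% for dry seeds and 96–98% CDS for imbibed stages;
start-pause weights set so that ~7% of dry mRNA P sites (about 1–2%
imbibed) sit on the start codon; codon pause weights elevating
glycine/aspartate/tyrosine codons in dry seeds (with a mild UAG stop
weight), glycine/proline/aspartate at 6 h, and G/D/Y/P later; and stop
geometry given by an explicit −4-upstream pause weight and a fraction of
+1-shifted footprints near stops — observables, not an eRF1 mechanism.
Contaminant fractions total ~24.5% (rRNA 15%, tRNA 5%, small RNAs ~2.5%,
lncRNA 2%): real libraries are far more contaminated, but a desk-scale
simulation must keep most reads on mRNA for every statistic to have
support. Reads are emitted 27–29 nt only, since those are the analyzed
lengths. Class and region are drawn once per read; placements that would
exit the transcript resample position/length within the same class and
region, so the emitted class/region marginals match the preset exactly.
Quality strings are constant ("I") and never used. The generator does not
model sequencing errors, ligation/PCR bias, or splice isoforms — passing
tests demonstrate the pipeline's correctness on its stated model, not
robustness to those artifacts.

Count matrices are negative-binomial with log-normal baselines, per-sample
size factors uniform on [0.7, 1.4], per-feature dispersions uniform on
[0.02, 0.2], and per-stage expression effects shared between assays so the
interaction is null unless a TE shift is planted; planted shifts apply to
the ribo assay from the second stage onward.

## Problem sizes and determinism

Simulated libraries of 20 000 reads over ~60 mRNAs suffice for exact
offset recovery and stable metagene geometry; calibration experiments use
500–2000 features with 3 replicates; the uORF-shift and Kozak null checks
use 100 seeded repetitions each. The pipeline's single seed is split per
stage/replicate through numpy's SeedSequence, outputs are written with
stable ordering and fixed float formatting, and the run log stores a
sha256 per artifact, so a config reproduces its bundle byte for byte.

## Known limitations

Offset calibration needs enough start-covering reads per length
(configurable support threshold); stages with weak start-codon occupancy
need correspondingly deeper libraries. The dispersion estimator is simple
by design and can be mildly anti-conservative for very low counts. The
mapper is not a general aligner; indels are not handled. Welch t-tests on
three replicates have limited power and are reported as in the original
design rather than replaced by a stronger test.
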