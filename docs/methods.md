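# Methods

## Assay model

The assay captures a panel of short (7–12 bp) mononucleotide repeats (MNRs)
with single-molecule molecular inversion probes (smMIPs). Each sequenced
amplicon carries, 5′→3′ on the read-1 strand, a 6-base molecular barcode
(UMI), the probe extension arm, the captured insert, and the ligation arm;
read 2 sequences the same molecule from the other end. Each marker's insert
contains a linked SNP 5′ of the repeat tract, so the SNP's insert offset is
invariant under repeat-length mutations.

### Read extraction (reference-free)

Because the panel fully determines every captured insert, reads are
assigned to markers by direct arm matching rather than by alignment to a
reference genome: at most one substitution per arm is tolerated and no
indels (arms are primer-like, and an arm indel would corrupt the UMI
frame); a pair matching two markers at equal distance is set aside as
ambiguous. Both orientations of a pair are tried. Assigned pairs are
projected onto the insert strand and a position-wise consensus is taken:
only base calls supported by both reads survive; disagreements are masked.
Both reads must span the captured molecule (equal read lengths after arm
anchoring); non-spanning pairs are discarded and counted.

Repeat length is the number of consecutive repeat-unit bases between exact,
unmasked matches of the left and right flank anchors. A read is
unmeasurable — excluded from the length histogram but kept in the
accounting — when either anchor is missing, the tract contains a masked or
non-unit base, or the measured length exceeds the reference by more than 10
bases (treated as chimeric). The linked-SNP base is read at its insert
offset; a masked base there is "uncalled". The exclusion rule for pairs
that disagree inside the repeat tract is this package's contract; an
interrupted or partially masked tract has no well-defined length.

UMIs are counted as distinct exact 6-mers, with no error clustering: the
count is used as a template-number estimate for quality control, not for
consensus calling of repeat lengths, so sequencing errors in the barcode
inflate the census slightly at high depth (documented limitation).

### Traits and classifier

Per marker *m*: the deletion frequency `d_m` is the proportion of measured
reads with repeat length strictly below the reference (insertions stay in
the denominator); the allelic-bias p-value is the two-sided Fisher exact
test on the 2×2 allele × deletion table, computed only for samples called
heterozygous at the linked SNP. Heterozygosity (not specified by the assay
description; our rule) requires a minor-allele read fraction ≥ 0.2 and ≥ 5
reads per allele, which is robust to ~0.6% base-call error and allelic
dropout.

Training estimates, per marker: the threshold `t_m` as the 95th percentile
of the MSS training `d_m` values (numpy linear interpolation between order
statistics, i.e. fractional rank `0.95(n−1)+1`), and per-class trait
probabilities with Laplace smoothing κ = 1:
`P(T=1|class) = (count + κ)/(n_observed + 2κ)`. Bias-trait probabilities
are conditioned on the trait being observed (heterozygous samples); a
marker whose bias trait is never observed in training falls back to an
uninformative 0.5/0.5 and is flagged. Scoring sums decadic log-likelihood
ratios over markers with observed traits, starting from the prior
log10(0.15/0.85) (prior P(MSS) = 0.85); markers absent from a sample are
skipped, never imputed. Boundary conventions are fixed: `D=1` iff
`d_m > t_m` (strict), `B=1` iff `p < .05` (strict), and a score of exactly
0 is reported as "indeterminate" since only >0 and <0 are defined calls.
Classification uses raw read counts, not UMI-collapsed counts; barcode
collapsing is available for BRAF but adds nothing to repeat-trait
separation here because the pair consensus already removes independent
base-call errors and stutter is shared by both ends of a pair.

Sensitivity/specificity of a labeled cohort are reported with exact
Clopper–Pearson 95% intervals (for x = n successes the lower bound is
(α/2)^(1/n)).

### Stepwise marker selection

Backward–forward search starting from the full panel. The objective is
leave-one-out (LOO) cross-validated accuracy, tie-broken by the mean
absolute score (margin); a backward step removes the marker whose removal
keeps accuracy at least as high as the current value (ties resolved by the
smallest deletion-trait log-likelihood-ratio magnitude, then name), a
forward step re-adds a removed marker only on strict improvement, and the
search stops at a fixed point (with a visited-set guard against
remove/re-add cycles). Because each marker's naïve-Bayes parameters do not
depend on the rest of the subset, each LOO fold is fitted once and a
per-fold, per-marker contribution matrix makes subset evaluation exact and
cheap; this is algebraically identical to refitting per subset. The
objective is pluggable ("training" reclassification accuracy is also
provided).

### Quality control and BRAF

QC: mean distinct UMIs over panel markers (zero-coverage markers count 0),
pass at ≥ 75; advisory resampling-derived minima of 10 (24-marker scoring)
and 15 (6-marker) are reported alongside. A QC failure never suppresses the
classification — the call is emitted with a FAIL flag.

BRAF c.1799T>A: the raw variant allele frequency counts each read end's
base call at the variant offset individually, so in variant-free samples it
tracks the per-base error rate toward the specific alternate base (~0.62%/3
for uniform substitution errors). Error reduction groups calls by exact
barcode; groups with < 2 calls or a tied vote are dropped and the remaining
groups vote by majority. A sample is positive when the chosen VAF is
strictly > 5%.

### In-silico detection limits

Read mixing draws whole read records (repeat length and SNP allele jointly
— allelic bias would be destroyed by mixing marginal histograms) from an
MSI-H and an MSS sample, binomially at fraction *p* and at a depth matched
to the shallower sample. UMI resampling subsamples distinct barcodes (with
their reads) per marker to a target census. Detection limits are reported
on the evaluated grid only, without interpolation, as the smallest
condition with > 95% correct calls. The equal-volume serial-dilution
arithmetic (50%, 25%, …, 0.78%) is provided as a closed form.

## Synthetic cohort generator

The generator emulates the data-generating process the traits rely on, with
defaults at the assay's working point:

| parameter | default | meaning |
| --- | --- | --- |
| templates per marker | 150 | molecules sequenced per locus |
| reads per template | Poisson(3) | sequencing depth per molecule |
| per-base substitution error | 0.0062 | observed base-calling error rate |
| stutter per amplicon copy | 0.005→0.03 | 1 bp slippage, linear in repeat length 7→12 |
| MSI-H mutant-template fraction | U(0.3, 0.7) per marker | somatic deletion rate before dilution |
| tumor content | U(0.3, 1.0) per MSI-H sample | dilution by normal cells |
| SNP heterozygosity probability | 0.3 | per sample-marker |
| haplotype linkage of deletions | 0.9 | source of allelic bias |
| UMI length | 6 | collision-free within a sample-marker |

Somatic deletions (1–3 bp, geometric sizes) are drawn per template and
preferentially on one haplotype; stutter is drawn per amplicon copy and is
therefore shared by both reads of a pair, while substitution errors are
independent per read end — exactly the asymmetry that pair consensus can
remove (base-call errors) and cannot (stutter), and that the deletion/bias
traits exploit. MSS samples receive stutter only, with no haplotype
linkage, so their bias p-values are (conservatively) uniform. Every byte of
output is a function of the configuration and its seed; UMIs are assigned
without replacement so distinct-barcode counts are an exact template
census.

What the generator does **not** model: FFPE deamination damage, indel
sequencing errors outside the repeat, base-quality variation (flat
qualities), PCR-efficiency differences between loci, and real inter-marker
sensitivity spread. Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline under the stated error model, not
clinical performance on real tumors; the real assay's detection-limit
constants are properties of its cohorts and are not reproduced here. The
fixture panel is synthetic — real marker loci and probe sequences are not
redistributed.

## Problem sizes and numerical choices

The validation experiments use fixture-scale cohorts chosen as the smallest
sizes at which each claim is meaningful: training 51 MSI-H/47 MSS and
validation 50/49 for end-to-end accuracy; 10-marker, 10+10-sample cohorts
for the stepwise-vs-exhaustive (1,023 subsets) comparison; a 24-marker,
10+10 cohort with 2×2 sample pairs, seven mixing fractions and five UMI
targets (4 replicates each) for detection limits; 20 negative replicates at
400 templates for the BRAF error model; Fisher agreement is verified
exhaustively for all 2×2 tables with total ≤ 40 in the test suite and ≤ 25
in the acceptance script. Two-sided Fisher p-values use point-probability
ordering with a 1+1e−9 relative tolerance in the enumeration oracle to
absorb floating-point ties. Scores are sums of log10 ratios of smoothed
probabilities, all strictly inside (0,1), so no clipping is needed. Model,
panel, and report files are versioned JSON/TSV; loading refuses unknown
format tags rather than guessing.

## Known limitations

* Arm matching tolerates only substitutions; a real indel in an arm loses
  the pair (counted as unassigned).
* Pairs that do not span the full captured molecule are discarded rather
  than partially used; with capture sizes ≤ 150 bp and paired reads this
  is the common case by design.
* Distinct-UMI counts are inflated by barcode sequencing errors at high
  read-to-template ratios and deflated by barcode collisions at high
  template numbers (4⁶ = 4,096 barcodes).
* The score is not calibrated to tumor purity, and MSI-low is not modeled
  as a separate class (such samples are labeled MSS upstream by
  convention).
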