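# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the design choices made where more than one reasonable option existed.

## MSI from targeted sequencing (`msi_ngs`)

The scorer follows the mSINGS family of methods. The per-locus statistic
is the **distinct-allele count**: the number of observed repeat lengths
carrying at least `support_fraction` (default 0.05) of the locus's reads.
The count is compared with a baseline built from normal controls; a locus
is unstable when its count strictly exceeds `mean + k_sd * sd` (default
`k_sd = 3`). The specimen-level call is the unstable fraction over
evaluable loci, MSI-high when strictly greater than `msi_threshold = 0.20`.

Fixed-by-design constants: loci under `min_depth = 30` reads are excluded
from numerator and denominator (clinical quality filter), and the 0.20
cutoff is a validated clinical threshold, both treated here as given.
Choices that were open and are therefore parameters:

* *"statistically greater"* is operationalized as mean + 3·SD of the
  control allele counts. Three SDs is the conventional outlier bound and
  makes the rule fully deterministic and testable.
* The SD is the **population** SD (ddof = 0): the control set is treated
  as the reference population itself, not a sample from one. With few
  controls the sample SD would systematically widen the band; either
  convention is defensible, this one is fixed and documented for
  reproducibility.
* `min_evaluable = 20`: below 20 evaluable loci a specimen-level fraction
  is too coarse (each locus moves it by ≥ 5 percentage points), so the
  call is *indeterminate* rather than forced. The clinically used minimum
  is not public; this is a package choice.
* Ties exactly at the baseline cutoff are **stable** (the rule is strictly
  "greater").

## MSI by PCR (`msi_pcr`)

The five-marker mononucleotide panel is interpreted with an explicit
novel-allele rule, since the commercial kit's internal scoring is not
published: a marker is unstable when the tumor has a peak (≥
`intensity_fraction = 0.10` of the tumor maximum) at a length at least
`shift_min = 3` units from **every** normal peak. Three units separates
real somatic shifts from the stutter ladder, which decays to < 10%
intensity within two units in both the generator and typical
electropherograms. A specimen is MSI positive with ≥ 2 of 5 unstable
markers; fewer than 2 evaluable markers yields *indeterminate*.

## Hypermutation (`hypermutation`)

Filters, with boundary semantics fixed from their definitions: tumor VAF
≥ 0.10 retained (inclusive); common-variant flag set → removed (the
common-variant database membership arrives as a precomputed boolean, since
shipping a full dbSNP snapshot is out of scope and the flag preserves the
filter's logic exactly); normal allele balance ≥ 0.40 in any germline
sample → removed (inclusive removal). The filter is order-preserving and
idempotent; records with fractions outside [0, 1] are rejected with a
logged reason rather than raising, so one corrupt record does not abort a
cohort run.

Classification: hypermutated iff the protein-altering count strictly
exceeds 300. All protein-altering records count, SNV or indel — the
definition is stated in terms of protein-altering mutations without
distinguishing the two, and the ambiguity is noted here. Patient-level
status uses the any-site rule with a per-patient concordance flag.

PDX mode (no matched normal): the allele-balance filter is disabled and
only the common-variant comparison applies. The resulting novSNV count
still contains on the order of a couple hundred residual germline
variants per genome, so it is reported separately and never compared to
the 300 threshold; patient-level status for PDX lines comes from prior
characterization supplied by the caller.

## MMR lesions (`mmr_lesions`)

**Split-read clustering.** Clip points on the same chromosome and clip
side within `window = 10` bp merge into a cluster whose breakpoint is the
modal clip point (ties toward the smaller coordinate). Clusters pair when
each one's modal partner coordinate lands within the window of the other
(reciprocal support); only pairs with ≥ `min_support = 4` reads on both
sides are emitted, with `n_support` the weaker side. Type assignment:
different chromosomes → translocation; same clip side on both ends →
inversion (an inversion junction joins two same-orientation ends); else
deletion when the lower breakpoint is right-clipped, tandem-duplication
otherwise. The defaults are strict against the generator's noise and are
exposed as parameters; this is a desk-scale reconstruction, not a
re-implementation of assembly-based SV callers.

**Exon CNV.** Exon state from the tumor/normal depth ratio: homozygous
loss ≤ 0.15, loss ≤ 0.70, else neutral. Runs of ≥ `min_consecutive = 2`
like-state exons merge into segments ("MSH2 exon 8-16 del"). The 0.70 /
0.15 cutoffs sit midway between the expected ratios of diploid (1.0),
one-copy (0.5) and zero-copy (~0, plus noise floor) states at realistic
noise; single-exon dips are not segment-reported, guarding against
capture-efficiency artifacts.

**MSI-artifact exclusion.** Frameshifts inside cataloged homopolymer
tracts (the MSH6 exon-5 poly-G and exon-7 poly-A tracts) are mosaic
consequences of MSI, not drivers, and are set aside before zygosity
counting. The exclusion is catalog-based and applied regardless of the
specimen's MSI status: a tract indel is unreliable evidence in any
specimen, and making the rule status-independent keeps it deterministic.

**Zygosity.** Homozygous copy loss alone → biallelic; otherwise ≥ 2
distinct events → biallelic; 1 → monoallelic; 0 → none. Events are
de-duplicated first, and a rearrangement counts once per gene even when
both breakpoints hit it. The verdict is monotone in evidence.

## Assay scores (`assay_scores`)

IHC: score = Σ intensity(0/1/2) × percent of cells, range 0–200, nuclear
staining only; duplicate cores are averaged; damaged/missing cores are
dropped and a sample with no valid core is reported missing rather than
zero. Methylation qPCR: ordinary least squares on the standards, Cq = a +
b·log10(quantity); sample Cqs are inverted, replicates averaged with the
s.e.m. reported when ≥ 2; results are methyl/ALUC4 and unmethyl/ALUC4
ratios. A methyl assay with no Cq, or amplifying more than one cycle
after the last (lowest-quantity) standard, is "not detected" with ratio
0 — non-detection is reported as a binary state without a numeric cutoff,
so the curve's range defines the detection limit. Cqs more than one cycle
outside the standards' range are flagged as extrapolation.

## Synthetic data (`synthetic_data`)

What the generator emulates, and the defaults that define the simulated
study conditions:

* **Stutter**: each read's observed repeat length slips downward by a
  geometric number of units, P(K = k) = (1 − p)·p^k with `stutter_prob`
  p = 0.10. One-directional deletion stutter is the dominant PCR slippage
  mode at mononucleotide runs; a 10% slip probability gives a first
  stutter peak at ~9% of reads, comparable to visible stutter in
  electropherograms, and the closed form makes the generator auditable by
  a chi-square goodness-of-fit test.
* **Destabilized loci**: an MMR-deficient specimen destabilizes exactly
  `round(msi_locus_fraction × n_loci)` loci (default 0.5 × 146 = 73, the
  regime of a clearly MSI-high tumor). Each destabilized locus keeps half
  its mass at the reference allele and gains 1–2 shifted modes at
  reference − (1 + Poisson(`msi_shift_mean` = 1)) units. Shifts of 1–2
  units can hide inside the stutter tail — real MSI callers face the same
  confound — so per-locus detection is ~2/3 rather than 1; at the default
  destabilized fraction the specimen-level unstable fraction (~0.31–0.38)
  still clears the 0.20 bound with a wide margin.
* **Depth**: per-locus depth ~ Poisson(`depth_mean` = 200), a typical
  deep-targeted-panel coverage; at this depth the 30× exclusion rule
  essentially never fires, so full-coverage specimens evaluate all 146
  loci.
* **Contaminants**: each specimen receives max(3, burden/2) contaminant
  records; a `contamination_germline_rate` = 0.30 fraction are germline
  (normal allele balance drawn in [0.40, 0.60], 70% also database-flagged)
  and the rest are low-VAF artifacts (VAF in [0.01, 0.095]). Both classes
  are removed by the filters *by construction* — the planted margins
  (somatic VAF ≥ 0.15, somatic allele balance ≤ 0.05) do not straddle the
  filter boundaries, which is what makes exact burden recovery a valid
  oracle test rather than a statistical one.
* **Rearrangements**: 12 clipped reads per breakpoint (well above
  `min_support = 4`), reciprocal partner coordinates, optional positional
  jitter (default 0, so recovery is exact).
* **Copy losses**: exon ratios ~ N(1.0, 0.04) neutral, N(0.5, 0.04)
  heterozygous, N(0.03, 0.008) homozygous, truncated at 0 — three-sigma
  separated from the 0.70/0.15 thresholds.
* **PCR profiles**: a four-peak stutter ladder (100/25/6/1.5% relative
  intensity) with 5% multiplicative intensity noise; unstable markers mix
  in an allele shifted 5–8 units below the normal mode, beyond the
  3-unit stutter guard.
* **Cohort fixture**: 15 PDX lines (3 hypermutated) and 50 autopsy
  patients (5 hypermutated, burdens from the published per-patient
  table), five PDX↔autopsy links of which one joins two hypermutated
  entries — collapsing to 60 unique patients, 7 hypermutated (11.67%).
  Multi-site patients share truth except explicitly site-restricted
  lesions (e.g. a lymph-node-only MLH1 frameshift). Gene spans for
  MSH2/MSH6/MLH1 are hg19-like but the exon intervals are synthetic,
  evenly spaced boxes.

What it does **not** emulate: base-level reads or quality scores,
sequencing error beyond stutter, alignment ambiguity, upward (insertion)
stutter, tumor purity/subclonality gradients, FFPE artifacts, and
capture-efficiency variation between loci. Passing recovery tests
therefore demonstrates the correctness and calibration of the decision
rules under the stated noise model — not performance on real BROCA data,
whose empirical noise distribution is not characterized here.

Determinism: all randomness flows from `SimulationConfig.seed` combined
with a CRC32 of the entity id (specimen, control, marker, patient), so
identical seed + config reproduce byte-identical outputs, and specimens
are reproducible individually without regenerating a whole cohort.

## Problem sizes

The validation suite uses the sizes the analyses are designed for: a
146-locus panel, 10 normal controls for baselines, 100 + 100 specimens
for MSI parameter recovery, 100 seeds for exact burden recovery, and the
full 60-patient / 81-specimen cohort for the end-to-end run. The complete
suite runs in well under a minute on one CPU.

## Known limitations

* The mSINGS-style statistic uses only the allele count, not peak-shape
  divergence; loci whose instability manifests as 1-unit shifts are
  systematically harder to detect (shared with the original method).
* Breakpoint pairing requires reciprocal clusters; one-sided evidence
  (e.g. one breakpoint in unmappable sequence) is not called.
* The PDX novSNV pathway reports counts without germline subtraction;
  cross-cohort burden comparisons should use matched-normal specimens.
* The methylation detection limit is defined by the standard curve's
  range rather than an absolute copy-number cutoff.
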