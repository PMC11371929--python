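# Methods

This note documents the models, parameter choices and numerical conventions
behind `oncointerp`, and what the synthetic-data experiments do and do not
establish about behavior on real genomes.

## Data model and coordinates

All records use 1-based inclusive coordinates (VCF convention); BEDPE output
converts to 0-based half-open at the I/O boundary only. SV breakend
orientation `+` means the derivative chromosome retains sequence to the left
of (at lower coordinates than) the breakpoint, `-` to the right. Chromosome
names are accepted verbatim; a canonical order (1..22, X, Y, then others) is
used for sorting only, so miniature synthetic genomes need no special casing.
Fractional fields are serialized at 6 decimals and rounded to 6 decimals on
read, which makes every write-then-read round-trip exact (pysam surfaces VCF
INFO floats as C floats, so un-rounded comparison would fail at the 8th
digit).

## Somatic selection

The high-confidence criteria (tumor alt reads ≥ 2, normal alt reads ≤ 1,
MQ ≥ 15, normal VAF ≤ 5%, PoN ≤ 1%; SVs: support ≥ 2 tumor / ≤ 1 normal,
MQ ≥ 15, PoN ≤ 5%) are all inclusive on the passing side. Two readings of the
5% VAF ceiling are possible; it is applied to the **normal** sample by default
(a tumor-side 5% ceiling would discard nearly all true somatic calls, whereas a
normal-side ceiling is a standard contamination guard), and the tumor-side
reading is available via `FilterThresholds(vaf_ceiling_applies_to="tumor")`.
Zero normal depth is treated as normal VAF 0 with a log note rather than an
error. Verdicts are total: every record receives a pass/fail with each failed
criterion named, so filtering partitions its input.

## Signature refitting

Catalogs use the standard channel systems: SBS96 (pyrimidine-strand
substitution × flanking bases, purine-context records reverse-complemented),
ID83 (1-bp indels in C/T homopolymers by tract length; longer indels by size ×
repeat count; deletions at microhomology by size × homology length — repeat
context takes precedence over microhomology), and SV32 ({clustered,
non-clustered} × {DEL, DUP, INV in five size bins; TRA}). An SV is *clustered*
when either breakpoint lies in a 1 Mb window containing ≥ 8 breakpoints — a
deterministic density rule chosen over the piecewise-constant-fit convention
used elsewhere in the literature because it is directly checkable against an
enumeration oracle; the divergence matters only near the density threshold.

Exposures solve the non-negative least-squares problem over the active
signature columns (scipy's Lawson–Hanson NNLS) and are rescaled to attributed
counts when the solution is non-degenerate. An all-zero catalog returns zero
exposures with cosine reported as 1.0 plus a degenerate flag — this avoids NaN
propagation while preserving the information that the fit is vacuous.

Refinement automates the "adjust the set when the fit is insufficient"
step: if the initial cosine is ≥ 0.90 (the trigger is strictly < 0.90) the fit
stands; otherwise candidates from the full reference are added greedily
(largest cosine gain; gains ≤ 0.005 rejected) until the threshold is reached,
then signatures attributing < 1% of mutations are pruned when removal costs
< 0.005 cosine. The 0.005 and 1% knobs are package choices, configurable at
module level. A fit that cannot reach 0.90 is returned with a best-effort
flag.

Initial sets are tailored per cancer type from a fixture table following the
tissue-prevalence convention: HRD-prone tissues (breast, ovarian, prostate,
stomach) include SBS3/SBS8, ID6 and RS3/RS5; gastrointestinal types include
the seven MSI signatures. This matters because the flat HRD-type spectra
reconstruct acceptably without their minority components: a 20% SBS3 share
still fits at cosine ≈ 0.97 under {SBS1, SBS5} alone, so a <0.90 trigger
cannot *discover* flat signatures — they must be offered by the tailored set.
The same logic motivates including MSI signatures for stomach/colorectal: with
them in the active set a 60% MSI-class mixture is recovered within ±0.05 at
n = 5,000, while mostly being absorbed by flat signatures if they must enter
through refinement.

## Synthetic reference signatures

The bundled reference (`refsigs.py`) is **synthetic**: the real catalogues are
not redistributable, so each column is generated deterministically from the
signature's name — a seeded gamma-noise spectrum blended (65% theme weight)
with peaks mimicking the signature's qualitative character (N[C>T]G for the
clock-like signature, T[C>N]N for APOBEC, microhomology-deletion channels for
ID6, small tandem duplications/deletions for RS3/RS5, distinct concentrated
C>T / T>C peaks for the seven MSI signatures; SBS3 and SBS40 stay flat).
Everything downstream is matrix algebra agnostic to the actual column values,
so the synthetic reference exercises identical code paths; absolute exposure
values on real data require substituting the real matrices via
`read_signature_reference`.

## Genome phenotypes

**TMB** divides the filtered somatic count by a callable genome size,
default 2,800 Mb (configurable; assays differ and no single value is
canonical). **WGD** is ploidy > 3.5, strict.

**HRD** is a logistic model over six feature groups: SBS3 fraction, SBS8
fraction, ID6 fraction, RS3+RS5 fraction, microhomology-deletion proportion
(microhomology deletion channels ÷ all deletion-class indels; 0 and flagged
degenerate when no deletions), and the count of LOH segments (minor CN = 0,
length ≥ 15 Mb, whole-chromosome excluded — the standard HRD-LOH convention;
the source rules say only "CNVs"). Each feature is standardized as
(x − mean)/scale with constants shipped in `data/hrd_coefficients.json`
(editable), weighted, summed with intercept −3 and passed through a logistic;
positive at ≥ 0.7 inclusive. The feature set follows the HRDetect lineage; the
exact coefficients of the assay this models are proprietary, so these defaults
are the package's own, chosen so a feature vector at the reference point
scores ≈ 0.05 and the monotonicity of each positively-weighted feature is
preserved. Whether exposures enter as counts, fractions or log-counts was an
open choice; fractions plus a raw LOH count were chosen for scale invariance
across mutation burdens.

**MSI** combines two independent evidence sources. The site-level score is the
percentage of evaluable microsatellite loci (≥ 20 reads in both samples) whose
tumor repeat-length histogram differs from the normal by chi-square with
Benjamini–Hochberg control at 0.05 across loci — the FDR step mirrors
MSIsensor and keeps the null score at 0 rather than at the test's type-I rate,
which would otherwise sit above the 3.5-point call threshold for every stable
tumor. The signature-side evidence is the summed exposure fraction of
SBS6/15/20/21/26/30/44. MSI-H is called when score ≥ 3.5 **or** proportion
≥ 0.20 (both inclusive); the two thresholds are package defaults chosen midway
through the wide empirical separation between stable and unstable samples, and
are configurable.

## Drivers and actionability

Gene copy number is the length-weighted mean of overlapping segments' total CN
(a max-segment rule is available), since multi-segment genes have no canonical
single CN. The COSMIC-recurrence cutoff for the oncogene branch is
hotspot count ≥ 10 (the source says only "frequently reported");
"targeted drugs available" lowers the amplification cutoff from ploidy + 5 to
ploidy + 1 and is interpreted as the gene carrying any drug or trial link.
Hyperamplification (CN ≥ 50) is an annotation inspired by the ecDNA cases
(80+, ~185 copies) and never changes amplification status. The TSG truncating
set is {frameshift, nonsense, splice}. Fusion calling requires an allow-listed
pair (any 5′ partner is accepted for ALK and NRG1) and head-to-tail
orientation compatibility derived from gene strand; fusion mechanism
(e.g. chromothripsis) is deliberately not inferred.

Category assignment is precedence-ordered and deterministic: I-1 > I-2 > I-3
within the actionability arm, II-1 > II-2 > II-3 within the clarity arm
(patients can satisfy several; the published breakdowns are mutually
exclusive, and the clarity precedence mirrors the actionability decision since
the per-patient enrolment sub-question is not an input here). The II-1
wild-type-allele-amplification rule fires when a hyperamplified drug-target
gene carries a point mutation at observed VAF < 0.5 × the VAF expected if the
mutant allele were amplified (expected VAF = p·(CN/2)/(p·CN + 2(1−p)) at
purity p); the 0.5 factor is a package choice. II-2 origin inference is
limited to the etiologic tobacco rule (SBS4 fraction ≥ 0.20 AND ID3 fraction
≥ 0.20); no general tissue-of-origin classifier is attempted. II-3 reports a
positive germline screen, or a confident negative (no retained variant and HRD
probability < 0.7). Cohort percentages round half-up (one decimal by default,
zero on request).

Samples with tumor cell fraction < 0.15 (strict) are marked noninterpretable
and all downstream sections are suppressed.

## Synthetic-data generator

The generator emulates *caller outputs*, not reads, on a miniature genome of
23 chromosomes × 60 Mb with fictitious but fixed gene intervals. Channel
counts are multinomial draws from the configured signature mixture; records are
materialized per channel (contexts generated directly, ~30% presented on the
purine strand to exercise folding). Read evidence follows the expected-VAF
model p·m/(p·CN + 2(1−p)) with binomial alt counts and Poisson depths — 40×
diploid-equivalent tumor (locally scaled by copy number, which is what makes
hyperamplified loci deeply covered) and 20× normal, matching the assay scale
this emulates. Intended-pass records are clamped to ≥ 2 tumor alt reads so
ground-truth labels stay achievable; injected artifacts each violate exactly
one named criterion (tumor support 1; normal support 2 at depth 60; MQ 10;
normal VAF 10%; PoN 5%). Clustered-channel SVs place breakpoint A in a fixed
1 Mb hotspot so the density rule deterministically flags them; non-clustered
SVs avoid that region. Copy-number ground truth starts from a
ploidy-rounded baseline, overlays copy-neutral 20 Mb LOH segments (12 for
HRD-true samples, 2 otherwise), then driver amplifications/deletions
(overlays win, segments re-split to stay disjoint). MSI-H samples shift the
tumor repeat-length distribution at 30% of 200 microsatellite loci (60 reads
per sample, three-length support). Default burdens are 3,000 SBS, 800 indels,
200 SVs per tumor — desk-scale but large enough for stable refitting.
Identical configs produce byte-identical outputs.

What passing tests show: the decision rules, refitting numerics and category
logic are implemented exactly and are recoverable from data that obey the
generative assumptions. What they do not show: robustness to caller-specific
artifact spectra (FFPE damage, alignment artifacts), subclonality, real
signature collinearity (flat signatures are genuinely harder to separate than
any synthetic stand-in), or real microsatellite locus heterogeneity.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of 20–77 simulated
samples at the default per-sample burdens above, with every random draw
derived from a single integer seed (child seeds kept below 2³¹); two runs of
any pipeline at the same seed produce byte-identical artifacts, which the
suite asserts at the file level.

## Known limitations

- The synthetic signature reference preserves structure, not values; exposure
  magnitudes on real catalogs require the real matrices.
- HRD coefficients are package defaults, not the proprietary assay's; only the
  feature set and the 0.7 decision boundary carry over.
- The knowledgebase covers the genes the rule set references (24 genes), not a
  clinical-grade catalogue; trial identifiers beginning `TRIAL-` are synthetic
  placeholders.
- Complex-rearrangement mechanism classification (chromothripsis, chromoplexy,
  breakage–fusion–bridge) is out of scope; fusions are reported without
  mechanism labels.
- The clarity arm assigns by evidence precedence, not by the patient's actual
  enrolment sub-question, which is unavailable to the package.
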