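# Methods

This note documents the models behind `dualstrand`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want to know about.

## The assay being modeled

A short-amplicon hotspot panel genotypes FFPE tumor DNA for clinically
actionable mutations. Two problems dominate at the 1–5% allele fractions
of interest:

1. **Fragmentation.** Fixation breaks DNA; templates shorter than an
   amplicon cannot be amplified, so degraded samples lose library yield
   and depth. The qPCR ΔQc score (cycle difference against an undamaged
   control) measures this: each extra cycle ≈ half the amplifiable
   template.
2. **Cytosine deamination.** A deaminated C reads as T. The lesion sits on
   *one* strand of a molecule, so a library prepared from forward-strand
   templates and one prepared from reverse-strand templates cannot both
   contain the same artifact. True variants, present on both strands,
   appear in both.

The pipeline therefore (i) triages samples by ΔQc but sequences everything,
(ii) calls each strand library independently, (iii) reports only variants
detected in both (consensus), and (iv) declares a sample interpretable only
if both libraries reach a median per-amplicon depth cutoff.

## Panel model

Amplicons are intervals on a reference: forward primer | insert | reverse
primer, contiguous, in 0-based half-open coordinates (converted to 1-based
only at VCF emission). Design rules checked by `validate_design`:

| rule | default | rationale |
| --- | --- | --- |
| amplicon length | 120–150 bp | short enough for fragmented FFPE templates |
| primer length | 22–30 bases | specific hybridization |
| exon padding | ≥ 5 bp per side | capture splice-site mutations |
| tiling overlap | ≥ 1 base | no uncovered junction base |
| coverage | 100% of padded exons | assay completeness |
| primer GC | 0.15–0.85 | permissive; a toy reference is ~50% GC |
| primer SNPs | disjoint from a position blacklist | a file stands in for live population databases (reproducible offline) |

An asymmetric padding profile (−7/+6) observed after primer trimming in
practice is selectable via `fixtures.PADDING_PROFILES`.

**Toy reference.** Real panel coordinates are not redistributable, so the
fixture generator fabricates one contig per gene and places the 48 hotspot
exons (sizes 60–220 bp, 250 bp introns, 400 bp flanks) so that tiling with
70–92 bp inserts yields exactly 150 amplicons. Per-exon tile counts are
drawn in {2,3,4} and adjusted to sum to 150 before sizes are chosen, which
makes the count a structural property rather than a tuned outcome. The
resulting footprint is ~9.0 kb. Everything is a pure function of the
fixture seed (default 7); regeneration is byte-identical.

## Synthetic samples

`make_sample` builds, per amplicon, a pool of `n_molecules` (default 2000)
double-stranded source molecules, each contributing one forward- and one
reverse-strand template:

* a truth variant is carried by a molecule — on both strands — with
  probability `target_vaf`;
* each cytosine of each single strand deaminates independently at rate
  `deamination_rate` (default 3×10⁻⁴ per cytosine per molecule). On a
  reverse-strand template the artifact appears as G→A in forward
  coordinates. The default keeps per-site artifact fractions around
  0.01–0.05% per library, far below true-variant VAFs; `jackpot_sites`
  force a chosen site to a chosen fraction on one strand for stress tests
  (a stand-in for early-cycle PCR jackpots);
* a fragment length is drawn lognormal(median `fragment_length_median`,
  shape 0.5); the molecule survives an amplicon only if the fragment is at
  least amplicon-length. `DamageModel.for_delta_qc(x)` inverts this
  survival for a 130 bp amplicon so the preset's realized ΔQc lands near
  `x`; presets span ΔQc ≈ {0, 1, 4.3, 6.6, 10.1, 15.1}, the bands seen in
  degraded clinical extractions.

Molecules are **amplicon-scoped**: a variant is applied to the templates of
the single amplicon whose insert fully contains it, and control variants
are placed in *exclusive zones* (insert regions covered by no other
amplicon) so overlap tiling does not dilute the realized VAF. This is a
deliberate simplification of molecule-level physics — a real deletion
spans every amplicon that covers it — and is why reference-standard
placement rejects positions in overlap regions.

**Sequencing.** Per amplicon, library and sample, the number of read pairs
is negative-binomial around `depth` (default 1000 pairs; dispersion size
1000, i.e. mildly super-Poisson), scaled linearly by pooling concentration
(4 nM standard) and capped by a yield model: effective depth factor
min(1, headroom × amplifiable fraction × triage input scaling), headroom
32. Reads are 2×100 from opposite amplicon ends (always overlapping, since
amplicons ≤150 bp); substitutions occur at `error_rate` 10⁻³ per base with
quality Q20 against Q30 for correct bases — deterministic qualities chosen
so a base-quality floor is meaningful without a recalibration model.

**qPCR.** Cq = 24 − log₂(amplifiable fraction); ΔQc is the difference
against an undamaged pool and is +∞ for a dead pool.

What the generator does **not** emulate: PCR chimeras and polymerase
slippage, sequence-context-dependent error and damage, melanin or other
inhibitors, quality-score noise, real genome homology (primer
cross-hybridization is impossible on the toy reference by construction).
Green tests therefore establish the *logic* of the dual-strand method —
strand confinement, consensus suppression, depth/VAF power — not its
performance on any real chemistry.

## Caller

1. **Assignment.** Read 1's prefix is matched against every forward primer;
   the unique best match within `k=2` mismatches wins, equal-best ties are
   discarded and counted. Read 2's prefix must match the reverse primer
   within `k` as well.
2. **Merging.** The pair is overlap-merged across the whole amplicon (the
   expected indel-free overlap is tried first, then all overlaps longest to
   shortest; ≤2 mismatches accepted in overlaps ≥8, disagreements resolved
   toward the higher base quality). Primer flanks are then cut off, so a
   fragment is one molecule's complete insert observation and per-position
   depth equals fragment count. Merging before trimming matters: a read
   can run through a deletion-shortened molecule into the opposite primer.
3. **Comparison.** A fragment equal in length to the reference insert is
   compared positionally; otherwise a banded global alignment with affine
   gap costs (mismatch 3, gap open 6, extend 1, band ≥20) produces the
   event list. Affine costs keep a 15-bp deletion in one piece instead of
   letting chance matches split it — with unit costs the optimal alignment
   of a long deletion frequently decomposes, which mis-keys the variant.
   Bases below the quality floor become `N` and never generate events.
4. **Calling.** Per site: depth ≥ 100, alt count ≥ 4, VAF ≥ 0.005 (all
   overridable). These per-library floors give ≥99% power for a 1% variant
   at 1000–2000× while the dual-library intersection controls errors; the
   published assay's exact thresholds are not public, so these are this
   package's own choices. Indels are left-normalized (right-trim with
   left extension, then left-trim; property-tested against brute-force
   enumeration of equivalent representations). Runs of adjacent
   substitutions are reported as one MNV when ≥90% of the reads supporting
   each component carry the full run — an invented but conservative rule,
   since the assay's MNV policy is likewise not public.
5. **Consensus.** Variants are keyed by normalized (contig, pos, ref, alt).
   Present in both libraries → PASS, combined VAF = arithmetic mean
   (pooled-count alternative via `combine="pooled"`). Present in one →
   `SINGLE_LIBRARY_REJECTED`, or `LOW_DEPTH` when the other library lacked
   the depth to weigh in; never PASS.

## QC and depth cutoff

Triage: ΔQc ≤ 4 → STANDARD (the boundary counts as standard — the degraded
class is defined by strict excess); above → DEGRADED_ATTEMPT with input
scaling 2^(ΔQc−4) capped at 16, invented plumbing for the manufacturer's
fold-dilution lookup. Degraded samples are still sequenced;
interpretability is decided afterwards by median per-amplicon depth ≥
cutoff (default 700) in *both* libraries.

`determine_depth_cutoff` takes a concentration-sorted dilution series and
returns the smallest realized median depth of the maximal fully concordant
(FP=FN=0) prefix; it refuses to propose a cutoff if even the deepest point
is discordant. In simulation the concordance break is driven by false
negatives (the 1–2% controls drop below the alt-count floor near ~400–500×);
false positives stay at zero throughout because an error-rate pileup cannot
reach 4 identical alternate reads at any depth in the series — the
qualitative FP-versus-dilution rise seen with permissive callers is only
weakly reproduced, and the cutoff this procedure returns on the toy data
(~500×) should be read as a procedure demonstration, not a recommended
clinical value.

## Validation statistics

Per-base confusion counts treat each interrogated nucleotide as one
Bernoulli trial: truth anchor positions called → TP, uncalled → FN, called
non-truth positions → FP, everything else → TN; TP+TN+FP+FN equals the
interrogated size by construction, and calls outside the region are an
error rather than an FP. Metrics carry Wilson score 95% CIs (statsmodels),
chosen over Clopper–Pearson because the score interval is the standard
informative choice at proportions of 0 or 1 (lower bound 1/(1+z²/n) at
k=n); tests verify it against closed form and numeric score-test inversion.
Pearson concordance (scipy) is cross-checked against the covariance
formula; per-variant SD uses n−1 and CV% = 100·SD/mean. Report percentages
round half-up at one decimal; raw fractions are retained. Cohort summaries
report diagnosis rates with both candidate denominators (interpretable
samples and all samples) because conventions differ; zero denominators
yield flagged `None`, never 0/0.

## Test scaling

The heavier stated properties run at reduced scale to stay inside a
desk-scale time budget: consensus artifact suppression uses a single-gene
sub-panel at 300× across 20 seeds, dilution monotonicity the same sub-panel
across 10 seeds, and the validation cohort runs at 600× per library (power
calculations above make 600× ample for ≥5% variants). Seed counts follow
the stated invariants; only the problem size is scaled down.

## Known limitations

* Amplicon-scoped molecules (see above): indels spanning amplicon overlaps
  are out of the simulator's vocabulary, and the caller has never been
  exercised on them.
* The ΔQc → input-scaling → yield chain is a plausible monotone model, not
  a fit to any instrument; rescue rates for degraded samples depend on its
  headroom constant.
* Consensus requires presence in both libraries, so any true variant lost
  to a zero-depth library in one strand becomes a false negative; the
  interpretability gate is what keeps this rare.
* MNV merging and all per-library thresholds are package choices
  (config-overridable), not reconstructions of any vendor tool.
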