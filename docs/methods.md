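# Methods

## The measurement model

A-to-I editing at a genomic site is observed through RNA-Seq reads as
an A→G mismatch on the transcribed strand. For a site with A-count *a*
and G-count *g* in one sample, the editing index is

    φ = g / (a + g).

C and T reads at an A→G site are treated as sequencing noise, not as
unedited transcripts; the package can be switched to a total-coverage
denominator (`build_editing_matrix(..., denominator="coverage")`), but
A+G is the default because errors then perturb the numerator and
denominator symmetrically. Which convention the original survey used
is not documented; the choice matters only at third-decimal level for
error rates ≤ 1%.

All counts are expressed on the transcribed strand: pileup counts over
minus-strand genes are complemented, so an editing event is always an
A→G regardless of gene orientation. Internally coordinates are 0-based
half-open; exported tables carry a `pos_1based` column.

## Discovery cascade

Candidate sites are nominated with a deliberately minimal rule —
transcribed-strand reference A and at least one G read in at least one
sample — so that all stringency is explicit in the filter stages:

1. **multi-editing exclusion** (per sample, per site): among a
   sample's non-reference reads (if at least `consensus_reads` of
   them), more than `max_other_alt_fraction` (default 0.2) being a
   base other than G excludes the sample at that site;
2. **consistency** (per site): among samples with at least
   `consensus_reads` non-reference reads, the fraction whose dominant
   alternative base is G (ties count for G) must be at least
   `min_dominant_sample_fraction` (default 0.8); a site with no such
   informative sample is dropped. Samples excluded in stage 1 still
   count here — a heavily A→C sample is exactly the evidence of
   inconsistency this stage looks for;
3. **per-tissue cutoffs**: a sample *supports* a site when coverage ≥
   `min_coverage`, G reads ≥ `consensus_reads`, φ ≥ `min_editing`, and
   it was not excluded in stage 1; the site needs
   ≥ `min_supporting_samples` supporters. `min_editing` is applied per
   sample inside the support predicate (the site mean is additionally
   reported); this is the only reading that makes a per-sample support
   count well-defined;
4. **blacklist**: sites inside user-supplied intervals (hypervariable
   loci such as HLA or ribosomal genes) are removed; 0-based half-open
   arithmetic.

All scalar comparisons are inclusive (≥). The five bundled per-tissue
profiles are the published cutoff sets (aorta 0.05/2/15/70,
ventricular appendage 0.05/2/5/70, coronaries 0.03/2/15/70, tibial
artery 0.05/2/5/70, left ventricle 0.03/2/5/100 for minimum editing /
consensus reads / minimal coverage / minimum supporting samples). The
0.2 and 0.8 auxiliary defaults are this package's quantification of
the qualitative multi-editing and consistency criteria; no published
numbers exist for them. They were chosen so that uniform-error
simulations pass cleanly while planted A→C confounders are rejected,
and both are configurable per profile.

For cutoff tuning the cascade can run over candidates of all 12
mismatch classes; the report then traces the A→G fraction of
surviving candidates per stage. Under uniform errors this starts near
1/12 and should approach 1.0 after the support stages — the diagnostic
used to tailor per-tissue cutoffs.

Pileup hygiene: only primary, mapped alignments with MAPQ ≥ 20; bases
below quality 20 skipped when the file carries qualities; base N
ignored; positions claimed by genes on both strands skipped and
logged. The MAPQ/baseQ defaults are package decisions (configurable);
the original thresholds are not documented.

## Differential editing

Per site, per-sample editing indices of two cohorts are compared with
a two-sided Welch t-test (default; robust to the unequal variances and
sizes of, e.g., a 69-vs-112 design) or Mann–Whitney U as the
nonparametric fallback. Group means use valid cells only; sites with
fewer than 2 valid samples in a group are skipped and listed. The
effect flag is |log₂(mean₁/mean₂)| ≥ 0.9: the fold-change cutoff is
interpreted on the log₂ scale, since log₂ 1.9 ≈ 0.926 ≈ 0.9 makes the
0.9 cutoff and the ">1.9-fold" phrasing consistent; the cutoff is a
parameter. Raw p-values are reported (that is what the original
analysis quotes); a Benjamini–Hochberg column is optional. Degenerate
zero-variance cases: identical constant groups report p = 1, distinct
constant groups p = 0.

Expression–editing correlation is Pearson r with the least-squares
line and the two-sided p for r (≥3 complete pairs, non-constant
vectors). Tissue clustering averages the editing matrix per tissue,
drops sites missing in any tissue, sorts tissue labels alphabetically
(deterministic tie-break), and runs average-linkage Euclidean
hierarchical clustering; the dendrogram is exported as an ultrametric
newick string (leaf-to-parent length = half the merge-height
difference).

## The simulator

The generator emulates the statistical structure of large per-tissue
RNA-Seq cohorts:

- **per-sample editing rate**: Beta(μκ, (1−μ)κ) around the cohort
  mean μ with concentration κ (`per_sample_dispersion`). Printed
  per-group SDs of real cohorts imply κ = μ(1−μ)/σ² − 1 ≈ 13–77; the
  package default κ = 30 is a round mid value of that range. Presets
  with printed SDs use the implied per-group κ exactly.
- **reads**: coverage per site is Poisson(`mean_depth`); edited reads
  are Binomial(coverage, per-sample rate) and emitted as clean G
  calls; every unedited read base substitutes to one of the three
  alternatives with probability `error_rate` (default 10⁻³), elevated
  inside hypervariable regions (default 0.1). Reads are ungapped,
  full-length, quality-free (CIGAR `<len>M`): the filters under test
  operate on substitution pileups, so indel/quality realism would add
  nothing they can see.
- **strands**: genes are laid out disjointly (one per contig slot,
  jittered), a configurable fraction on the minus strand; sites are
  planted only where the transcribed-strand base is A, so a
  minus-strand site sits on a plus-strand T and edited reads carry C
  on the reference strand.
- **confounders**: `snp_like` plants a homozygous-G genotype in a
  deterministic half of the samples (CRC32 of seed and sample id);
  `multi_mismatch` emits A→C at an editing-like rate; 
  `hypervariable_region` elevates the error rate over an interval.
- **cohorts/presets**: a sample sheet (sample, tissue, group) drives
  per-sample generation from independent child RNG streams spawned
  off the config seed, so any sample regenerates independently and
  identical config+seed gives byte-identical outputs. The
  `flna_dcm` (0.23/0.12, n = 69/112), `tibial` (0.878/0.685, κ from
  SDs 0.037/0.125, n = 4/7) and `aorta` (0.775/0.626, κ from
  0.091/0.118, n = 4/7) presets feed printed cohort parameters in as
  simulation inputs.

What the simulator does *not* model — and what passing tests therefore
do not establish about real data: alignment and mapping artifacts
(multi-mapping, splicing, indels, soft-clips), PCR duplicates,
position-dependent error profiles, allele-specific expression,
germline variation beyond the SNP-like confounder, and correlated
coverage (counts mode draws coverage independently per position;
SAM mode has read-induced correlation). Conclusions from simulations
are about the statistical logic of the cascade, not about aligner
behaviour.

In counts mode edited reads bypass the substitution-error step
(a second-order effect of order rate × error ≈ 10⁻⁴); in SAM mode an
edit decision overrides an error at the same base.

## Problem sizes and numerical choices

Test and acceptance runs use a 10–20 kb single-contig genome with
5–10 genes, 12–80 samples and depth 20–100 — sizes where every stage
(including the all-class diagnostic cascade) runs in seconds while
binomial/beta standard errors are still tight enough for 3-SE
assertions. The acceptance script's recovery run uses 100 planted
sites at rates U[0.1, 0.9] over 80 samples at depth 50 with the aorta
profile rescaled to 60 supporting samples (75% of the cohort, the
same proportion as 70-of-~95 per-tissue donors).

Ties and degenerate inputs: dominance ties in the consistency stage
favour the target base; sites where every cell is invalid report a
missing (not zero) mean; a zero-depth sample is emitted empty with a
warning; the contraction window is half-open (t₀, t₀+30]; relaxation
(rising cell index) yields negative contraction percentages,
unclamped, since nothing documents clipping. The contraction formula
(1 − CI_min) × 100 itself is this package's explicit arithmetic for a
readout whose ingredients (normalization at agonist time, CI_min
within 30 min) are named but whose formula is not written out
anywhere.

## Known limitations

- SNP-like sites (homozygous G in a donor subset: φ ≈ 1 there, ≈ 0
  elsewhere) *pass* the cascade — they are consistent, well-supported
  A→G signals by every printed criterion. The test suite documents
  this rather than hiding it; the blacklist stage (or genotype masking
  upstream) is the extension point for real data.
- The cascade's sensitivity at true rates near `min_editing` depends
  on depth through the consensus-read requirement; detection
  probability is monotone in rate and depth (tested on a grid) but
  not calibrated in absolute terms.
- The differential module reports per-sample-index tests; it does not
  model within-donor correlation across tissues, covariates, or
  editing QTLs.
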