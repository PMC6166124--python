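# rnaedit

Detection, quantification and cohort comparison of A-to-I RNA editing
from bulk RNA-Seq, with a planted-truth simulator that makes every
stage testable at desk scale.

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA;
since inosine is read as guanosine, editing shows up in RNA-Seq as
A→G mismatches on the transcribed strand. In cardiovascular tissue
this recoding is massive — the FLNA Q2341R site is edited in the
vast majority of arterial transcripts — and editing levels drop in
patients with cardiovascular disease. This package reimplements the
computational side of that kind of survey for anyone who wants to run
it on their own alignments or stress-test it on simulations:

- **site discovery** — strand-aware base-count pileups from
  coordinate-sorted SAM/BAM over an annotated genome, then a staged
  filter cascade (multi-editing exclusion → cross-sample consistency →
  per-tissue cutoffs on coverage, consensus reads, minimum editing and
  supporting samples → hypervariable-region blacklist), with an A→G
  enrichment trace over all 12 mismatch classes for cutoff tuning;
- **quantification** — per-site, per-sample editing index
  φ = G/(A+G), editing matrices with validity masks, per-tissue
  summaries;
- **cohort analysis** — per-site Welch t-test (or Mann–Whitney)
  between cohorts with log₂ fold-change flags
  (|log₂ FC| ≥ 0.9 ⇔ >1.9-fold), Pearson expression–editing
  correlation, hierarchical clustering of tissue editing profiles with
  newick export;
- **simulation** — references, gene annotations, reads (SAM) or
  base-count tables with planted editing sites whose per-sample rate
  is Beta(μκ, (1−μ)κ)-distributed around the cohort mean μ, uniform
  sequencing errors, SNP-like / multi-mismatch / hypervariable
  confounders, and presets that reproduce printed cohort effects
  (23%→12%, 87.8%→68.5%, 77.5%→62.6%) as simulation inputs;
- **phenotype metrics** — circumferential cyclic strain
  Eθθ(t) = ½[(r(t)/r(0))² − 1] = [A(t)/A(0) − 1]/2 and percentage
  contraction (1 − CI_min) × 100 from cell-index traces.

## Worked example

Simulate the FLNA-like two-cohort design and recover the planted
effect (`examples/simulate_cohort.py`):

```python
import numpy as np
import rnaedit as re_

cfg = re_.SimConfig(seed=42, n_edit_sites=1, error_rate=0.001,
                    reference_length=2000, n_genes=1, mean_depth=100)
matrix, truth, design = re_.preset_cohort("flna_dcm", config=cfg)
merged = matrix.sites.reset_index().merge(truth.sites[["contig", "pos"]])
em = re_.build_editing_matrix(matrix, site_index=merged["index"].to_numpy(),
                              sample_meta=design)
for group in ("healthy", "diseased"):
    cols = (em.samples["group"] == group).to_numpy()
    print(group, f"{100 * np.nanmean(em.values[:, cols]):.1f}%")
```

prints

```
observed mean editing, healthy (n=69): 23.5%
observed mean editing, diseased (n=112): 11.1%
```

i.e. the pipeline hands back the planted 23% / 12% cohort means up to
donor-to-donor beta spread and binomial read sampling. The full
discovery round trip (reads → pileup → cascade,
`examples/discover_and_filter.py`) prints the per-stage site counts
and the A→G enrichment trace — ≈ 1/12 at nomination when uniform
sequencing errors populate all twelve mismatch classes, 1.0 after the
support stages, with exactly the 8 planted sites surviving:

```
          stage  sites_in  sites_out
     nomination      6603       6021
  multi_editing      6021       6021
    consistency      6021       1236
profile_cutoffs      1236          8
      blacklist         8          8
final sites: 8 (planted: 8)
```

The other examples cover differential editing (volcano-ready table,
the five perturbed sites land at log₂ FC ≈ log₂(23/12) ≈ 0.94 with
vanishing p), tissue clustering (two clades: heart-like vs
artery-like profiles) and the closed-form strain/contraction metrics.

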