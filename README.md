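# yampop

Mixed-ploidy population genomics for clonally propagated crops, built around
the analysis needs of greater yam (*Dioscorea alata*): a dioecious
autopolyploid (2x/3x/4x via unreduced gametes) cultivated almost exclusively
by vegetative propagation, genotyped by reduced-representation sequencing
(GBS). The package turns a VCF with per-sample read depths into ploidy
calls, clone partitions, diversity statistics and demographic model
rankings — and ships a synthetic-data generator with known truth so every
stage can be exercised and validated without any raw sequencing data.

## What it does

1. **Ploidy inference from allele balance** (`yampop.ploidy`). At a
   heterozygous site the alternate-allele read fraction concentrates near
   dosage/ploidy, so its distribution over sites is unimodal at ½ for a
   diploid, bimodal at ⅓ and ⅔ for a triploid, trimodal at ¼, ½, ¾ for a
   tetraploid. The method histograms fractions at well-covered heterozygous
   sites (default: depth ≥ 30×), least-squares fits an even-degree
   polynomial with no modality prior, counts its interior local maxima and
   maps 1/2/3 maxima to 2x/3x/4x (anything else → unknown). A grid search
   tunes depth threshold, class count and degree on a labelled panel.
2. **Clone detection** (`yampop.clonality`). Method-of-moments
   identity-by-descent: for each pair, identity-by-state counts are combined
   with their expectations given IBD state to estimate (P0, P1, P2) and
   π̂ = P1/2 + P2. A kernel-density valley between the parent–offspring peak
   (π̂ ≈ ½, anchored by known sib cohorts) and the clone peak (π̂ ≈ 1) sets
   the clone threshold; multi-locus lineages (MLLs) are connected components
   of the above-threshold graph. Also: Manhattan kinship (fraction of shared
   alleles) with a fitted normal-law significance threshold, genotypic
   richness R = (G−1)/(N−1), fixation index Fis = 1 − Ho/He, and
   GraphML/TSV network export.
3. **Diversity statistics** (`yampop.popgen`). Nucleotide diversity π,
   Tajima's D and Weir–Cockerham Fst on 100-kb bins containing ≥ 3 SNPs.
4. **Demographic inference** (`yampop.sfs`, `yampop.coalescent`,
   `yampop.demography`). Joint 2-D site-frequency spectra with
   expectation-based hypergeometric projection to handle missing data; a
   numba-accelerated structured-coalescent simulator (splits, mergers,
   continuous migration); multinomial composite likelihood and AIC = 2k −
   2 logL model ranking over built-in split-and-migration templates,
   including the three Africa-origin scenarios (from the Indian Peninsula,
   from the Pacific, or from the Indian Peninsula with Pacific gene flow).
5. **Synthetic GBS generator** (`yampop.synth`). Wright–Fisher founder gene
   pools, polyploids via unreduced gametes, clonal expansion with somatic
   mutation, binomial read sampling with error/dropout, VCF 4.2 + truth TSV
   output.

## Worked example

```python
from yampop.synth import simulate_het_accession
from yampop.ploidy import PloidyParams, call_sample

for ploidy in (2, 3, 4):
    t = simulate_het_accession(ploidy, 2000, 60, 0.005, seed=11 + ploidy)
    call = call_sample(t.samples[0], t, PloidyParams())
    print(f"true {ploidy}x -> called {call.ploidy}x, modes at "
          + ", ".join(f"{m:.3f}" for m in call.maxima))
```

prints

```
true 2x -> called 2x, modes at 0.501
true 3x -> called 3x, modes at 0.329, 0.672
true 4x -> called 4x, modes at 0.228, 0.495, 0.775
```

i.e. at 60× depth the fitted allele-balance modes recover the theoretical
dosage ratios (½; ⅓, ⅔; ¼, ½, ¾) to within a few hundredths, and the mode
count alone identifies the ploidy.

The same stages are available from the shell: `yampop simulate | filter |
ploidy | clones | stats | sfs | compare` (see `yampop --help`).

## Scope

Upstream wet-lab and read-processing steps (demultiplexing, trimming,
mapping, SNP calling) are out of scope: the pipeline starts from a VCF with
GT/AD/DP. PCA/ADMIXTURE, graphical network layout and full-scale ECM
optimization of demographic parameters are also out of scope; see
`docs/methods.md` for the model details and design choices.
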