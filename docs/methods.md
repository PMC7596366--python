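# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Genotype model and filtering

Input is a VCF with per-sample GT, AD (ref,alt read counts) and DP.
Genotypes are handled on the diploid 012 scale (alternate-allele dosage,
−1 = missing); depth 0 encodes missingness. Two filtering regimes share one
fixed order — per-cell depth mask (cells < 8 reads become missing), then
site-level biallelic, minor-allele-count ≥ 3, minor-allele-frequency ≥ 0.05
and ≤ 10% missing tests:

* **standard regime** — all five rules; used for ploidy, clonality and
  diversity statistics;
* **SFS regime** — identical but with the frequency rule disabled, since
  rare variants carry most of the demographic signal.

Allele counts and frequencies are computed on non-missing calls *after* the
depth mask (the mask can therefore flip a MAC/MAF decision; this ordering is
deliberate and tested). Mean imputation replaces a missing cell by its
site's mean observed code, so imputed values are fractional on [0, 2]; this
is required by the Manhattan kinship below and leaves observed cells
untouched.

## Ploidy from allele balance

For accession *i* and heterozygous site *s*, the allele balance is
`alt/(ref+alt)`. Under binomial read sampling with error rate *e*, its mean
is `(1−e)·d/p + e·(1−d/p)` for dosage *d* and ploidy *p*, so the balance
distribution over het sites has modes at the dosage ratios: {½} (2x),
{⅓, ⅔} (3x), {¼, ½, ¾} (4x).

Procedure: keep sites called heterozygous with depth ≥ `min_site_depth`
(default 30×, the trained threshold; at 8× the binomial spread of the
balance swamps the mode separation); histogram on (0,1) with `n_classes`
equal-width classes (100/250/500 canvassed, default 250); least-squares fit
a polynomial of even degree through (midpoint, height); locate interior
maxima analytically as derivative roots with a +→− sign change inside the
window (0.1, 0.9); merge maxima closer than 0.08; discard maxima whose
fitted height is below 15% of the tallest. The mode count maps to ploidy
(1→2x, 2→3x, 3→4x, else unknown); samples with fewer than 100 usable
fractions are unknown without fitting.

Numerical choices that matter:

* **Degree 10 default.** The derivative must admit three +→− sign changes
  plus tail behaviour; degree 8 consistently fused the tetraploid's outer
  modes at 250 classes, while degree 10 resolves all three across 100–500
  classes. The degree is exposed in the training grid.
* **Relative-height rule (15%).** Any high-degree polynomial fitted to the
  near-empty histogram tails develops low-amplitude ripples; treating a
  ripple as a mode would inflate the mode count. Requiring a maximum to
  reach 15% of the tallest maximum removes them without touching genuine
  modes, whose heights are comparable (the rule is skipped for non-positive
  curves, where "relative height" is meaningless).
* The search window (0.1, 0.9) excludes edge artefacts from sequencing
  error at homozygous-leaning dosages.

Training is an exhaustive grid evaluation of call accuracy on a labelled
panel (unknown counts as wrong); ties prefer the higher depth threshold,
then fewer classes (the more conservative, smoother setting).

## Relatedness and clone partitioning

Two relatedness measures serve two different decisions:

* **Kinship** `1 − Manhattan/(2L)` on the imputed 012 matrix — the fraction
  of shared alleles; a normal law fitted to kinship among independent
  individuals gives the upper one-sided P = 0.05 significance threshold used
  for network edges.
* **π̂ (method of moments)**: per pair, the counts of IBS states 0/1/2 over
  polymorphic co-observed loci are equated to their expectations given IBD
  state, using sample alternate-allele frequencies from the full filtered
  panel with no small-sample bias correction (the simplest published form;
  clone-heavy panels bias the frequencies slightly, which shifts unrelated
  π̂ by ≲ 0.02 at the default design). Probabilities are clipped to [0, 1]
  and renormalized; π̂ = P1/2 + P2.

The clone threshold is the minimum of a Gaussian-KDE density of all pairwise
π̂ between the kin peak and the clone peak. Known sib cohorts anchor the kin
side: the search starts above their 95th percentile, so the threshold
separates clones (π̂ ≈ 1) from parent–offspring/full sibs (π̂ ≈ ½) even
when the kin pairs are too few to raise a KDE mode of their own. A mode
pressed against 0 or 1 counts as a peak. With a unimodal density the method
falls back to a supplied threshold (typically the kinship significance
threshold) and flags it.

MLLs are **connected components** of the above-threshold graph, not
cliques: a lineage diversifying by somatic mutation is a chain through its
ancestor, and clique semantics would shatter it. Components of size ≥ 2 are
MLLs (one seeded representative each); singletons are unique genotypes.
Genotypic richness is R = (G−1)/(N−1) on the 0–1 scale; Fis is
1 − Ho/He (He = 2pq) averaged over polymorphic loci and goes negative under
clonal propagation (heterozygosity frozen at the founder's).

## Diversity statistics

Per-site π uses the unbiased estimator `n/(n−1)·2p̂q̂` over the observed
allele copies (n varies by site under missingness). Bins are fixed 100-kb
tiles with ≥ 3 SNPs. π is reported per analyzed variant site by default; a
per-bp mode divides the summed site π by the bin width, the scale on which
whole-genome surveys report ~1e−5 diversity (synthetic data carry no
invariant-site track, hence the two modes). Tajima's D uses the standard
a1…e2 constants with n = rounded mean observed copies over the bin's
segregating sites (exact for complete data). Weir–Cockerham Fst computes
the a/b/c variance components per site; the multi-locus value is the ratio
of sums, and slightly negative values are retained as estimates.

## Joint SFS and projection

The 2-D SFS for a population pair counts SNPs by alternate-allele copies in
each pool. Missing data are handled by projecting each site's observed
counts down to a fixed number of copies (the smallest population's size)
via the hypergeometric expectation over subsamples — deterministic, mass
conserving, and lower-variance than resampling once. Sites observed in
fewer copies than the projection size are dropped and counted. The
alternate allele is treated as derived (the reference genome is an outgroup
species); a folded mode is provided. Spectra round-trip through a
dadi-style plain-text format: header `n1 n2 folded|unfolded "pop1" "pop2"`,
then the row-major flattened matrix.

## Coalescent simulator

Backward-time structured coalescent: within pool k lineage pairs coalesce
at rate 1/(2N_k) per generation (N_k diploid); migration moves a lineage
from k to l at backward rate m[k,l]; at each merger (a split viewed
backwards) the source pool's lineages join the destination, whose size may
change — the deepest merger restores N_ANC. One segregating site per locus
under infinite sites: each branch accumulates its raw length into the SFS
entry indexed by its per-pool descendant counts, and the spectrum is
normalized to the locus count, giving the low-mutation-rate expectation
E[ℓ_i]/E[ℓ_tot] (the classical 1/i law in the single-pool case, verified
against that closed form and against an independent coalescent
implementation). `sample_sites=True` draws integer counts from the expected
spectrum, producing data-like observations. The event loop is numba-JITted;
time scales only as generations × rates, so parameters are reported in
coalescent units without a mutation-rate or generation-time calibration.

## Scenario templates and model comparison

Templates cover four gene pools (MSEA, InP, Pac, Afr): the Pacific splits deepest (TDIV3), then MSEA/InP (TDIV2), then
Africa from its source at TDIV1, with constant InP↔Pac gene flow; the three
Africa-origin variants are (A) from InP, (B) from Pac, (C) from InP with
Pac↔Afr gene flow.

Desk-scale defaults: the InP-Pac gene-flow rate is the conventional 0.005
per lineage per generation. Sizes and times are package choices made once
for an *identifiable* desk-scale design: constant migration m homogenizes
two pools on the 1/m timescale, so all divergence windows must sit well
inside 1/m = 200 generations — N = 500 for every pool and
TDIV = 80/200/500 generations satisfy this while spanning up to 0.5
coalescent units of drift. (With times ≫ 1/m the origin of Africa is
genuinely unidentifiable from joint spectra, whatever the method.)

Fitting maximizes the multinomial composite log-likelihood
Σ obs·log p̂ over SFS entries, expected proportions floored at 1e−8 and the
monomorphic corners excluded (SNP-only data carry no invariant-site
information; for a pair this also drops the (0,0)/(full,full) classes fed
by variants private to other pools). Free parameters are searched on a log
scale by multi-restart Nelder–Mead; every evaluation simulates the expected
spectrum with the same seed (common random numbers), making the objective
deterministic given the fit seed — so a nested model can never rank below
its special case through simulation noise alone. Final log-likelihoods are
re-evaluated at each model's best fit with a common seed and locus budget,
and models are ranked by AIC = 2k − 2 logL, k = number of free parameters.
Defaults (10 restarts × 20 000 loci) are desk-scale stand-ins for an
industrial ECM optimization; the comparison only needs consistent
maximization, and restart/budget are configurable.

## Synthetic generator: what it emulates, what it does not

Emulated: several diverged diploid gene pools (forward Wright–Fisher drift
on allele frequencies with island-model mixing; serial splits off a trunk,
most recent first); triploids/tetraploids via unreduced gametes (reduced +
unreduced; two unreduced) from parents of one pool; clonal lineages whose
ramets differ by Poisson(μ·L) somatic one-copy dosage shifts; binomial read
sampling at fixed or Poisson depth with symmetric error and per-cell
dropout; 20-linkage-group coordinates; VCF 4.2 with GT:AD:DP where the het
call needs ≥ 2 reads of each allele (ties between alleles go to reference).

Not emulated: linkage disequilibrium along chromosomes (sites are
exchangeable), selection, allele-specific amplification bias, index
hopping, genotyping-caller idiosyncrasies, reference bias. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling models, not robustness to every artefact of real GBS
libraries.

Benchmark conditions used throughout the tests: ploidy stages use 2000
heterozygous sites at 60× depth with 0.005 error; the clonal panel plants
40 clone groups (2–19 ramets, 247 total) plus 53 singletons over 5000 loci
with somatic μ = 2·10⁻⁴ per site per ramet and two 15-member progenies
sharing a parent for threshold calibration; demographic experiments use
5000 observed SNPs and 8 sampled allele copies per pool. These sizes keep
every stage's full run in minutes on one CPU while leaving each test's
signal an order of magnitude above its Monte Carlo noise.

## Known limitations

* Ploidy beyond 4x, aneuploidy and contamination are out of scope; the
  classifier is a pure function of the mode count.
* π̂ assumes diploidy; polyploid relatedness is assessed via Manhattan
  kinship only.
* Tajima's D with heavy, uneven missingness uses an averaged sample size
  per bin; with complete data the constants are exact.
* The composite likelihood ignores linkage between SFS entries, as is
  standard; AIC differences are therefore indicative rankings, not
  calibrated evidence ratios.
* Scenario parameters are reported in coalescent units; calibrating to
  years requires an external mutation rate and generation time.
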