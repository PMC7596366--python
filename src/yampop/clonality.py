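"""Relatedness, clone detection and multi-locus lineage (MLL) partitioning.

Two relatedness measures are computed, mirroring two distinct procedures:

* **Kinship** = 1 - Manhattan distance / (2L) on the mean-imputed 012 matrix,
  i.e. the fraction of shared alleles; significant kinship edges use an upper
  one-sided P = 0.05 threshold from a normal law fitted to kinship between
  independent individuals.
* **pi-hat** (method-of-moments identity-by-descent): per pair, observed
  identity-by-state counts are combined with their expectations given IBD
  state 0/1/2 under the sample allele frequencies to estimate (P0, P1, P2);
  pi-hat = P1/2 + P2. Clone calls use pi-hat with a threshold placed in the
  valley of its density between the parent-offspring peak and the clone peak.

Clone clusters are connected components of the above-threshold graph (a chain
of somatic mutations can make two ramets of one lineage mutually distant, so
clique semantics would shatter true lineages). Genotypic richness is
R = (G - 1)/(N - 1) and the fixation index Fis = 1 - Ho/He averaged over
polymorphic loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import MISSING


@dataclass
class KinshipMatrix:
    samples: list
    values: np.ndarray  # symmetric, unit diagonal, in [0, 1]


@dataclass
class MLLPartition:
    clusters: dict  # clone_id -> list of member sample ids (size >= 2)
    unique_genotypes: list  # singleton sample ids
    threshold: float
    representatives: dict = field(default_factory=dict)  # clone_id -> sample id

    @property
    def n_genotypes(self) -> int:
        """G: number of distinct multi-locus genotypes (MLLs + singletons)."""
        return len(self.clusters) + len(self.unique_genotypes)

    def labels(self, samples) -> np.ndarray:
        """Integer partition labels in the given sample order."""
        lab = {}
        for k, (cid, members) in enumerate(sorted(self.clusters.items())):
            for s in members:
                lab[s] = k
        for k, s in enumerate(sorted(self.unique_genotypes), start=len(self.clusters)):
            lab[s] = k
        return np.array([lab[s] for s in samples])


def kinship_matrix(imputed: np.ndarray, samples=None) -> KinshipMatrix:
    """Kinship as 1 - Manhattan distance / (2 * loci) over an imputed 012 matrix.

    ``imputed`` is (sites x samples) with no missing values (fractional
    imputed codes allowed). Identical rows give 1; fully opposite homozygotes
    give 0.
    """
    n_loci = imputed.shape[0]
    if n_loci == 0:
        raise ValueError("no loci")
    d = squareform(pdist(imputed.T, metric="cityblock")) / (2.0 * n_loci)
    values = 1.0 - d
    np.fill_diagonal(values, 1.0)
    if samples is None:
        samples = list(range(imputed.shape[1]))
    return KinshipMatrix(list(samples), values)


def significance_threshold(values, p: float = 0.05):
    """Upper one-sided normal-law threshold on kinship between independents.

    Fits Normal(mu, sigma) to the supplied kinship values and returns
    ``(mu + z(1-p) * sigma, diagnostics)``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need >= 10 independent pairs to fit the normal law")
    mu, sigma = stats.norm.fit(values)
    thr = mu + stats.norm.ppf(1 - p) * sigma
    return float(thr), {"mu": float(mu), "sigma": float(sigma), "p": p}


def _ibs_counts(gi: np.ndarray, gj: np.ndarray, poly: np.ndarray):
    """Counts of IBS state 0/1/2 over polymorphic, co-observed loci."""
    ok = poly & (gi != MISSING) & (gj != MISSING)
    diff = np.abs(gi[ok] - gj[ok])
    n2 = int((diff == 0).sum())
    n1 = int((diff == 1).sum())
    n0 = int((diff == 2).sum())
    return n0, n1, n2, ok


def _ibd_expectations(p: np.ndarray):
    """Per-locus P(IBS=s | IBD=z) sums under allele frequencies ``p``."""
    q = 1 - p
    e0_0 = 2 * p**2 * q**2
    e1_0 = 4 * p**3 * q + 4 * p * q**3
    e2_0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_1 = 2 * p * q
    e2_1 = p**2 + q**2
    return e0_0, e1_0, e2_0, e1_1, e2_1


def _solve_ibd(n0, n1, n2, s0_0, s1_0, s2_0, s1_1, s2_1, n_loci):
    """Moment equations solved sequentially, clipped to [0,1], renormalized."""
    p0 = n0 / s0_0 if s0_0 > 0 else 0.0
    p1 = (n1 - p0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
    p2 = (n2 - p0 * s2_0 - p1 * s2_1) / n_loci
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    if total > 0:
        probs = probs / total
    pihat = probs[1] / 2 + probs[2]
    return float(pihat), tuple(float(x) for x in probs)


def ibd_pihat(gi: np.ndarray, gj: np.ndarray, freqs: np.ndarray):
    """Method-of-moments pi-hat for one diploid pair.

    ``gi``/``gj`` are 012 genotype vectors (missing allowed), ``freqs`` the
    per-locus alternate-allele frequencies used for the IBS-given-IBD
    expectations (typically sample frequencies from the full filtered panel,
    without small-sample bias correction).
    """
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("pi-hat needs polymorphic loci")
    n0, n1, n2, ok = _ibs_counts(np.asarray(gi), np.asarray(gj), poly)
    p = freqs[ok]
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibd_expectations(p)
    return _solve_ibd(n0, n1, n2, e0_0.sum(), e1_0.sum(), e2_0.sum(),
                      e1_1.sum(), e2_1.sum(), int(ok.sum()))


def pihat_matrix(codes: np.ndarray, samples=None, freqs=None) -> KinshipMatrix:
    """Vectorized pairwise pi-hat over a complete 012 matrix (sites x samples).

    Requires no missing data (impute or drop first); frequencies default to
    the sample alternate-allele frequencies of the matrix itself.
    """
    codes = np.asarray(codes)
    if (codes == MISSING).any():
        raise ValueError("pihat_matrix requires a complete matrix")
    if freqs is None:
        freqs = codes.mean(axis=1) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("pi-hat needs polymorphic loci")
    g = codes[poly].astype(np.float64)
    p = freqs[poly]
    n_loci, n = g.shape
    # indicator matrices per genotype value turn IBS counting into matmuls
    m0 = (g == 0).astype(np.float64)
    m1 = (g == 1).astype(np.float64)
    m2 = (g == 2).astype(np.float64)
    n0 = m0.T @ m2 + m2.T @ m0
    n1 = (m0 + m2).T @ m1 + m1.T @ (m0 + m2)
    n2 = n_loci - n0 - n1
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibd_expectations(p)
    s0_0, s1_0, s2_0 = e0_0.sum(), e1_0.sum(), e2_0.sum()
    s1_1, s2_1 = e1_1.sum(), e2_1.sum()
    p0 = n0 / s0_0
    p1 = (n1 - p0 * s1_0) / s1_1
    p2 = (n2 - p0 * s2_0 - p1 * s2_1) / n_loci
    probs = np.stack([p0, p1, p2]).clip(0.0, 1.0)
    probs /= probs.sum(axis=0, keepdims=True)
    values = probs[1] / 2 + probs[2]
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    if samples is None:
        samples = list(range(n))
    return KinshipMatrix(list(samples), values)


def clone_threshold_from_cohorts(pihat_values, cohort_pairs=None, fallback=None,
                                 bandwidth=None):
    """Clone threshold at the density valley below the clone peak.

    A Gaussian kernel density is fitted to all pairwise pi-hat values; the
    threshold is the location of the density minimum between the rightmost
    peak (clones, pi-hat near 1) and the peak immediately below it
    (parent-offspring / close kin, anchored by ``cohort_pairs`` sib pi-hat
    values when provided). If the density is unimodal the method falls back
    to ``fallback`` (e.g. a normal-law significance threshold) and flags it.
    Returns ``(threshold, info)``.
    """
    x = np.asarray(pihat_values, dtype=float)
    grid = np.linspace(0.0, 1.0, 512)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    is_peak = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = grid[interior[is_peak]]
    # a mode pressed against either edge of [0, 1] is still a mode
    if dens[0] > dens[1]:
        peaks = np.concatenate([[grid[0]], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid[-1]]])
    if len(peaks) < 2:
        if fallback is None:
            raise ValueError("pi-hat density is unimodal and no fallback threshold given")
        return float(fallback), {"fallback": True, "peaks": peaks.tolist()}
    clone_peak = peaks[-1]
    if cohort_pairs is not None and len(cohort_pairs):
        # sib/parent-offspring pairs anchor the kin peak even when too few to
        # raise a KDE mode of their own: search strictly above their range
        lower_peak = float(np.quantile(cohort_pairs, 0.95))
    else:
        lower_peak = peaks[-2]
    lo, hi = np.searchsorted(grid, [lower_peak, clone_peak])
    valley = grid[lo + int(np.argmin(dens[lo:hi + 1]))]
    return float(valley), {"fallback": False, "peaks": peaks.tolist(),
                           "lower_peak": float(lower_peak), "clone_peak": float(clone_peak)}


def mll_partition(relatedness: KinshipMatrix, threshold: float, seed: int = 0) -> MLLPartition:
    """Partition samples into MLLs as connected components above the threshold.

    Components of size >= 2 become clone clusters named MLL001, MLL002, ...
    (ordered by their first member); singletons are unique genotypes. One
    representative per MLL is drawn with the given seed.
    """
    n = len(relatedness.samples)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    above = np.argwhere(np.triu(relatedness.values > threshold, k=1))
    g.add_edges_from(map(tuple, above))
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    rng = np.random.default_rng(seed)
    clusters, singles, reps = {}, [], {}
    k = 0
    for comp in comps:
        members = [relatedness.samples[i] for i in comp]
        if len(members) == 1:
            singles.append(members[0])
        else:
            k += 1
            cid = f"MLL{k:03d}"
            clusters[cid] = members
            reps[cid] = members[int(rng.integers(len(members)))]
    return MLLPartition(clusters, singles, float(threshold), reps)


def genotypic_richness(n_genotypes: int, n_samples: int) -> float:
    """R = (G - 1)/(N - 1): 0 when all samples are one clone, 1 when all distinct."""
    if n_samples < 2:
        raise ValueError("genotypic richness undefined for N < 2")
    return (n_genotypes - 1) / (n_samples - 1)


def fis(codes: np.ndarray) -> float:
    """Fixation index 1 - Ho/He averaged over polymorphic loci.

    ``codes`` is a (sites x samples) 012 matrix for one group (missing
    allowed). He = 2pq from observed allele frequencies. Negative values
    indicate heterozygote excess, the signature of clonal propagation.
    """
    codes = np.asarray(codes)
    obs = codes != MISSING
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, codes, 0).sum(axis=1) / (2 * np.maximum(n_obs, 1))
        ho = (codes == 1).sum(axis=1) / np.maximum(n_obs, 1)
    poly = (n_obs > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("Fis undefined without polymorphic loci")
    he = 2 * p[poly] * (1 - p[poly])
    return float(np.mean(1 - ho[poly] / he))


def export_network(relatedness: KinshipMatrix, threshold: float, path_prefix,
                   node_attrs: dict | None = None):
    """Write the significant-relatedness network as GraphML + TSV edge list.

    ``node_attrs`` maps sample id -> dict of attributes (e.g. pop, ploidy)
    attached to nodes. Returns the networkx graph. Layout is left to
    downstream viewers.
    """
    g = nx.Graph()
    for s in relatedness.samples:
        g.add_node(str(s), **{k: str(v) for k, v in (node_attrs or {}).get(s, {}).items()})
    n = len(relatedness.samples)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            v = relatedness.values[i, j]
            if v > threshold:
                a, b = str(relatedness.samples[i]), str(relatedness.samples[j])
                g.add_edge(a, b, weight=float(v))
                edges.append((a, b, float(v)))
    nx.write_graphml(g, f"{path_prefix}.graphml")
    with open(f"{path_prefix}.tsv", "w") as fh:
        fh.write("sample_i\tsample_j\tkinship\n")
        for a, b, v in edges:
            fh.write(f"{a}\t{b}\t{v:.6f}\n")
    return g
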