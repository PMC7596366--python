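"""Synthetic mixed-ploidy GBS datasets with known truth.

The generator emulates the structure of a genotyping-by-sequencing panel of a
clonally propagated autopolyploid crop: diploid founders drawn from several
diverged gene pools, triploids and tetraploids formed through unreduced
gametes, clonal lineages that differ only by somatic mutations, and per-cell
read counts drawn binomially at a configurable depth with sequencing error and
missing data. Every stage is driven by an explicit integer seed so fixtures
are reproducible.

Founder gene pools are produced by a forward Wright-Fisher sampler: allele
frequencies drift by binomial resampling each generation, populations branch
off a single trunk at the configured split times (most recent first), and an
island-model migration term mixes frequencies of coexisting pools.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .tables import MISSING, ReadCountTable

#: minimum reads of each allele for a heterozygous call in synthetic VCFs
MIN_MINOR_READS = 2


@dataclass
class PopConfig:
    """Demographic configuration for the founder simulator.

    ``split_times`` are ages in generations, strictly increasing; population
    ``k`` (for ``k >= 1``) branches off the trunk (population 0) at
    ``split_times[k-1]``, so later-listed pools split deeper in the past.
    ``pop_sizes`` are diploid effective sizes. ``migration_rate`` is the
    per-generation fraction of each pool's gene pool replaced by the average
    of the other coexisting pools (island model).
    """

    n_pops: int = 3
    split_times: tuple = (200, 400, 800)
    pop_sizes: tuple = (500, 500, 500)
    migration_rate: float = 0.0
    n_sites: int = 2000
    n_chroms: int = 20
    chrom_length: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")
        times = list(self.split_times[: self.n_pops - 1])
        if len(times) < self.n_pops - 1:
            raise ValueError("need n_pops - 1 split times")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("split_times must be strictly increasing (backwards in time)")
        if len(self.pop_sizes) < self.n_pops:
            raise ValueError("need one pop_size per population")


@dataclass
class DepthModel:
    """Read-sampling model for one GBS library.

    ``error_rate`` is the per-read probability of reading the other allele;
    ``missing_rate`` is the per-cell probability of a dropout (depth 0).
    """

    mean_depth: float = 60.0
    depth_distribution: str = "poisson"  # "fixed" | "poisson"
    error_rate: float = 0.005
    missing_rate: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.depth_distribution not in ("fixed", "poisson"):
            raise ValueError("depth_distribution must be 'fixed' or 'poisson'")


@dataclass
class AccessionTruth:
    """Ground truth for one synthetic accession."""

    sample_id: str
    pop_label: str
    ploidy: int
    clone_id: str | None
    dosage: np.ndarray  # alt-allele dosage per site, each in [0, ploidy]

    def copy(self) -> "AccessionTruth":
        out = copy.copy(self)
        out.dosage = self.dosage.copy()
        return out


def _assign_positions(n_sites: int, n_chroms: int, chrom_length: int, rng) -> tuple:
    """Spread sites uniformly over chromosomes; 1-based sorted positions."""
    chrom_idx = np.sort(rng.integers(0, n_chroms, size=n_sites))
    pos = np.empty(n_sites, dtype=np.int64)
    for c in range(n_chroms):
        mask = chrom_idx == c
        k = int(mask.sum())
        if k == 0:
            continue
        # sample without replacement so positions are unique within a chromosome
        p = rng.choice(chrom_length, size=k, replace=False) + 1
        pos[mask] = np.sort(p)
    chrom = np.array([f"chr{c + 1:02d}" for c in chrom_idx])
    return chrom, pos


def simulate_founder_frequencies(cfg: PopConfig, ancestral_freqs=None) -> np.ndarray:
    """Per-pool allele frequencies after drift, shape ``(n_pops, n_sites)``.

    Ancestral frequencies default to Beta(0.5, 0.5), a U-shaped spectrum that
    drifts into a realistic mix of rare and common variants.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if ancestral_freqs is None:
        p_anc = rng.beta(0.5, 0.5, size=cfg.n_sites)
    else:
        p_anc = np.broadcast_to(np.asarray(ancestral_freqs, dtype=float), (cfg.n_sites,)).copy()

    # ages at which each pool comes into existence (trunk exists from the start)
    birth_age = [np.inf] + list(cfg.split_times[: cfg.n_pops - 1])
    t_start = max([t for t in birth_age[1:]], default=0)
    freqs = {0: p_anc.copy()}
    for age in range(int(t_start), 0, -1):
        for k in range(1, cfg.n_pops):
            if birth_age[k] == age:  # pool k branches off the trunk now
                freqs[k] = freqs[0].copy()
        active = sorted(freqs)
        if cfg.migration_rate > 0 and len(active) > 1:
            mean_p = np.mean([freqs[k] for k in active], axis=0)
            for k in active:
                freqs[k] = (1 - cfg.migration_rate) * freqs[k] + cfg.migration_rate * mean_p
        for k in active:
            two_n = 2 * int(cfg.pop_sizes[k])
            freqs[k] = rng.binomial(two_n, freqs[k]) / two_n
    for k in range(cfg.n_pops):
        freqs.setdefault(k, p_anc.copy())
    return np.stack([freqs[k] for k in range(cfg.n_pops)])


def simulate_founders(cfg: PopConfig, n_per_pop: int = 30, ancestral_freqs=None):
    """Draw diploid founder accessions from each gene pool.

    Returns ``(founders, sites)`` where ``founders`` is a list of
    :class:`AccessionTruth` with dosages in {0,1,2} (Hardy-Weinberg draws from
    the pool frequency) and ``sites`` is a ``(chrom, pos)`` tuple of arrays.
    """
    pool_freqs = simulate_founder_frequencies(cfg, ancestral_freqs)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chrom, pos = _assign_positions(cfg.n_sites, cfg.n_chroms, cfg.chrom_length, rng)
    founders = []
    for k in range(cfg.n_pops):
        for i in range(n_per_pop):
            dosage = rng.binomial(2, pool_freqs[k]).astype(np.int8)
            founders.append(
                AccessionTruth(
                    sample_id=f"P{k + 1}_D{i + 1:03d}",
                    pop_label=f"pop{k + 1}",
                    ploidy=2,
                    clone_id=None,
                    dosage=dosage,
                )
            )
    return founders, (chrom, pos)


def _reduced_gamete(dosage: np.ndarray, rng) -> np.ndarray:
    """One meiotic gamete from a diploid: each site passes 0/1 alt copies."""
    return rng.binomial(1, dosage / 2.0).astype(np.int8)


def make_polyploids(diploids, triploid_fraction: float, tetraploid_fraction: float, seed: int):
    """Create triploids/tetraploids via unreduced gametes within gene pools.

    A triploid receives a reduced gamete from one diploid parent plus the full
    (unreduced) dosage of a second; a tetraploid receives two unreduced
    gametes. Counts are fractions of the diploid set size, and parents are
    drawn from a single gene pool. Returns the input diploids followed by the
    new polyploids.
    """
    if triploid_fraction < 0 or tetraploid_fraction < 0:
        raise ValueError("fractions must be >= 0")
    if triploid_fraction + tetraploid_fraction > 1:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[AccessionTruth]] = {}
    for acc in diploids:
        pools.setdefault(acc.pop_label, []).append(acc)
    for label, members in pools.items():
        if len(members) < 2:
            raise ValueError(f"gene pool {label!r} has fewer than 2 diploids")
    labels = sorted(pools)
    n_tri = int(round(triploid_fraction * len(diploids)))
    n_tet = int(round(tetraploid_fraction * len(diploids)))
    out = list(diploids)
    for j in range(n_tri + n_tet):
        pool = pools[labels[rng.integers(len(labels))]]
        a, b = rng.choice(len(pool), size=2, replace=False)
        parent_a, parent_b = pool[a], pool[b]
        if j < n_tri:
            dosage = _reduced_gamete(parent_a.dosage, rng) + parent_b.dosage
            ploidy, tag, idx = 3, "T", j + 1
        else:
            dosage = parent_a.dosage + parent_b.dosage
            ploidy, tag, idx = 4, "Q", j - n_tri + 1
        out.append(
            AccessionTruth(
                sample_id=f"{parent_a.pop_label}_{tag}{idx:03d}",
                pop_label=parent_a.pop_label,
                ploidy=ploidy,
                clone_id=None,
                dosage=dosage.astype(np.int8),
            )
        )
    return out


def clonal_expand(founder: AccessionTruth, n_ramets: int, somatic_mu: float, seed: int):
    """Propagate a founder clonally; each ramet carries its own somatic mutations.

    Each ramet differs from the founder at ``Poisson(somatic_mu * n_sites)``
    sites; a somatic mutation shifts the dosage at a site by one allele copy
    (up or down, bounded by [0, ploidy]). The founder's ``clone_id`` is set
    (to its sample id if unset) and shared by all ramets. Returns the list of
    ramets; the founder itself is not duplicated.
    """
    if somatic_mu < 0:
        raise ValueError("somatic_mu must be >= 0")
    rng = np.random.default_rng(seed)
    if founder.clone_id is None:
        founder.clone_id = founder.sample_id
    n_sites = len(founder.dosage)
    ramets = []
    for r in range(n_ramets):
        ramet = founder.copy()
        ramet.sample_id = f"{founder.sample_id}_r{r + 1}"
        n_mut = rng.poisson(somatic_mu * n_sites)
        n_mut = min(n_mut, n_sites)
        if n_mut:
            sites = rng.choice(n_sites, size=n_mut, replace=False)
            for s in sites:
                d = ramet.dosage[s]
                if d == 0:
                    d = 1
                elif d == founder.ploidy:
                    d -= 1
                else:
                    d += rng.choice([-1, 1])
                ramet.dosage[s] = d
        ramets.append(ramet)
    return ramets


def expected_alt_fraction(dosage, ploidy, error_rate):
    """E[alt-read fraction] = (1-e) * dosage/ploidy + e * (1 - dosage/ploidy)."""
    theta = np.asarray(dosage, dtype=float) / ploidy
    return (1 - error_rate) * theta + error_rate * (1 - theta)


def sample_reads(truths, dm: DepthModel, seed: int, sites=None) -> ReadCountTable:
    """Draw per-cell read counts and genotype calls for a set of accessions.

    Depth per cell follows ``dm.depth_distribution``; cells drop out with
    probability ``dm.missing_rate`` (depth 0, missing call). Alt reads are
    ``Binomial(depth, (1-e) * dosage/ploidy + e * (1 - dosage/ploidy))``.
    The het call rule is documented in :data:`MIN_MINOR_READS`: a call is
    heterozygous iff both alleles are seen in >= 2 reads; otherwise the
    majority allele is called homozygous (ties go to the reference).
    """
    dm.validate()
    rng = np.random.default_rng(seed)
    truths = list(truths)
    n_sites = len(truths[0].dosage)
    n_samples = len(truths)
    if sites is None:
        chrom, pos = _assign_positions(n_sites, 20, max(1_000_000, 2 * n_sites), rng)
    else:
        chrom, pos = sites
        chrom, pos = np.asarray(chrom), np.asarray(pos)

    depth = np.empty((n_sites, n_samples), dtype=np.int32)
    alt = np.empty_like(depth)
    for j, acc in enumerate(truths):
        if dm.depth_distribution == "fixed":
            d = np.full(n_sites, int(round(dm.mean_depth)), dtype=np.int32)
        else:
            d = rng.poisson(dm.mean_depth, size=n_sites).astype(np.int32)
        if dm.missing_rate > 0:
            d[rng.random(n_sites) < dm.missing_rate] = 0
        p_alt = expected_alt_fraction(acc.dosage, acc.ploidy, dm.error_rate)
        alt[:, j] = rng.binomial(d, p_alt)
        depth[:, j] = d
    ref = depth - alt

    gt = np.full((n_sites, n_samples), MISSING, dtype=np.int8)
    covered = depth > 0
    het = (ref >= MIN_MINOR_READS) & (alt >= MIN_MINOR_READS)
    gt[covered] = np.where(alt[covered] > ref[covered], 2, 0)
    gt[covered & het] = 1

    return ReadCountTable(
        samples=[a.sample_id for a in truths],
        chrom=chrom,
        pos=pos,
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "T"),
        ref_reads=ref,
        alt_reads=alt,
        depth=depth,
        gt=gt,
    )


def simulate_het_accession(ploidy: int, n_het_sites: int, depth: float, error_rate: float,
                           seed: int, depth_distribution: str = "poisson") -> ReadCountTable:
    """Benchmark accession for ploidy inference: every site heterozygous.

    Dosages are drawn uniformly from {1, ..., ploidy-1}, so the alt-read
    fraction distribution has the textbook modes (1/2 for diploids, 1/3 and
    2/3 for triploids, 1/4, 1/2, 3/4 for tetraploids).
    """
    if ploidy not in (2, 3, 4):
        raise ValueError("ploidy must be 2, 3 or 4")
    rng = np.random.default_rng(seed)
    dosage = rng.integers(1, ploidy, size=n_het_sites).astype(np.int8)
    acc = AccessionTruth(
        sample_id=f"bench_{ploidy}x", pop_label="bench", ploidy=ploidy,
        clone_id=None, dosage=dosage,
    )
    dm = DepthModel(mean_depth=depth, depth_distribution=depth_distribution,
                    error_rate=error_rate, missing_rate=0.0)
    return sample_reads([acc], dm, seed=int(rng.integers(2**31)))


def _cross(parent_a: AccessionTruth, parent_b: AccessionTruth, sample_id: str, rng):
    dosage = _reduced_gamete(parent_a.dosage, rng) + _reduced_gamete(parent_b.dosage, rng)
    return AccessionTruth(sample_id, parent_a.pop_label, 2, None, dosage.astype(np.int8))


def simulate_clonal_panel(n_clone_groups: int = 40, n_singletons: int = 53,
                          n_clonal_total: int = 247, n_sites: int = 5000,
                          somatic_mu: float = 2e-4, n_progeny: int = 15,
                          seed: int = 0):
    """Diploid panel with planted clonal structure and two sib progenies.

    Emulates a calibration design for clone detection in a clonally
    propagated crop: independent diploid founders from one gene pool, of
    which ``n_clone_groups`` are expanded into clonal lineages (group sizes
    between 2 and 19 ramets, summing to ``n_clonal_total``) while
    ``n_singletons`` stay unique; plus two progenies of ``n_progeny``
    full/half sibs sharing one parent, giving known parent-offspring pairs.

    Returns ``(codes, clone_labels, meta)``: a 012 matrix (sites x samples)
    of true genotypes, the truth partition label per panel sample, and a dict
    with sample ids, the parent-offspring index pairs and the
    progeny/founder bookkeeping.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    n_founders = n_clone_groups + n_singletons
    founders = [
        AccessionTruth(f"F{i:03d}", "pool", 2, None,
                       rng.binomial(2, freqs).astype(np.int8))
        for i in range(n_founders)
    ]
    # clone-group sizes: 2..19 ramets summing to the requested total
    sizes = rng.integers(2, 20, size=n_clone_groups)
    while sizes.sum() != n_clonal_total:
        j = rng.integers(n_clone_groups)
        step = 1 if sizes.sum() < n_clonal_total else -1
        if 2 <= sizes[j] + step <= 19:
            sizes[j] += step

    panel, labels = [], []
    for g in range(n_clone_groups):
        founder = founders[g]
        ramets = clonal_expand(founder, int(sizes[g]) - 1, somatic_mu,
                               seed=int(rng.integers(2**31)))
        for acc in [founder] + ramets:
            panel.append(acc)
            labels.append(g)
    for s in range(n_singletons):
        acc = founders[n_clone_groups + s]
        panel.append(acc)
        labels.append(n_clone_groups + s)

    # two progenies sharing parent p0 anchor the clone-threshold calibration
    p0, p1, p2 = (AccessionTruth(f"PP{i}", "pool", 2, None,
                                 rng.binomial(2, freqs).astype(np.int8))
                  for i in range(3))
    progeny, po_pairs = [], []
    parents = [p0, p1, p2]
    offset = len(panel) + 3
    for fam, other in ((1, p1), (2, p2)):
        for i in range(n_progeny):
            child = _cross(p0, other, f"PR{fam}_{i:02d}", rng)
            progeny.append(child)
    everyone = panel + parents + progeny
    for i, child in enumerate(progeny):
        po_pairs.append((len(panel), offset + i))  # (p0, child)
    codes = np.stack([a.dosage for a in everyone], axis=1)
    meta = {
        "samples": [a.sample_id for a in everyone],
        "n_panel": len(panel),
        "po_pairs": po_pairs,
        "progeny_idx": list(range(offset, offset + len(progeny))),
        "parent_idx": [len(panel), len(panel) + 1, len(panel) + 2],
    }
    return codes, np.array(labels), meta


def write_vcf(table: ReadCountTable, path, truth=None) -> None:
    """Write a VCF 4.2 file with GT:AD:DP, one contig line per chromosome."""
    chroms = sorted(set(table.chrom.tolist()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=yampop-synth\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        order = np.lexsort((table.pos, table.chrom))
        for i in order:
            cells = []
            for j in range(table.n_samples):
                g = gt_str[int(table.gt[i, j])]
                cells.append(f"{g}:{table.ref_reads[i, j]},{table.alt_reads[i, j]}:{table.depth[i, j]}")
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}"
                     f"\t.\t.\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n")


def write_truth(truths, path) -> None:
    """Truth table as TSV: sample_id, pop, ploidy, clone_id."""
    with open(path, "w") as fh:
        fh.write("sample_id\tpop\tploidy\tclone_id\n")
        for acc in truths:
            clone = acc.clone_id if acc.clone_id is not None else "."
            fh.write(f"{acc.sample_id}\t{acc.pop_label}\t{acc.ploidy}\t{clone}\n")
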