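"""Windowed diversity and differentiation statistics for diploid panels.

Statistics are computed per 100-kb genomic bin containing at least three
SNPs: nucleotide diversity pi (unbiased per-site heterozygosity, optionally
normalized per base pair of the bin), Tajima's D, and the Weir & Cockerham
variance-components Fst between population pairs. Missing genotypes are
excluded per site, so the number of sampled allele copies varies by site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import MISSING, GenotypeMatrix

BIN_WIDTH = 100_000
MIN_SNPS_PER_BIN = 3


def _allele_counts(codes: np.ndarray):
    """Per-site (alt copies, total observed copies) for a 012 matrix."""
    obs = codes != MISSING
    n = 2 * obs.sum(axis=1)
    alt = np.where(obs, codes, 0).sum(axis=1)
    return alt.astype(float), n.astype(float)


def site_diversity(codes: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi: (n/(n-1)) * 2 p q over n observed allele copies."""
    alt, n = _allele_counts(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        pi = np.where(n > 1, n / (n - 1) * 2 * p * (1 - p), np.nan)
    return pi


def tajima_constants(n: int) -> dict:
    """Standard constants a1..e2 for a sample of n sequences."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(k_bar: float, n_segregating: int, n: int) -> float:
    """D = (k_bar - S/a1) / sqrt(e1 S + e2 S (S-1)); NaN when S = 0."""
    if n_segregating == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * n_segregating + c["e2"] * n_segregating * (n_segregating - 1)
    return float((k_bar - n_segregating / c["a1"]) / np.sqrt(var))


def tajimas_d_from_codes(codes: np.ndarray) -> float:
    """Tajima's D for a set of sites from a 012 matrix.

    k_bar sums the per-site mean pairwise difference (n/(n-1) * 2pq); the
    sample size entering the constants is the rounded mean number of observed
    allele copies over segregating sites (exact when data are complete).
    """
    alt, n = _allele_counts(codes)
    seg = (alt > 0) & (alt < n)
    if not seg.any():
        return float("nan")
    pi = site_diversity(codes)[seg]
    n_eff = int(round(n[seg].mean()))
    return tajimas_d(float(np.nansum(pi)), int(seg.sum()), n_eff)


def make_bins(chrom: np.ndarray, pos: np.ndarray, width: int = BIN_WIDTH,
              min_snps: int = MIN_SNPS_PER_BIN) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins; keep bins with enough SNPs.

    Positions are 1-based; bins are half-open [start, end) on the 0-based
    scale internally and reported 1-based inclusive. Returns a DataFrame with
    chrom, start, end, n_snps and the site indices of each bin.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    bin_idx = (pos - 1) // width
    df = pd.DataFrame({"chrom": chrom, "bin": bin_idx, "site": np.arange(len(pos))})
    rows = []
    for (c, b), grp in df.groupby(["chrom", "bin"], sort=True):
        if len(grp) < min_snps:
            continue
        rows.append({
            "chrom": c,
            "start": int(b) * width + 1,
            "end": (int(b) + 1) * width,
            "n_snps": len(grp),
            "sites": grp["site"].to_numpy(),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "sites"])


def bin_statistics(gm: GenotypeMatrix, width: int = BIN_WIDTH,
                   min_snps: int = MIN_SNPS_PER_BIN, per_bp: bool = False) -> pd.DataFrame:
    """Per-bin pi and Tajima's D for one population.

    ``per_bp=True`` divides the summed site pi by the bin width (the scale on
    which whole-genome surveys report ~1e-5 diversity); otherwise pi is the
    mean over analyzed variant sites.
    """
    bins = make_bins(gm.chrom, gm.pos, width, min_snps)
    pis, ds = [], []
    for _, row in bins.iterrows():
        codes = gm.codes[row["sites"]]
        pi = site_diversity(codes)
        pis.append(float(np.nansum(pi)) / (width if per_bp else len(pi)))
        ds.append(tajimas_d_from_codes(codes))
    bins = bins.drop(columns="sites")
    bins["pi"] = pis
    bins["tajima_d"] = ds
    return bins


def weir_cockerham_fst(codes1: np.ndarray, codes2: np.ndarray):
    """Weir & Cockerham (1984) Fst between two populations of diploids.

    Returns ``(per_site, mean)`` where per-site values are a/(a+b+c) from the
    among-population (a), among-individual (b) and within-individual (c)
    variance components, and the mean is the ratio of sums over sites (the
    standard multi-locus combination; slightly negative means are possible
    and retained). Sites where no component information exists are NaN.
    """
    comps = []
    for codes in (codes1, codes2):
        codes = np.asarray(codes)
        if codes.shape[1] < 2:
            raise ValueError("each population needs >= 2 individuals")
        obs = codes != MISSING
        n_i = obs.sum(axis=1).astype(float)  # individuals observed per site
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(obs, codes, 0).sum(axis=1) / (2 * np.maximum(n_i, 1))
            h_i = (codes == 1).sum(axis=1) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = n_bar / n_c * (s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar)
                                                   - (r - 1) / r * s2 - h_bar / 4))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        per_site = np.where(denom != 0, a / denom, np.nan)
    usable = np.isfinite(denom) & (denom != 0)
    mean = float(a[usable].sum() / denom[usable].sum()) if usable.any() else float("nan")
    per_site = np.where(usable, per_site, np.nan)
    return per_site, mean


def pairwise_fst_table(gm: GenotypeMatrix, pop_of: dict, width: int = BIN_WIDTH,
                       min_snps: int = MIN_SNPS_PER_BIN) -> pd.DataFrame:
    """Mean Fst for every population pair, per 100-kb bin and overall."""
    pops = sorted(set(pop_of.values()))
    cols = {p: [i for i, s in enumerate(gm.samples) if pop_of.get(s) == p] for p in pops}
    bins = make_bins(gm.chrom, gm.pos, width, min_snps)
    rows = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            c1, c2 = gm.codes[:, cols[p1]], gm.codes[:, cols[p2]]
            _, overall = weir_cockerham_fst(c1, c2)
            bin_means = []
            for _, row in bins.iterrows():
                _, m = weir_cockerham_fst(c1[row["sites"]], c2[row["sites"]])
                bin_means.append(m)
            rows.append({"pop1": p1, "pop2": p2, "fst": overall,
                         "fst_bin_mean": float(np.nanmean(bin_means)) if bin_means else np.nan})
    return pd.DataFrame(rows)
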