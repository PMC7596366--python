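"""VCF loading and the two SNP-filtering regimes.

The standard regime keeps biallelic SNPs with per-cell depth >= 8 (cells
below are masked to missing first), minor-allele count >= 3, minor-allele
frequency >= 0.05 and at most 10% missing calls. The SFS regime is identical
except that the frequency filter is disabled, so rare variants are retained
for demographic inference. Filters are applied in a fixed, documented order
and their removal counts reported per criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .tables import MISSING, GenotypeMatrix, ReadCountTable

#: fixed application order for site filters
FILTER_ORDER = ("depth_mask", "biallelic", "mac", "maf", "missingness")


@dataclass
class FilterParams:
    min_depth: int = 8
    min_allele_count: int = 3
    min_maf: float | None = 0.05  # None disables (SFS regime)
    biallelic_only: bool = True
    max_missing: float = 0.10

    def validate(self) -> None:
        if self.min_maf is not None and not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")

    @classmethod
    def sfs_regime(cls, **kw) -> "FilterParams":
        """Same thresholds without the minimum-allele-frequency filter."""
        return cls(min_maf=None, **kw)


class VcfFormatError(ValueError):
    pass


def load_vcf(path):
    """Read a VCF with GT (and AD/DP if present) into a ReadCountTable.

    Returns ``(table, genotype_matrix)``. Coordinates stay 1-based.
    Multiallelic records are retained but flagged via ``table.is_biallelic``.
    Raises :class:`VcfFormatError` if the file has no GT field or a record
    cannot be parsed (the error names the offending record number).
    """
    vcf = VCF(str(path), gts012=True)
    if "ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: no GT field in FORMAT header")
    samples = list(vcf.samples)
    n = len(samples)
    chrom, pos, ref, alt = [], [], [], []
    biallelic = []
    gts, ads_ref, ads_alt, dps = [], [], [], []
    for rec_no, v in enumerate(vcf, start=1):
        try:
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(",".join(v.ALT) if v.ALT else ".")
            biallelic.append(len(v.ALT) == 1)
            # cyvcf2 gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
            g = np.asarray(v.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            gts.append(g)
            ad = v.format("AD")
            if ad is not None:
                ad = np.asarray(ad, dtype=np.int64)
                ad[ad < 0] = 0
                ads_ref.append(ad[:, 0])
                ads_alt.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(n, dtype=np.int64))
            else:
                ads_ref.append(np.zeros(n, dtype=np.int64))
                ads_alt.append(np.zeros(n, dtype=np.int64))
            dp = v.format("DP")
            if dp is not None:
                dp = np.asarray(dp, dtype=np.int64).reshape(n)
                dp[dp < 0] = 0
            else:
                dp = ads_ref[-1] + ads_alt[-1]
            dps.append(dp)
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfFormatError(f"{path}: malformed record {rec_no}: {exc}") from exc
    if not pos:
        warnings.warn(f"{path}: no variant records")
    table = ReadCountTable(
        samples=samples,
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        ref_reads=np.array(ads_ref, dtype=np.int32).reshape(len(pos), n),
        alt_reads=np.array(ads_alt, dtype=np.int32).reshape(len(pos), n),
        depth=np.array(dps, dtype=np.int32).reshape(len(pos), n),
        gt=np.array(gts, dtype=np.int8).reshape(len(pos), n),
        is_biallelic=np.array(biallelic, dtype=bool),
    )
    # depth-0 cells are missing by convention even if a caller emitted a GT
    table.gt[table.depth == 0] = MISSING
    return table, table.genotype_matrix()


def apply_site_filters(table: ReadCountTable, params: FilterParams):
    """Apply the filtering regime; returns ``(filtered_table, removal_counts)``.

    Order is fixed: per-cell depth masking first (cells with depth below
    ``min_depth`` become missing; the count reported is masked cells), then
    site-level biallelic, minor-allele-count, minor-allele-frequency and
    missingness tests, each evaluated on the calls that survive the previous
    steps. Allele counts/frequencies use non-missing diploid calls after the
    depth mask. Idempotent by construction.
    """
    params.validate()
    table = table.take_sites(np.arange(table.n_sites))  # defensive copy
    counts = dict.fromkeys(FILTER_ORDER, 0)

    mask = (table.depth < params.min_depth) & (table.gt != MISSING)
    counts["depth_mask"] = int(mask.sum())
    table.gt[mask] = MISSING

    keep = np.ones(table.n_sites, dtype=bool)
    if params.biallelic_only:
        fail = keep & ~table.is_biallelic
        counts["biallelic"] = int(fail.sum())
        keep &= table.is_biallelic

    obs = table.gt != MISSING
    n_obs = obs.sum(axis=1)
    alt_count = np.where(obs, table.gt, 0).sum(axis=1)
    total = 2 * n_obs
    mac = np.minimum(alt_count, total - alt_count)

    fail = keep & (mac < params.min_allele_count)
    counts["mac"] = int(fail.sum())
    keep &= ~fail

    if params.min_maf is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(total > 0, mac / np.maximum(total, 1), 0.0)
        fail = keep & (maf < params.min_maf)
        counts["maf"] = int(fail.sum())
        keep &= ~fail

    miss_frac = 1 - n_obs / table.n_samples
    fail = keep & (miss_frac > params.max_missing)
    counts["missingness"] = int(fail.sum())
    keep &= ~fail

    out = table.take_sites(keep)
    if out.n_sites == 0:
        warnings.warn("no sites survive filtering")
    return out, counts


def encode_012_impute(gm: GenotypeMatrix):
    """Mean-impute the 012 matrix; returns ``(float matrix, kept site mask)``.

    Missing cells take the per-site mean of observed codes (so imputed values
    are fractional on [0, 2]); observed cells are unchanged. Sites with no
    observed call are dropped with a warning.
    """
    codes = gm.codes.astype(float)
    obs = gm.codes != MISSING
    n_obs = obs.sum(axis=1)
    keep = n_obs > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} sites with no observed calls")
    codes = codes[keep]
    obs = obs[keep]
    means = np.where(obs, codes, 0).sum(axis=1) / obs.sum(axis=1)
    codes = np.where(obs, codes, means[:, None])
    return codes, keep
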