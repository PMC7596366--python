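"""Core in-memory containers shared across the pipeline.

Layout convention: sites are rows, samples are columns, matching the VCF
record-per-site orientation. Genotype codes are alternate-allele dosage on the
diploid 012 scale with ``-1`` marking a missing call. Coordinates are 1-based,
as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1


@dataclass
class ReadCountTable:
    """Per-site x per-sample read counts and genotype calls.

    ``ref_reads``, ``alt_reads``, ``depth`` and ``gt`` are ``(n_sites,
    n_samples)`` integer arrays; ``gt`` holds 0/1/2 dosage codes with -1 for
    missing. ``is_biallelic`` flags sites that had exactly one ALT allele in
    the source VCF (multiallelic records are retained but flagged).
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    depth: np.ndarray
    gt: np.ndarray
    is_biallelic: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(self.n_sites, dtype=bool)
        n, m = self.n_sites, self.n_samples
        for name in ("ref_reads", "alt_reads", "depth", "gt"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def take_sites(self, idx) -> "ReadCountTable":
        """Return a new table restricted to the given site indices."""
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ref_reads=self.ref_reads[idx],
            alt_reads=self.alt_reads[idx],
            depth=self.depth[idx],
            gt=self.gt[idx],
            is_biallelic=self.is_biallelic[idx],
        )

    def genotype_matrix(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            codes=self.gt.copy(),
        )

    def equals(self, other: "ReadCountTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref_reads, other.ref_reads)
            and np.array_equal(self.alt_reads, other.alt_reads)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.gt, other.gt)
        )


@dataclass
class GenotypeMatrix:
    """012 genotype codes (sites x samples) with site coordinates."""

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    codes: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            codes=self.codes[idx],
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset samples by a list of ids or an index array."""
        if len(which) and isinstance(which[0], str):
            idx = [self.samples.index(s) for s in which]
        else:
            idx = list(which)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            codes=self.codes[:, idx],
        )
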