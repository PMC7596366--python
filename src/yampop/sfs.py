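"""Joint site-frequency spectra with missing-data projection.

The 2-D SFS for a population pair counts SNPs by their alternate-allele copy
number in each population. Missing genotypes are handled by hypergeometric
projection: each site's observed allele counts are projected down to a fixed
number of copies per population (the size of the smallest population) by
taking the expectation over all subsamples, which is deterministic and has
lower variance than resampling once. Sites observed in fewer copies than the
projection size in either population are dropped and counted.

The alternate allele is treated as derived by default (the reference genome
being an outgroup species); a folded mode is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .tables import MISSING


@dataclass
class JointSFS:
    pop_labels: tuple
    sizes: tuple  # projected sample sizes in allele copies
    matrix: np.ndarray  # (sizes[0]+1) x (sizes[1]+1) site masses
    folded: bool = False
    n_dropped: int = 0

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def proportions(self, exclude_fixed: bool = True) -> np.ndarray:
        """Entry proportions; fixed corners (0,0) and (d1,d2) optionally zeroed."""
        m = self.matrix.copy()
        if exclude_fixed:
            m[0, 0] = 0.0
            m[-1, -1] = 0.0
        s = m.sum()
        return m / s if s > 0 else m

    def fold(self) -> "JointSFS":
        """Fold onto the minor allele: entries with more than half the total
        copies reflect onto their complement; the central diagonal splits."""
        if self.folded:
            return self
        d1, d2 = self.sizes
        m = self.matrix
        out = np.zeros_like(m, dtype=float)
        half = (d1 + d2) / 2.0
        for i in range(d1 + 1):
            for j in range(d2 + 1):
                if i + j < half:
                    out[i, j] += m[i, j] + m[d1 - i, d2 - j]
                elif i + j == half:
                    out[i, j] += m[i, j] / 2 + m[d1 - i, d2 - j] / 2
        return JointSFS(self.pop_labels, self.sizes, out, True, self.n_dropped)

    def to_file(self, path) -> None:
        """dadi-style plain text: a header line "n1 n2 folded/unfolded" then
        the row-major flattened matrix on one line."""
        with open(path, "w") as fh:
            fh.write(f"{self.sizes[0] + 1} {self.sizes[1] + 1} "
                     f"{'folded' if self.folded else 'unfolded'} "
                     f"\"{self.pop_labels[0]}\" \"{self.pop_labels[1]}\"\n")
            fh.write(" ".join(f"{v:.10g}" for v in self.matrix.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointSFS":
        with open(path) as fh:
            head = fh.readline().split()
            n1, n2, fold = int(head[0]), int(head[1]), head[2] == "folded"
            labels = tuple(t.strip('"') for t in head[3:5]) if len(head) >= 5 else ("pop1", "pop2")
            vals = np.array(fh.readline().split(), dtype=float).reshape(n1, n2)
        return cls(labels, (n1 - 1, n2 - 1), vals, fold)


def projection_weights(n_obs: int, k_alt: int, d: int) -> np.ndarray:
    """Expected distribution of alt copies in a subsample of d from n_obs.

    Hypergeometric pmf over j = 0..d: C(k,j) C(n-k, d-j) / C(n, d).
    """
    j = np.arange(d + 1)
    return hypergeom.pmf(j, n_obs, k_alt, d)


def build_joint_sfs(codes1: np.ndarray, codes2: np.ndarray, project_to,
                    pop_labels=("pop1", "pop2"), folded: bool = False) -> JointSFS:
    """Joint SFS of two populations' 012 matrices with projection.

    ``project_to`` is ``(d1, d2)`` allele copies (an int applies to both).
    Each site contributes the outer product of its two hypergeometric
    projection weight vectors; sites with fewer observed copies than the
    projection size in either population are dropped and counted in
    ``n_dropped``.
    """
    if np.isscalar(project_to):
        project_to = (int(project_to), int(project_to))
    d1, d2 = project_to
    if d1 < 2 or d2 < 2:
        raise ValueError("project_to must be >= 2 copies per population")
    weights = []
    usable = None
    for codes, d in ((np.asarray(codes1), d1), (np.asarray(codes2), d2)):
        obs = codes != MISSING
        n = 2 * obs.sum(axis=1)
        alt = np.where(obs, codes, 0).sum(axis=1)
        ok = n >= d
        w = np.zeros((codes.shape[0], d + 1))
        # group sites by (n, alt): one pmf evaluation per distinct pair
        pairs = np.stack([n, alt], axis=1)
        for (n_o, k_a) in np.unique(pairs[ok], axis=0):
            sel = ok & (n == n_o) & (alt == k_a)
            w[sel] = projection_weights(int(n_o), int(k_a), d)
        weights.append(w)
        usable = ok if usable is None else (usable & ok)
    w1, w2 = weights[0][usable], weights[1][usable]
    matrix = w1.T @ w2
    out = JointSFS(tuple(pop_labels), (d1, d2), matrix,
                   n_dropped=int((~usable).sum()))
    return out.fold() if folded else out
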