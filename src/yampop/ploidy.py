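"""Ploidy inference from the allele-balance distribution at heterozygous sites.

For one accession, the alternate-allele read fraction at a heterozygous site
concentrates near dosage/ploidy: a diploid shows a single mode at 1/2, a
triploid two modes at 1/3 and 2/3, a tetraploid three modes at 1/4, 1/2 and
3/4. The method histograms the fractions over well-covered heterozygous
sites, fits an even-degree polynomial to the class heights by least squares
with no modality prior, and reads the ploidy off the number of interior local
maxima of the fitted curve: 1 -> 2x, 2 -> 3x, 3 -> 4x, anything else ->
unknown. A small exhaustive grid search tunes the depth threshold, class
count and degree on a labelled training panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .tables import ReadCountTable

PLOIDY_BY_N_MAXIMA = {1: 2, 2: 3, 3: 4}
EXPECTED_MODES = {2: (0.5,), 3: (1 / 3, 2 / 3), 4: (0.25, 0.5, 0.75)}


@dataclass
class PloidyParams:
    """Tunable knobs of the allele-balance method.

    ``min_site_depth`` defaults to the trained 30x per-accession-per-site
    threshold; ``n_classes`` to 250 of the three canvassed class counts.
    ``maxima_window`` excludes edge artefacts driven by sequencing error;
    maxima closer than ``merge_tolerance`` are merged into one mode.
    """

    min_site_depth: int = 30
    n_classes: int = 250
    poly_degree: int = 10
    maxima_window: tuple = (0.1, 0.9)
    merge_tolerance: float = 0.08
    min_rel_height: float = 0.15
    min_het_sites: int = 100

    def validate(self) -> None:
        if self.poly_degree < 4 or self.poly_degree % 2:
            raise ValueError("poly_degree must be even and >= 4")
        if not 0 <= self.maxima_window[0] < self.maxima_window[1] <= 1:
            raise ValueError("maxima_window must be an interval inside [0, 1]")


@dataclass
class HistogramFit:
    class_midpoints: np.ndarray
    class_heights: np.ndarray
    polynomial: Polynomial
    local_maxima: list
    residual: float

    @property
    def n_maxima(self) -> int:
        return len(self.local_maxima)


@dataclass
class PloidyCall:
    sample_id: str
    ploidy: int | str  # 2, 3, 4 or "unknown"
    n_maxima: int
    maxima: list = field(default_factory=list)
    n_het_sites_used: int = 0


def het_site_fractions(sample_id: str, table: ReadCountTable, params: PloidyParams) -> np.ndarray:
    """Alt-read fractions at the sample's heterozygous, well-covered sites.

    Only sites whose genotype call is heterozygous and whose depth for this
    sample reaches ``min_site_depth`` contribute; the fraction is
    ``alt_reads / (ref_reads + alt_reads)``.
    """
    j = table.sample_index(sample_id)
    depth = table.ref_reads[:, j] + table.alt_reads[:, j]
    use = (table.gt[:, j] == 1) & (depth >= params.min_site_depth)
    with np.errstate(invalid="ignore"):
        return table.alt_reads[use, j] / depth[use]


def _find_maxima(poly: Polynomial, window, merge_tol: float, min_rel_height: float) -> list:
    """Interior maxima of the polynomial: derivative roots with + -> - sign change.

    Maxima whose fitted height falls below ``min_rel_height`` times the
    tallest maximum are discarded: a high-degree polynomial fitted to the
    near-zero histogram tails develops low-amplitude ripples that would
    otherwise masquerade as modes.
    """
    deriv = poly.deriv()
    roots = deriv.roots()
    real = np.real(roots[np.abs(np.imag(roots)) < 1e-9])
    lo, hi = window
    cand = sorted(r for r in real if lo < r < hi)
    maxima = []
    eps = 1e-6
    for r in cand:
        if deriv(r - eps) > 0 and deriv(r + eps) < 0:
            maxima.append(float(r))
    if maxima:
        h_max = max(float(poly(r)) for r in maxima)
        if h_max > 0:  # histogram densities; inapplicable to non-positive curves
            maxima = [r for r in maxima if float(poly(r)) >= min_rel_height * h_max]
    # merge maxima closer than the tolerance (single broad mode split by noise)
    merged: list[list[float]] = []
    for r in maxima:
        if merged and r - merged[-1][-1] < merge_tol:
            merged[-1].append(r)
        else:
            merged.append([r])
    return [float(np.mean(group)) for group in merged]


def fit_distribution(fractions: np.ndarray, params: PloidyParams) -> HistogramFit:
    """Histogram the fractions on (0, 1) and fit the polynomial.

    The histogram uses ``n_classes`` equal-width classes; an even-degree
    polynomial is least-squares fitted through (midpoint, height) pairs with
    no prior on modality, and local maxima are located analytically from the
    derivative's real roots inside ``maxima_window``.
    """
    params.validate()
    fractions = np.asarray(fractions, dtype=float)
    edges = np.linspace(0.0, 1.0, params.n_classes + 1)
    heights, _ = np.histogram(fractions, bins=edges, density=True)
    mid = 0.5 * (edges[:-1] + edges[1:])
    try:
        poly = Polynomial.fit(mid, heights, deg=params.poly_degree)
    except np.linalg.LinAlgError:
        return HistogramFit(mid, heights, Polynomial([0.0]), [], float("inf"))
    residual = float(np.sqrt(np.mean((poly(mid) - heights) ** 2)))
    maxima = _find_maxima(poly, params.maxima_window, params.merge_tolerance,
                          params.min_rel_height)
    return HistogramFit(mid, heights, poly, maxima, residual)


def classify_ploidy(fit: HistogramFit, sample_id: str = "", n_sites: int = 0) -> PloidyCall:
    """Map the number of local maxima to a ploidy level.

    One maximum -> diploid, two -> triploid, three -> tetraploid; zero or
    more than three -> unknown.
    """
    ploidy = PLOIDY_BY_N_MAXIMA.get(fit.n_maxima, "unknown")
    return PloidyCall(sample_id, ploidy, fit.n_maxima, list(fit.local_maxima), n_sites)


def call_sample(sample_id: str, table: ReadCountTable, params: PloidyParams) -> PloidyCall:
    """Full per-sample pipeline: fractions -> fit -> call.

    Samples with fewer than ``min_het_sites`` usable fractions are flagged
    unknown without fitting (sparse histograms are unstable).
    """
    fr = het_site_fractions(sample_id, table, params)
    if len(fr) < params.min_het_sites:
        return PloidyCall(sample_id, "unknown", 0, [], len(fr))
    fit = fit_distribution(fr, params)
    return classify_ploidy(fit, sample_id, len(fr))


def infer_ploidy(table: ReadCountTable, params: PloidyParams | None = None) -> list:
    params = params or PloidyParams()
    return [call_sample(s, table, params) for s in table.samples]


def train_parameters(table: ReadCountTable, labels: dict, grid: dict | None = None):
    """Exhaustive grid search maximizing call accuracy on a labelled panel.

    ``labels`` maps sample id -> known ploidy; ``grid`` maps PloidyParams
    field names to candidate values (defaults: min_site_depth 8/30, the three
    class counts, degree 8). Accuracy counts unknown calls as wrong. Ties are
    broken toward the higher depth threshold, then fewer classes. Returns
    ``(best_params, best_accuracy, records)`` where records holds accuracy and
    a per-class confusion dict for each combination.
    """
    if len(set(labels.values())) < 2:
        raise ValueError("training set needs >= 2 distinct ploidy labels")
    grid = grid or {
        "min_site_depth": [8, 30],
        "n_classes": [100, 250, 500],
        "poly_degree": [8],
    }
    names = sorted(grid)
    combos = list(itertools.product(*(grid[n] for n in names)))
    if not combos:
        raise ValueError("empty parameter grid")
    records = []
    for combo in combos:
        params = PloidyParams(**dict(zip(names, combo)))
        confusion: dict = {}
        n_ok = 0
        for sample_id, truth in labels.items():
            call = call_sample(sample_id, table, params)
            confusion[(truth, call.ploidy)] = confusion.get((truth, call.ploidy), 0) + 1
            n_ok += call.ploidy == truth
        records.append({
            "params": params,
            "accuracy": n_ok / len(labels),
            "confusion": confusion,
        })
    best = max(
        records,
        key=lambda r: (r["accuracy"], r["params"].min_site_depth, -r["params"].n_classes),
    )
    return best["params"], best["accuracy"], records


def plot_fit(fit: HistogramFit, ax=None, title: str = ""):
    """Barplot of the allele-balance histogram with the fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(fit.class_midpoints, fit.class_heights,
           width=fit.class_midpoints[1] - fit.class_midpoints[0], alpha=0.5)
    xs = np.linspace(0, 1, 400)
    ax.plot(xs, fit.polynomial(xs), "r-")
    for m in fit.local_maxima:
        ax.axvline(m, color="k", ls="--", lw=0.8)
    ax.set_xlabel("alternate-allele read fraction")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    return ax
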