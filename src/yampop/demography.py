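"""Demographic scenario definition, composite-likelihood fitting and AIC ranking.

A scenario is a split-and-migration history over named gene pools: per-pool
diploid effective sizes, ordered divergence times TDIV1 < TDIV2 < ... at
which pools merge backwards in time (the deepest merger restores the
ancestral size N_ANC), and constant gene-flow rates between designated pool
pairs. The built-in templates cover the classic yam domestication-history
designs over four gene pools (MSEA = Mainland Southeast Asia, InP = Indian
Peninsula, Pac = Pacific, Afr = Africa): three-population topologies with or without InP-Pac gene
flow, then three Africa-origin models -- (A) Africa from the Indian
Peninsula, (B) Africa from the Pacific, (C) Africa from the Indian Peninsula
with Pacific-Africa gene flow.

Model fit uses the multinomial composite likelihood over joint-SFS entries:
logL = sum(obs * log p_hat) with expected proportions floored at a
pseudo-count, monomorphic corner entries excluded. Free parameters are
optimized on a log scale by multi-restart Nelder-Mead; every likelihood
evaluation simulates the expected spectrum with the same random seed (common
random numbers), so the objective is deterministic given the fit seed and
nested models cannot rank below their special cases by simulation noise
alone. Models are compared by AIC = 2k - 2 logL.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .coalescent import simulate_sfs
from .sfs import JointSFS

PSEUDOCOUNT = 1e-8  # floor for expected SFS entry proportions


@dataclass
class DemographicScenario:
    """Split-and-migration model over named populations.

    ``params`` holds sizes (``N_<pop>``, ``N_ANC``), divergence times
    (``TDIV1`` < ``TDIV2`` < ...) and gene-flow rates (``GF_<a>_<b>``).
    ``mergers`` lists (time_param, src, dst, size_param_or_None) backwards in
    time; ``migrations`` lists (rate_param, popA, popB) applied symmetrically
    while both pools exist. ``free`` names the parameters estimated from
    data; everything else stays fixed at its template value.
    """

    name: str
    pops: list
    params: dict
    mergers: list
    migrations: list = field(default_factory=list)
    free: list = field(default_factory=list)
    bounds: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.free)

    def with_params(self, **updates) -> "DemographicScenario":
        out = copy.deepcopy(self)
        out.params.update(updates)
        return out

    def validate(self) -> None:
        times = [self.params[t] for t, *_ in self.mergers]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.name}: divergence times out of order")
        if any(self.params[r] < 0 for r, *_ in self.migrations):
            raise ValueError(f"{self.name}: negative gene flow")

    def simulator_args(self):
        """Sizes, migration dict and merger list for :func:`simulate_sfs`."""
        self.validate()
        sizes = {p: self.params[f"N_{p}"] for p in self.pops}
        migration = {}
        for rate_param, a, b in self.migrations:
            m = self.params[rate_param]
            migration[(a, b)] = migration.get((a, b), 0) + m
            migration[(b, a)] = migration.get((b, a), 0) + m
        mergers = [
            (self.params[t], src, dst, self.params[size_p] if size_p else None)
            for t, src, dst, size_p in self.mergers
        ]
        return sizes, migration, mergers


def simulate_scenario_sfs(scenario: DemographicScenario, n_loci: int, samples: dict,
                          seed: int, pairs=None, sample_sites: bool = False):
    """Expected joint SFS(s) under a scenario; thin wrapper over the simulator."""
    sizes, migration, mergers = scenario.simulator_args()
    return simulate_sfs(samples, sizes, migration, mergers, n_loci, seed,
                        pairs=pairs, sample_sites=sample_sites)


def composite_loglik(obs, expected, pseudocount: float = PSEUDOCOUNT,
                     exclude_fixed: bool = True) -> float:
    """Multinomial composite log-likelihood of observed SFS entries.

    ``obs`` and ``expected`` are :class:`JointSFS` objects or dicts of them
    keyed by population pair (summed over pairs). Expected proportions are
    floored at ``pseudocount`` and renormalized; the monomorphic corners are
    excluded by default (SNP-only data carry no invariant-site information).
    """
    if isinstance(obs, dict):
        if set(obs) != set(expected):
            raise ValueError("observed and expected pair sets differ")
        return sum(composite_loglik(obs[k], expected[k], pseudocount, exclude_fixed)
                   for k in sorted(obs))
    if obs.matrix.shape != expected.matrix.shape:
        raise ValueError(f"SFS shape mismatch: {obs.matrix.shape} vs {expected.matrix.shape}")
    o = obs.matrix.copy()
    p = expected.proportions(exclude_fixed=exclude_fixed)
    if exclude_fixed:
        o[0, 0] = 0.0
        o[-1, -1] = 0.0
    p = np.maximum(p, pseudocount)
    p /= p.sum()
    return float(np.sum(o * np.log(p)))


def fit_scenario(obs, scenario: DemographicScenario, samples: dict, seed: int,
                 n_loci: int = 20_000, n_restarts: int = 10, maxiter: int = 60,
                 perturb: float = 0.5):
    """Maximize the composite likelihood over the scenario's free parameters.

    Free parameters are searched on a log scale with Nelder-Mead from the
    template values plus ``n_restarts - 1`` log-normally perturbed starts.
    Every objective evaluation simulates ``n_loci`` loci with the same seed
    (common random numbers), making the objective deterministic for a given
    fit seed. With no free parameters the scenario is evaluated once.
    Returns ``(best_scenario, best_logL, info)``.
    """
    pairs = sorted(obs) if isinstance(obs, dict) else None
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(2**31))

    def loglik_at(scn):
        joint, _ = simulate_scenario_sfs(scn, n_loci, samples, sim_seed, pairs=pairs)
        exp = joint if isinstance(obs, dict) else joint[list(joint)[0]]
        return composite_loglik(obs, exp)

    if not scenario.free:
        ll = loglik_at(scenario)
        return copy.deepcopy(scenario), ll, {"nfev": 1, "restarts": 0}

    x0 = np.log([scenario.params[name] for name in scenario.free])
    lo = np.log([scenario.bounds.get(n, (1e-8, np.inf))[0] for n in scenario.free])
    hi = np.log([np.minimum(scenario.bounds.get(n, (1e-8, 1e12))[1], 1e12)
                 for n in scenario.free])

    nfev = 0

    def objective(x):
        nonlocal nfev
        nfev += 1
        if np.any(x < lo) or np.any(x > hi):
            return 1e12
        scn = scenario.with_params(**dict(zip(scenario.free, np.exp(x))))
        try:
            return -loglik_at(scn)
        except ValueError:  # invalid ordering etc.
            return 1e12

    best_x, best_f = None, np.inf
    for r in range(max(n_restarts, 1)):
        start = x0 if r == 0 else x0 + rng.normal(0, perturb, size=len(x0))
        start = np.clip(start, lo, hi)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    best = scenario.with_params(**dict(zip(scenario.free, np.exp(best_x))))
    return best, -best_f, {"nfev": nfev, "restarts": max(n_restarts, 1),
                           "sim_seed": sim_seed}


@dataclass
class ModelComparison:
    table: pd.DataFrame  # model, logL, k, AIC, dAIC
    best_fits: dict  # model name -> fitted DemographicScenario

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])


def aic(loglik: float, k: int) -> float:
    return 2 * k - 2 * loglik


def compare_models(obs, scenarios, samples: dict, seed: int,
                   fit_kwargs: dict | None = None,
                   final_n_loci: int | None = None) -> ModelComparison:
    """Fit each scenario and rank by AIC.

    All models are fitted to the same observed spectra; final log-likelihoods
    are re-evaluated at the best-fit parameters with a common seed and
    ``final_n_loci`` loci (defaults to the fit's ``n_loci``) so the ranking
    compares models, not simulation budgets.
    """
    if not scenarios:
        raise ValueError("no scenarios to compare")
    fit_kwargs = dict(fit_kwargs or {})
    final_n = final_n_loci or fit_kwargs.get("n_loci", 20_000)
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(2**31, size=len(scenarios))
    final_seed = int(rng.integers(2**31))
    pairs = sorted(obs) if isinstance(obs, dict) else None

    rows, fits = [], {}
    for scn, fseed in zip(scenarios, fit_seeds):
        best, _, _ = fit_scenario(obs, scn, samples, int(fseed), **fit_kwargs)
        joint, _ = simulate_scenario_sfs(best, final_n, samples, final_seed, pairs=pairs)
        exp = joint if isinstance(obs, dict) else joint[list(joint)[0]]
        ll = composite_loglik(obs, exp)
        fits[scn.name] = best
        rows.append({"model": scn.name, "logL": ll, "k": scn.k, "AIC": aic(ll, scn.k)})
    table = pd.DataFrame(rows).sort_values("AIC", ignore_index=True)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    return ModelComparison(table, fits)


# ---------------------------------------------------------------------------
# Built-in scenario templates (desk-scale parameter defaults)

POPS3 = ("MSEA", "InP", "Pac")
POPS4 = ("MSEA", "InP", "Pac", "Afr")

# Desk-scale defaults. The InP-Pac gene-flow rate is the conventional
# 0.005 per lineage per generation; sizes and divergence times are chosen
# once for an identifiable desk-scale design: with constant gene flow m,
# pools homogenize on the 1/m timescale, so divergence times sit well inside
# 1/m = 200 generations of each other while still spanning enough drift
# (TDIV/2N up to 0.5) to shape the joint spectra.
_DEFAULTS = {
    "N_MSEA": 500.0, "N_InP": 500.0, "N_Pac": 500.0, "N_Afr": 500.0,
    "N_ANC": 500.0,
    "TDIV1": 80.0, "TDIV2": 200.0, "TDIV3": 500.0,
    "GF_InP_Pac": 0.005, "GF_Pac_Afr": 0.005,
}

_BOUNDS = {
    "N_MSEA": (50, 5e4), "N_InP": (50, 5e4), "N_Pac": (50, 5e4),
    "N_Afr": (50, 5e4), "N_ANC": (50, 5e4),
    "TDIV1": (10, 5e4), "TDIV2": (10, 5e4), "TDIV3": (10, 5e4),
    "GF_InP_Pac": (1e-6, 0.2), "GF_Pac_Afr": (1e-6, 0.2),
}


def _params(pops, extra=()):
    keys = [f"N_{p}" for p in pops] + ["N_ANC"] + list(extra)
    return {k: _DEFAULTS[k] for k in keys}


def three_pop_topology(split_first: str, migration: bool = False,
                       free=("TDIV1", "TDIV2")) -> DemographicScenario:
    """Three-pool scenario: ``split_first`` diverges deepest (at TDIV2).

    The two remaining pools split at TDIV1. Optional constant InP-Pac gene
    flow. Used to pick the best topology before adding Africa.
    """
    others = [p for p in POPS3 if p != split_first]
    mergers = [
        ("TDIV1", others[1], others[0], None),
        ("TDIV2", split_first, others[0], "N_ANC"),
    ]
    migs = [("GF_InP_Pac", "InP", "Pac")] if migration else []
    name = f"3pop_{split_first}_first" + ("_mig" if migration else "")
    params = _params(POPS3, ["TDIV1", "TDIV2"] + (["GF_InP_Pac"] if migration else []))
    return DemographicScenario(name, list(POPS3), params, mergers, migs,
                               free=list(free), bounds=dict(_BOUNDS))


def three_pop_model_set(migration: bool = False) -> list:
    """The three topologies over MSEA/InP/Pac, optionally with InP-Pac flow.

    Used as the first comparison round: pick the supported topology before
    adding the African pool.
    """
    return [three_pop_topology(p, migration=migration) for p in POPS3]


def _africa_base(name, afr_source, gene_flow_pac_afr, free):
    extra = ["TDIV1", "TDIV2", "TDIV3", "GF_InP_Pac"]
    migs = [("GF_InP_Pac", "InP", "Pac")]
    if gene_flow_pac_afr:
        extra.append("GF_Pac_Afr")
        migs.append(("GF_Pac_Afr", "Pac", "Afr"))
    mergers = [
        ("TDIV1", "Afr", afr_source, None),
        ("TDIV2", "InP", "MSEA", None),
        ("TDIV3", "Pac", "MSEA", "N_ANC"),
    ]
    return DemographicScenario(name, list(POPS4), _params(POPS4, extra), mergers,
                               migs, free=list(free), bounds=dict(_BOUNDS))


def africa_from_inp(free=("N_Afr", "TDIV1")) -> DemographicScenario:
    """Model A: the African pool splits from the Indian Peninsula at TDIV1."""
    return _africa_base("A_africa_from_InP", "InP", False, free)


def africa_from_pacific(free=("N_Afr", "TDIV1")) -> DemographicScenario:
    """Model B: the African pool splits from the Pacific at TDIV1."""
    return _africa_base("B_africa_from_Pac", "Pac", False, free)


def africa_from_inp_with_geneflow(free=("N_Afr", "TDIV1", "GF_Pac_Afr")) -> DemographicScenario:
    """Model C: Africa from the Indian Peninsula plus Pacific-Africa gene flow."""
    return _africa_base("C_africa_from_InP_gf", "InP", True, free)


def africa_model_set() -> list:
    """The three Africa-origin templates (the second comparison round)."""
    return [africa_from_inp(), africa_from_pacific(), africa_from_inp_with_geneflow()]
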