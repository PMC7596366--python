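"""Backward-time structured coalescent with migration and population mergers.

Simulates gene genealogies for samples spread over several populations:
within population k, each lineage pair coalesces at rate 1/(2 N_k) per
generation; a lineage in k traces its ancestry to population l at backward
rate m[k, l] per generation; at each merger event (a population split viewed
backwards) all lineages of the source population move to the destination,
whose size may change (this is how an ancestral size takes effect).

Sites follow the infinite-sites model: a mutation falls uniformly on the
genealogy, so a branch carries a site with probability proportional to its
length. Each branch adds its raw length to the spectrum entry indexed by its
per-population descendant counts, and the accumulated spectrum is normalized
to ``n_loci`` sites, giving the low-mutation-rate expectation
E[length_i]/E[length_total] (the classical 1/i law for a single panmictic
population). ``sample_sites=True`` additionally draws integer site counts
from that expectation, producing data-like spectra.

The event loop is JIT-compiled with numba; the first call in a session pays
a one-off compilation cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .sfs import JointSFS


@njit(cache=True)
def _simulate_loci(samples, sizes0, mig0, ev_time, ev_src, ev_dst, ev_newsize,
                   n_loci, seed, pair_a, pair_b,
                   out_pairs, out_marg):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_pops = samples.shape[0]
    n_tot = int(samples.sum())
    n_ev = ev_time.shape[0]
    n_pairs = pair_a.shape[0]

    lin_pop = np.empty(n_tot, dtype=np.int64)
    lin_cnt = np.empty((n_tot, n_pops), dtype=np.int64)
    lin_len = np.empty(n_tot, dtype=np.float64)
    br_cnt = np.empty((2 * n_tot, n_pops), dtype=np.int64)
    br_len = np.empty(2 * n_tot, dtype=np.float64)
    pop_n = np.empty(n_pops, dtype=np.int64)

    for locus in range(n_loci):
        sizes = sizes0.copy()
        mig = mig0.copy()
        idx = 0
        for k in range(n_pops):
            pop_n[k] = samples[k]
            for _ in range(samples[k]):
                lin_pop[idx] = k
                for kk in range(n_pops):
                    lin_cnt[idx, kk] = 0
                lin_cnt[idx, k] = 1
                lin_len[idx] = 0.0
                idx += 1
        n_act = n_tot
        n_br = 0
        t = 0.0
        ev_i = 0

        while n_act > 1:
            coal = 0.0
            for k in range(n_pops):
                if pop_n[k] > 1:
                    coal += pop_n[k] * (pop_n[k] - 1) / (4.0 * sizes[k])
            mig_tot = 0.0
            for k in range(n_pops):
                if pop_n[k] > 0:
                    row = 0.0
                    for l in range(n_pops):
                        row += mig[k, l]
                    mig_tot += pop_n[k] * row
            rate = coal + mig_tot

            if rate <= 0.0:
                if ev_i >= n_ev:
                    # unreachable for valid scenarios (validated in wrapper)
                    break
                dt = ev_time[ev_i] - t + 1.0
            else:
                dt = -np.log(np.random.random()) / rate

            if ev_i < n_ev and t + dt >= ev_time[ev_i]:
                # advance to the merger, move src lineages into dst
                step = ev_time[ev_i] - t
                for i in range(n_act):
                    lin_len[i] += step
                t = ev_time[ev_i]
                src = ev_src[ev_i]
                dst = ev_dst[ev_i]
                for i in range(n_act):
                    if lin_pop[i] == src:
                        lin_pop[i] = dst
                pop_n[dst] += pop_n[src]
                pop_n[src] = 0
                if ev_newsize[ev_i] > 0:
                    sizes[dst] = ev_newsize[ev_i]
                for l in range(n_pops):
                    mig[src, l] = 0.0
                    mig[l, src] = 0.0
                ev_i += 1
                continue

            for i in range(n_act):
                lin_len[i] += dt
            t += dt

            u = np.random.random() * rate
            if u < coal:
                # coalescence: find the population
                acc = 0.0
                k_ev = -1
                for k in range(n_pops):
                    if pop_n[k] > 1:
                        acc += pop_n[k] * (pop_n[k] - 1) / (4.0 * sizes[k])
                        if u < acc:
                            k_ev = k
                            break
                # pick two distinct lineages in pop k_ev
                a = int(np.random.random() * pop_n[k_ev])
                b = int(np.random.random() * (pop_n[k_ev] - 1))
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(n_act):
                    if lin_pop[i] == k_ev:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
                # record both children as finished branches
                for child in (ia, ib):
                    for kk in range(n_pops):
                        br_cnt[n_br, kk] = lin_cnt[child, kk]
                    br_len[n_br] = lin_len[child]
                    n_br += 1
                # ia becomes the parent; remove ib by swapping with the tail
                for kk in range(n_pops):
                    lin_cnt[ia, kk] += lin_cnt[ib, kk]
                lin_len[ia] = 0.0
                last = n_act - 1
                lin_pop[ib] = lin_pop[last]
                lin_len[ib] = lin_len[last]
                for kk in range(n_pops):
                    lin_cnt[ib, kk] = lin_cnt[last, kk]
                n_act -= 1
                pop_n[k_ev] -= 1
            else:
                # migration: lineage in k traces back to l
                u2 = u - coal
                acc = 0.0
                k_ev = 0
                l_ev = 0
                done = False
                for k in range(n_pops):
                    if pop_n[k] == 0:
                        continue
                    for l in range(n_pops):
                        acc += pop_n[k] * mig[k, l]
                        if u2 < acc:
                            k_ev = k
                            l_ev = l
                            done = True
                            break
                    if done:
                        break
                a = int(np.random.random() * pop_n[k_ev])
                seen = 0
                for i in range(n_act):
                    if lin_pop[i] == k_ev:
                        if seen == a:
                            lin_pop[i] = l_ev
                            break
                        seen += 1
                pop_n[k_ev] -= 1
                pop_n[l_ev] += 1

        # accumulate raw branch lengths; mutations fall on a branch with
        # probability proportional to length, so E[SFS] tracks E[length]
        for b_i in range(n_br):
            w = br_len[b_i]
            for pi in range(n_pairs):
                out_pairs[pi, br_cnt[b_i, pair_a[pi]], br_cnt[b_i, pair_b[pi]]] += w
            for k in range(n_pops):
                out_marg[k, br_cnt[b_i, k]] += w


def simulate_sfs(samples: dict, sizes: dict, migration: dict, mergers: list,
                 n_loci: int, seed: int, pairs=None, sample_sites: bool = False):
    """Run the simulator and return joint SFSs and 1-D marginals.

    Parameters
    ----------
    samples : dict pop -> sampled allele copies (haploid lineages)
    sizes : dict pop -> diploid effective size
    migration : dict (pop_from, pop_to) -> backward per-generation rate
        (entered for each direction; symmetric gene flow needs both keys)
    mergers : list of (time, src_pop, dst_pop, new_dst_size or None),
        times in generations, strictly increasing
    pairs : population pairs for joint SFSs; defaults to all sampled pairs
    sample_sites : draw integer site counts (one multinomial draw of
        ``n_loci`` sites from the expected spectrum) instead of returning
        the expectation itself

    Returns ``(joint, marginals)`` where ``joint`` maps a pop pair to a
    :class:`JointSFS` whose mass sums to the number of contributing loci and
    ``marginals`` maps each pop to its 1-D spectrum (monomorphic entries
    included at the margins).
    """
    pops = list(samples)
    if any(samples[p] < 0 for p in pops):
        raise ValueError("negative sample size")
    if sum(samples[p] for p in pops) < 2:
        raise ValueError("need at least two sampled lineages")
    pop_i = {p: i for i, p in enumerate(pops)}
    times = [m[0] for m in mergers]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("merger times must be strictly increasing")
    # every sampled pop except one must eventually merge away
    alive = set(pops)
    for _, src, dst, _ in mergers:
        if src in alive:
            alive.discard(src)
    if len(alive) > 1 and not any(migration.get((a, b), 0) > 0
                                  for a in alive for b in alive if a != b):
        raise ValueError("scenario leaves disconnected populations with no migration")

    n_pops = len(pops)
    samples_arr = np.array([samples[p] for p in pops], dtype=np.int64)
    sizes_arr = np.array([float(sizes[p]) for p in pops])
    if (sizes_arr <= 0).any():
        raise ValueError("population sizes must be positive")
    mig_arr = np.zeros((n_pops, n_pops))
    for (a, b), m in migration.items():
        if m < 0:
            raise ValueError("migration rates must be >= 0")
        mig_arr[pop_i[a], pop_i[b]] = m
    ev_time = np.array([float(m[0]) for m in mergers])
    ev_src = np.array([pop_i[m[1]] for m in mergers], dtype=np.int64)
    ev_dst = np.array([pop_i[m[2]] for m in mergers], dtype=np.int64)
    ev_newsize = np.array([float(m[3]) if m[3] else -1.0 for m in mergers])

    if pairs is None:
        sampled = [p for p in pops if samples[p] > 0]
        pairs = [(a, b) for i, a in enumerate(sampled) for b in sampled[i + 1:]]
    pair_a = np.array([pop_i[a] for a, _ in pairs], dtype=np.int64)
    pair_b = np.array([pop_i[b] for _, b in pairs], dtype=np.int64)

    d_max = int(samples_arr.max())
    out_pairs = np.zeros((max(len(pairs), 1), d_max + 1, d_max + 1))
    out_marg = np.zeros((n_pops, d_max + 1))
    _simulate_loci(samples_arr, sizes_arr, mig_arr, ev_time, ev_src, ev_dst,
                   ev_newsize, int(n_loci), int(seed) % (2**31), pair_a, pair_b,
                   out_pairs, out_marg)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7]))
    joint = {}
    for pi, (a, b) in enumerate(pairs):
        da, db = samples[a], samples[b]
        m = out_pairs[pi, :da + 1, :db + 1].copy()
        m *= n_loci / m.sum()
        if sample_sites:
            m = rng.multinomial(n_loci, (m / m.sum()).ravel()).reshape(m.shape).astype(float)
        joint[(a, b)] = JointSFS((a, b), (da, db), m)
    marginals = {}
    for p in pops:
        if samples[p] == 0:
            continue
        m = out_marg[pop_i[p], :samples[p] + 1].copy()
        m *= n_loci / m.sum()
        if sample_sites:
            m = rng.multinomial(n_loci, m / m.sum()).astype(float)
        marginals[p] = m
    return joint, marginals
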