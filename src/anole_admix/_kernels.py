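"""Numba kernels for the structured coalescent and microsatellite mutation.

Backward-time three-population coalescent with a single admixture pulse:
lineages sampled in SFL (code 0), MIA (1) and WCU (2) coalesce within
their populations; at the admixture time every MIA lineage jumps to WCU
with probability ``r_admix`` (else SFL); at the split time SFL and WCU
merge into an ancestral population.  Times are continuous, in generations.

The kernels use numba's per-thread legacy RNG, seeded explicitly at the
top of each call, so a (seed, arguments) pair fully determines the output.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def coalesce_kernel(pop0, copies, t_admix, r_admix, t_split, anc_copies, seed):
    """Simulate one genealogy; return (parent, node_time, origin).

    pop0      : int64[n] population code per sampled gene copy (0/1/2)
    copies    : float64[3] gene-copy numbers per population (2N autosomal,
                N/2 maternal haploid)
    anc_copies: gene-copy number of the ancestral population
    origin    : int64[2n-1]; for lineages alive at the admixture pulse, the
                population they occupy immediately after the jump (backward
                in time), -1 elsewhere
    parent of the root is -1; node ids increase with coalescence time.
    """
    np.random.seed(seed)
    n = pop0.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    ntime = np.zeros(n_nodes)
    origin = np.full(n_nodes, -1, np.int64)
    pop = np.full(n_nodes, -1, np.int64)
    pop[:n] = pop0
    active = np.empty(n_nodes, np.int64)
    for i in range(n):
        active[i] = i
    nact = n
    k = np.zeros(3, np.int64)  # lineages per population
    for i in range(n):
        k[pop0[i]] += 1
    t = 0.0
    phase = 0  # 0: before admixture, 1: before split, 2: ancestral
    node_id = n
    while nact > 1:
        if phase == 2:
            rate = nact * (nact - 1) / (2.0 * anc_copies)
        else:
            rate = 0.0
            for p in range(3):
                rate += k[p] * (k[p] - 1) / (2.0 * copies[p])
        if rate > 0.0:
            t_event = t + np.random.exponential(1.0 / rate)
        else:
            t_event = np.inf
        if phase == 0 and t_event >= t_admix:
            t = t_admix
            for i in range(nact):
                v = active[i]
                if pop[v] == 1:
                    if np.random.random() < r_admix:
                        pop[v] = 2
                    else:
                        pop[v] = 0
                    k[1] -= 1
                    k[pop[v]] += 1
                    origin[v] = pop[v]
            phase = 1
            continue
        if phase == 1 and t_event >= t_split:
            t = t_split
            phase = 2
            continue
        t = t_event
        # population in which the coalescence happens
        if phase == 2:
            psel = -1
            m = nact
        else:
            u = np.random.random() * rate
            acc = 0.0
            psel = 0
            for p in range(3):
                acc += k[p] * (k[p] - 1) / (2.0 * copies[p])
                if u < acc:
                    psel = p
                    break
            m = k[psel]
        # gather eligible lineage positions
        idxs = np.empty(m, np.int64)
        c = 0
        for i in range(nact):
            if psel == -1 or pop[active[i]] == psel:
                idxs[c] = i
                c += 1
        i1 = idxs[np.random.randint(m)]
        i2 = idxs[np.random.randint(m)]
        while i2 == i1:
            i2 = idxs[np.random.randint(m)]
        a = active[i1]
        b = active[i2]
        parent[a] = node_id
        parent[b] = node_id
        ntime[node_id] = t
        pop[node_id] = pop[a]
        if psel != -1:
            k[psel] -= 1
        lo = min(i1, i2)
        hi = max(i1, i2)
        active[hi] = active[nact - 1]
        active[lo] = node_id
        nact -= 1
        node_id += 1
    return parent, ntime, origin


@njit(cache=True)
def mutate_kernel(parent, ntime, n_tips, mu, gsm_p, root_state, seed):
    """Drop stepwise mutations down a genealogy; return tip allele states.

    Mutations are Poisson with rate ``mu`` per generation on each branch.
    Each mutation is +/-1 repeat unit with probability ``gsm_p``, otherwise
    a geometric multi-step jump with mean two steps; the sign is fair.
    """
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    state = np.empty(n_nodes, np.int64)
    state[n_nodes - 1] = root_state
    # parents always have larger ids, so a reverse sweep visits them first
    for v in range(n_nodes - 2, -1, -1):
        branch = ntime[parent[v]] - (ntime[v] if v >= n_tips else 0.0)
        s = state[parent[v]]
        n_mut = np.random.poisson(mu * branch)
        for _ in range(n_mut):
            if np.random.random() < gsm_p:
                step = 1
            else:
                step = np.random.geometric(0.5)  # geometric tail, mean 2
            if np.random.random() < 0.5:
                step = -step
            s += step
        state[v] = s
    return state[:n_tips]


@njit(cache=True)
def origin_at_admixture(parent, ntime, origin, n_tips, t_admix):
    """Propagate the post-pulse population codes down to the tips.

    For each tip, finds its ancestral lineage alive at the admixture time
    and returns that lineage's ``origin`` code (-1 for tips whose lineage
    was not in the admixed population).
    """
    out = np.full(n_tips, -1, np.int64)
    for tip in range(n_tips):
        v = tip
        while parent[v] != -1 and ntime[parent[v]] <= t_admix:
            v = parent[v]
        out[tip] = origin[v]
    return out
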