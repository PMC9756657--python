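"""Per-site structured-coalescent engine behind the genotype simulator.

Five populations sit on the fixed species tree
((((focal,niloticus),aureus),mossambicus),urolepis) with speciation times
TAU = (1, 2, 3, 4) in coalescent units. Each site gets an independent
genealogy: lineages coalesce within their current population, populations
merge at the speciation times, and at sites inside an introgressed block the
focal lineages are moved into the mossambicus population at a recent time
``t_adm``. One derived mutation is then placed on a branch chosen with
probability proportional to its length.

Incomplete lineage sorting is controlled through the coalescence rate in
ancestral populations: the probability that two lineages entering an
ancestor of unit duration fail to coalesce there is exp(-rate), and a failed
focal/niloticus coalescence resolves discordantly 2/3 of the time, so
``rate = -ln(1.5 * ils_rate)`` makes the discordance probability of the
shallowest split approximately ``ils_rate``.

Sites are independent; there is no recombination machinery here.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# population indices
FOCAL, NILOTICUS, AUREUS, MOSSAMBICUS, UROLEPIS = 0, 1, 2, 3, 4
TAU = (1.0, 2.0, 3.0, 4.0)
T_ADM = 0.05  # admixture time (coalescent units); recent relative to TAU

# per-site genealogy labels recorded in the truth set
LABEL_CONCORDANT = 0
LABEL_DISCORDANT = 1
LABEL_ADMIXED = 2


def ils_to_rate(ils_rate: float) -> float:
    """Map a target focal/niloticus discordance probability to a coalescence
    rate for ancestral populations (clamped to [1e-3, 1e6])."""
    if ils_rate <= 0.0:
        return 1.0e6
    return float(min(1.0e6, max(1.0e-3, -math.log(min(0.999, 1.5 * ils_rate)))))


@njit(cache=False)
def _simulate_patterns(
    n_sites: int,
    admixed: np.ndarray,  # bool per site
    n_dip: int,
    rate_extant: float,
    rate_anc: float,
    t_adm: float,
    seed: int,
):
    """Returns (derived[n_sites, 10*n_dip] int8, labels[n_sites] int8)."""
    np.random.seed(seed)
    lpp = 2 * n_dip  # lineages per population
    L = 5 * lpp
    n_nodes = 2 * L - 1
    derived = np.zeros((n_sites, L), dtype=np.int8)
    labels = np.zeros(n_sites, dtype=np.int8)
    tau = np.array([1.0, 2.0, 3.0, 4.0])

    parent = np.empty(n_nodes, dtype=np.int32)
    ntime = np.empty(n_nodes, dtype=np.float64)
    npop = np.empty(n_nodes, dtype=np.int32)
    active = np.empty(L, dtype=np.int32)
    rates = np.empty(5, dtype=np.float64)
    kpop = np.empty(5, dtype=np.int64)
    members = np.empty(L, dtype=np.int32)
    blen = np.empty(n_nodes, dtype=np.float64)
    cnt_fn = np.empty(n_nodes, dtype=np.int64)
    cnt_all = np.empty(n_nodes, dtype=np.int64)

    for s in range(n_sites):
        # init leaves
        for i in range(L):
            parent[i] = -1
            ntime[i] = 0.0
            npop[i] = i // lpp
            active[i] = i
        n_active = L
        next_node = L
        for p in range(5):
            rates[p] = rate_extant
        t = 0.0
        # boundary schedule: t_adm (admixed relocation), then speciation times
        bidx = 0  # 0: t_adm, 1..4: tau[0..3], 5: none
        is_adm = admixed[s]
        while n_active > 1:
            # next boundary time
            if bidx == 0:
                tb = t_adm
            elif bidx <= 4:
                tb = tau[bidx - 1]
            else:
                tb = 1.0e30
            # population lineage counts
            for p in range(5):
                kpop[p] = 0
            for a in range(n_active):
                kpop[npop[active[a]]] += 1
            total = 0.0
            for p in range(5):
                total += rates[p] * kpop[p] * (kpop[p] - 1) / 2.0
            if total > 0.0:
                dt = -math.log(np.random.random()) / total
            else:
                dt = 1.0e30
            if t + dt >= tb:
                # advance to boundary and apply relabels
                t = tb
                if bidx == 0:
                    if is_adm:
                        for a in range(n_active):
                            if npop[active[a]] == FOCAL:
                                npop[active[a]] = MOSSAMBICUS
                elif bidx == 1:
                    for a in range(n_active):
                        if npop[active[a]] == NILOTICUS:
                            npop[active[a]] = FOCAL
                    rates[FOCAL] = rate_anc
                elif bidx == 2:
                    for a in range(n_active):
                        if npop[active[a]] == AUREUS:
                            npop[active[a]] = FOCAL
                elif bidx == 3:
                    for a in range(n_active):
                        if npop[active[a]] == MOSSAMBICUS:
                            npop[active[a]] = FOCAL
                elif bidx == 4:
                    for a in range(n_active):
                        if npop[active[a]] == UROLEPIS:
                            npop[active[a]] = FOCAL
                bidx += 1
                continue
            # coalescence event at t + dt
            t += dt
            u = np.random.random() * total
            acc = 0.0
            cpop = 4
            for p in range(5):
                acc += rates[p] * kpop[p] * (kpop[p] - 1) / 2.0
                if u < acc:
                    cpop = p
                    break
            k = 0
            for a in range(n_active):
                if npop[active[a]] == cpop:
                    members[k] = a
                    k += 1
            i = np.random.randint(0, k)
            j = np.random.randint(0, k - 1)
            if j >= i:
                j += 1
            ai, aj = members[i], members[j]
            na, nb = active[ai], active[aj]
            parent[na] = next_node
            parent[nb] = next_node
            parent[next_node] = -1
            ntime[next_node] = t
            npop[next_node] = cpop
            # replace the two with the new node
            active[ai] = next_node
            active[aj] = active[n_active - 1]
            n_active -= 1
            next_node += 1
        root = active[0]
        # branch lengths
        total_len = 0.0
        for i in range(next_node):
            if parent[i] >= 0:
                blen[i] = ntime[parent[i]] - ntime[i]
                total_len += blen[i]
            else:
                blen[i] = 0.0
        # mutation placement proportional to branch length
        u = np.random.random() * total_len
        acc = 0.0
        mut = root
        for i in range(next_node):
            if parent[i] >= 0:
                acc += blen[i]
                if u < acc:
                    mut = i
                    break
        # derived = leaves descending from (and including) the mutated branch
        for leaf in range(L):
            node = leaf
            hit = 0
            while node >= 0:
                if node == mut:
                    hit = 1
                    break
                node = parent[node]
            derived[s, leaf] = hit
        # genealogy label: does focal+niloticus form a clade?
        if is_adm:
            labels[s] = LABEL_ADMIXED
        else:
            n_fn = 2 * lpp
            for i in range(next_node):
                cnt_fn[i] = 0
                cnt_all[i] = 0
            for leaf in range(L):
                cnt_all[leaf] = 1
                if leaf < n_fn:
                    cnt_fn[leaf] = 1
            for i in range(next_node):
                if parent[i] >= 0:
                    cnt_fn[parent[i]] += cnt_fn[i]
                    cnt_all[parent[i]] += cnt_all[i]
            lab = LABEL_DISCORDANT
            for i in range(next_node):
                if cnt_fn[i] == n_fn:
                    if cnt_all[i] == n_fn:
                        lab = LABEL_CONCORDANT
                    break
            labels[s] = lab
    return derived, labels


def simulate_site_patterns(
    n_sites: int,
    admixed: np.ndarray,
    n_dip_per_pop: int = 2,
    ils_rate: float = 0.1,
    rate_extant: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Derived/ancestral patterns per lineage for ``n_sites`` genealogies.

    Lineage layout: populations in order (focal, niloticus, aureus,
    mossambicus, urolepis), ``2 * n_dip_per_pop`` lineages each; consecutive
    lineage pairs form diploid individuals.
    """
    admixed = np.ascontiguousarray(np.asarray(admixed, dtype=np.bool_))
    if admixed.shape[0] != n_sites:
        raise ValueError("admixed mask length must equal n_sites")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return _simulate_patterns(
        n_sites,
        admixed,
        n_dip_per_pop,
        float(rate_extant),
        ils_to_rate(ils_rate),
        T_ADM,
        int(seed) % (2**31),
    )
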