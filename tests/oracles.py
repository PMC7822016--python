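"""Independent brute-force oracles used by the test suite.

Everything here works directly on the raw state-by-state TPM with explicit
loops over all joint states -- no shared code with the package's
marginalization, caching or composition machinery.
"""

import itertools
import math

import numpy as np


def all_states(radices):
    return [
        tuple(reversed(rev))
        for rev in itertools.product(*[range(r) for r in reversed(radices)])
    ]


def encode(state, radices):
    idx, stride = 0, 1
    for v, r in zip(state, radices):
        idx += v * stride
        stride *= r
    return idx


def effect_repertoire_oracle(tpm, radices, mech, mstate, purview):
    """Product over purview nodes of their next-state marginals, computed
    by filtering and averaging raw TPM rows."""
    states = all_states(radices)
    rows = [
        h
        for h, hs in enumerate(states)
        if all(hs[i] == v for i, v in zip(mech, mstate))
    ]
    per_node = []
    for z in purview:
        acc = np.zeros(radices[z])
        for h in rows:
            for s, ss in enumerate(states):
                acc[ss[z]] += tpm[h, s]
        per_node.append(acc / len(rows))
    purv_radices = [radices[z] for z in purview]
    out = np.zeros(int(np.prod(purv_radices)) if purview else 1)
    if not purview:
        return np.ones(1)
    for k, zs in enumerate(all_states(purv_radices)):
        val = 1.0
        for j, z in enumerate(purview):
            val *= per_node[j][zs[j]]
        out[k] = val
    return out


def cause_repertoire_oracle(tpm, radices, mech, mstate, purview):
    """Per-mechanism-node likelihoods over prior purview states (uniform
    prior), multiplied and normalized.  Returns None for a null cause."""
    states = all_states(radices)
    purv_radices = [radices[z] for z in purview]
    size = int(np.prod(purv_radices)) if purview else 1
    if not purview:
        return np.ones(1)
    if not mech:
        return np.full(size, 1.0 / size)
    prod = np.ones(size)
    for i, v in zip(mech, mstate):
        li = np.zeros(size)
        for h, hs in enumerate(states):
            pz = tuple(hs[z] for z in purview)
            lik = 0.0
            for s, ss in enumerate(states):
                if ss[i] == v:
                    lik += tpm[h, s]
            li[encode(pz, purv_radices)] += lik
        prod *= li
    total = prod.sum()
    if total <= 0:
        return None
    return prod / total


def aid_oracle(p, q):
    best, arg = 0.0, 0
    for s in range(len(p)):
        if p[s] > 0:
            term = math.inf if q[s] <= 0 else p[s] * abs(math.log2(p[s] / q[s]))
            if term > best:
                best, arg = term, s
    return best, arg


def tripartitions_oracle(mech, purview):
    """Generate-and-canonicalize enumeration of tripartitions: canonical
    form is the frozenset of (frozenset, frozenset) parts."""
    nodes = [("m", i) for i in mech] + [("z", z) for z in purview]
    seen = set()
    for assign in itertools.product(range(3), repeat=len(nodes)):
        parts = []
        for slot in range(3):
            pm = frozenset(i for (kind, i), a in zip(nodes, assign) if a == slot and kind == "m")
            pz = frozenset(z for (kind, z), a in zip(nodes, assign) if a == slot and kind == "z")
            if pm or pz:
                parts.append((pm, pz))
        canon = frozenset(parts)
        if len(parts) == 1 and parts[0] == (frozenset(mech), frozenset(purview)):
            continue
        seen.add(canon)
    return seen


def phi_oracle(tpm, radices, mech, mstate, purview, direction):
    """Minimum AID over tripartitions, everything recomputed from raw rows."""
    rep = (
        cause_repertoire_oracle
        if direction == "cause"
        else effect_repertoire_oracle
    )
    p = rep(tpm, radices, mech, mstate, purview)
    if p is None:
        return 0.0
    state_of = dict(zip(mech, mstate))
    purv_radices = [radices[z] for z in purview]
    best = math.inf
    for partition in tripartitions_oracle(mech, purview):
        q = np.zeros(len(p))
        for k, zs in enumerate(all_states(purv_radices)):
            val = 1.0
            for pm, pz in partition:
                if not pz:
                    continue
                pz_sorted = sorted(pz)
                pm_sorted = sorted(pm)
                r = rep(
                    tpm,
                    radices,
                    pm_sorted,
                    [state_of[i] for i in pm_sorted],
                    pz_sorted,
                )
                if r is None:
                    val = 0.0
                    break
                sub = tuple(zs[purview.index(z)] for z in pz_sorted)
                val *= r[encode(sub, [radices[z] for z in pz_sorted])]
            q[k] = val
        phi, _ = aid_oracle(p, q)
        best = min(best, phi)
    return best


def mechanism_phi_oracle(tpm, radices, mech, mstate):
    """min over directions of the max-over-purviews phi."""
    n = len(radices)
    out = {}
    for direction in ("cause", "effect"):
        best = 0.0
        for size in range(1, n + 1):
            for purview in itertools.combinations(range(n), size):
                best = max(
                    best,
                    phi_oracle(tpm, radices, mech, mstate, list(purview), direction),
                )
        out[direction] = best
    return min(out["cause"], out["effect"])
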