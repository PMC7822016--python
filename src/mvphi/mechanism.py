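"""Mechanism-level irreducibility: tripartitions, AID, phi, MICE.

A mechanism's repertoire over a purview is *irreducible* to the extent
that no partition of the mechanism-purview pair reproduces it.  Partitions
here are tripartitions: every mechanism node and every purview node is
assigned to one of three part slots; each part contributes the repertoire
of its mechanism subset over its purview subset, parts are multiplied, and
the result is compared with the unpartitioned repertoire using the
absolute intrinsic difference (AID)::

    AID(p, q) = max_s  p(s) * | log2( p(s) / q(s) ) |

phi of a mechanism-purview pair is the minimum AID over all tripartitions
(the minimum information partition, MIP); the state attaining the maximum
at the MIP is the *specified state* -- the specific cause or effect of the
mechanism.  The maximally irreducible cause/effect (MICE) maximizes phi
over purviews.
"""

from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import states as st
from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import ValidationError
from .network import Network
from .repertoires import (
    CAUSE,
    EFFECT,
    Repertoire,
    _cause_dist,
    _effect_dist,
    repertoire,
)

__all__ = [
    "PHI_PRECISION",
    "aid",
    "MechanismPartition",
    "enumerate_tripartitions",
    "partitioned_repertoire",
    "phi_mip",
    "MICE",
    "mice",
    "Distinction",
    "compute_distinction",
]

#: phi values below this are treated as exactly zero (float round-off from
#: products of repertoire entries).
PHI_PRECISION = 1e-10


# ---------------------------------------------------------------------------
# measure


def aid(p, q, cap: Optional[float] = None) -> Tuple[float, int]:
    """Absolute intrinsic difference between two repertoires.

    Accepts :class:`Repertoire` objects over the same purview or plain
    arrays of equal length.  Returns ``(phi, state_index)`` where the index
    is the argmax state (first one on ties).  States with ``p(s) = 0``
    contribute 0; ``q(s) = 0`` with ``p(s) > 0`` contributes ``+inf``
    unless ``cap`` is given.
    """
    if isinstance(p, Repertoire) or isinstance(q, Repertoire):
        if p.purview != q.purview:
            raise ValidationError(
                f"mismatched purviews {p.purview} vs {q.purview}"
            )
        p, q = p.dist, q.dist
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"mismatched repertoire shapes {p.shape} vs {q.shape}")
    terms = _aid_terms(p, q)
    if cap is not None:
        terms = np.minimum(terms, cap)
    idx = int(np.argmax(terms))
    return float(terms[idx]), idx


def _aid_terms(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    terms = np.zeros_like(p)
    pos = p > 0
    qz = q <= 0
    both = pos & ~qz
    terms[both] = p[both] * np.abs(np.log2(p[both] / q[both]))
    terms[pos & qz] = np.inf
    return terms


# ---------------------------------------------------------------------------
# tripartitions


@dataclasses.dataclass(frozen=True)
class MechanismPartition:
    """A tripartition: up to three parts ``(mechanism subset, purview
    subset)``; trivially empty parts are dropped."""

    parts: Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], ...]

    def __str__(self) -> str:
        def fmt(nodes):
            return "{" + ",".join(map(str, nodes)) + "}" if nodes else "[]"

        return " x ".join(f"({fmt(m)} / {fmt(z)})" for m, z in self.parts)


@lru_cache(maxsize=None)
def _tripartition_positions(
    n_mech: int, n_purv: int
) -> Tuple[Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], ...], ...]:
    """All tripartitions over *positions* 0..n_mech-1 (mechanism) and
    0..n_purv-1 (purview), deduplicated under part-slot permutation, with
    the identity excluded and empty-empty parts dropped.  Deterministic
    order: fewest parts first, then lexicographic."""
    total = n_mech + n_purv
    seen = set()
    out = []
    for assign in itertools.product(range(3), repeat=total):
        parts_m: List[List[int]] = [[], [], []]
        parts_z: List[List[int]] = [[], [], []]
        for pos in range(n_mech):
            parts_m[assign[pos]].append(pos)
        for pos in range(n_purv):
            parts_z[assign[n_mech + pos]].append(pos)
        parts = tuple(
            sorted(
                (tuple(m), tuple(z))
                for m, z in zip(parts_m, parts_z)
                if m or z
            )
        )
        if len(parts) == 1 and len(parts[0][0]) == n_mech and len(parts[0][1]) == n_purv:
            continue  # identity: severs nothing
        if parts in seen:
            continue
        seen.add(parts)
        out.append(parts)
    out.sort(key=lambda parts: (len(parts), parts))
    return tuple(out)


def enumerate_tripartitions(
    mechanism: Sequence[int], purview: Sequence[int]
) -> List[MechanismPartition]:
    """All non-identity tripartitions of a mechanism-purview pair."""
    mech = tuple(sorted(mechanism))
    purv = tuple(sorted(purview))
    if not purv:
        raise ValidationError("purview must be non-empty")
    out = []
    for parts in _tripartition_positions(len(mech), len(purv)):
        out.append(
            MechanismPartition(
                tuple(
                    (
                        tuple(mech[p] for p in pm),
                        tuple(purv[p] for p in pz),
                    )
                    for pm, pz in parts
                )
            )
        )
    return out


# ---------------------------------------------------------------------------
# partitioned repertoires and phi


def _compose_parts(
    net: Network,
    direction: str,
    parts: Sequence[Tuple[Tuple[int, ...], Tuple[int, ...]]],
    state_of: dict,
    purview: Tuple[int, ...],
) -> np.ndarray:
    """Multiply part repertoires into a flat distribution over the full
    purview (little-endian).  Parts with empty purviews contribute the
    scalar 1; empty-mechanism parts contribute unconstrained repertoires."""
    radices = tuple(net.radices[i] for i in purview)
    axis_of = {z: k for k, z in enumerate(purview)}
    md = np.ones(radices)
    for pm, pz in parts:
        if not pz:
            continue
        rep = repertoire(net, direction, pm, tuple(state_of[i] for i in pm), pz)
        shape = [1] * len(purview)
        for z in pz:
            shape[axis_of[z]] = net.radices[z]
        part_md = rep.multidim() if len(pz) > 1 else rep.dist
        md = md * part_md.reshape(shape, order="F")
    return st.flatten_md(md)


def partitioned_repertoire(
    net: Network,
    partition: MechanismPartition,
    direction: str,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
) -> Repertoire:
    """Repertoire obtained by multiplying the partition's part repertoires."""
    state_of = dict(zip(mechanism, mech_state))
    purview = tuple(sorted(itertools.chain.from_iterable(z for _, z in partition.parts)))
    dist = _compose_parts(net, direction, partition.parts, state_of, purview)
    return Repertoire(purview, tuple(net.radices[i] for i in purview), dist)


@dataclasses.dataclass(frozen=True)
class PhiMIP:
    phi: float
    partition: Optional[MechanismPartition]
    specified_state: Optional[Tuple[int, ...]]


def _detachment_partition(
    mechanism: Tuple[int, ...], purview: Tuple[int, ...], detach_purview_node: int
) -> MechanismPartition:
    rest = tuple(z for z in purview if z != detach_purview_node)
    parts = [((), (detach_purview_node,))]
    if mechanism or rest:
        parts.append((mechanism, rest))
    return MechanismPartition(tuple(sorted(parts)))


def phi_mip(
    net: Network,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    purview: Sequence[int],
    direction: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> PhiMIP:
    """Minimum AID over all tripartitions of (mechanism, purview).

    Returns phi, the minimizing partition (first in enumeration order on
    ties) and the specified purview state.  A null cause repertoire gives
    phi = 0 with no partition.
    """
    mech = tuple(sorted(mechanism))
    state = tuple(v for _, v in sorted(zip(mechanism, mech_state)))
    purv = tuple(sorted(purview))
    if not purv:
        raise ValidationError("purview must be non-empty")
    p = repertoire(net, direction, mech, state, purv)
    if p.null:
        return PhiMIP(0.0, None, None)
    state_of = dict(zip(mech, state))

    # Cheap sufficient test for reducibility: if detaching a single purview
    # node reproduces the repertoire exactly, phi = 0 via that partition.
    if direction == EFFECT and mech:
        for z in purv:
            rz = repertoire(net, EFFECT, mech, state, (z,))
            uz = repertoire(net, EFFECT, (), (), (z,))
            if np.allclose(rz.dist, uz.dist, atol=1e-12, rtol=0):
                part = _detachment_partition(mech, purv, z)
                return PhiMIP(0.0, part, p.state_tuple(0))

    best = np.inf
    best_parts = None
    best_terms = None
    cap = config.phi_cap
    dist_fn = _cause_dist if direction == CAUSE else _effect_dist
    radices = net._radices
    axis_of = {z: k for k, z in enumerate(purv)}
    p_flat = p.dist
    support = np.flatnonzero(p_flat > 0)
    p_sup = p_flat[support]
    logp_sup = np.log2(p_sup)
    part_cache: dict = {}
    seen_keys: set = set()

    def part_array(pm, pz):
        """Part repertoire broadcast over the full purview axes (cached)."""
        arr = part_cache.get((pm, pz))
        if arr is None:
            dist = dist_fn(net, pm, tuple(state_of[i] for i in pm), pz)
            shape = [1] * len(purv)
            for z in pz:
                shape[axis_of[z]] = radices[z]
            arr = dist.reshape(shape, order="F")
            part_cache[(pm, pz)] = arr
        return arr

    with np.errstate(divide="ignore"):
        for parts in _tripartition_positions(len(mech), len(purv)):
            # Mechanism nodes in empty-purview parts do not affect q;
            # partitions differing only in how they are grouped are
            # equivalent -- evaluate each severing pattern once.
            key = tuple((pm, pz) for pm, pz in parts if pz)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            q = None
            for pm, pz in key:
                arr = part_array(
                    tuple(mech[i] for i in pm), tuple(purv[i] for i in pz)
                )
                q = arr if q is None else q * arr
            q_flat = q.ravel(order="F") if q.ndim > 1 else q
            terms = p_sup * np.abs(logp_sup - np.log2(q_flat[support]))
            if cap is not None:
                terms = np.minimum(terms, cap)
            phi = float(terms.max())
            if phi < best - 1e-15:
                best = phi
                best_parts = parts
                best_terms = terms
                if best < PHI_PRECISION:
                    best = 0.0
                    break
    best_partition = None
    best_state = 0
    if best_parts is not None:
        best_partition = MechanismPartition(
            tuple(
                (tuple(mech[i] for i in pm), tuple(purv[i] for i in pz))
                for pm, pz in best_parts
            )
        )
        best_state = int(support[int(np.argmax(best_terms))])
    return PhiMIP(float(best), best_partition, p.state_tuple(best_state))


# ---------------------------------------------------------------------------
# MICE and distinctions


@dataclasses.dataclass(frozen=True)
class MICE:
    """Maximally irreducible cause or effect of a mechanism."""

    direction: str
    purview: Tuple[int, ...]
    repertoire: Optional[Repertoire]
    phi: float
    specified_state: Optional[Tuple[int, ...]]
    mip: Optional[MechanismPartition]


def _candidate_purviews(n: int) -> List[Tuple[int, ...]]:
    subsets = []
    for size in range(n, 0, -1):
        subsets.extend(itertools.combinations(range(n), size))
    return subsets


def mice(
    net: Network,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    direction: str,
    config: RunConfig = DEFAULT_CONFIG,
    candidate_purviews: Optional[Sequence[Sequence[int]]] = None,
) -> MICE:
    """Maximize phi over all non-empty purviews.

    Ties are broken toward the largest purview, then the lexicographically
    first one; candidates are scanned in that order and only a strict
    improvement replaces the incumbent.
    """
    mech = tuple(sorted(mechanism))
    if not mech:
        raise ValidationError("mechanism must be non-empty")
    state = tuple(v for _, v in sorted(zip(mechanism, mech_state)))
    if candidate_purviews is None:
        purviews = _candidate_purviews(net.n)
    else:
        purviews = sorted(
            (tuple(sorted(p)) for p in candidate_purviews), key=lambda p: (-len(p), p)
        )
    best: Optional[PhiMIP] = None
    best_purview: Tuple[int, ...] = ()
    for purv in purviews:
        result = phi_mip(net, mech, state, purv, direction, config)
        if best is None or result.phi > best.phi + PHI_PRECISION:
            best = result
            best_purview = purv
    assert best is not None
    rep = repertoire(net, direction, mech, state, best_purview)
    phi = 0.0 if best.phi <= PHI_PRECISION else best.phi
    return MICE(direction, best_purview, rep, phi, best.specified_state, best.partition)


@dataclasses.dataclass(frozen=True)
class Distinction:
    """A mechanism with its maximally irreducible cause and effect."""

    mechanism: Tuple[int, ...]
    mech_state: Tuple[int, ...]
    cause: MICE
    effect: MICE
    phi: float

    @property
    def order(self) -> int:
        return len(self.mechanism)


def compute_distinction(
    net: Network,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    config: RunConfig = DEFAULT_CONFIG,
) -> Optional[Distinction]:
    """The distinction of a mechanism, or ``None`` if it is reducible
    (min of cause phi and effect phi is zero)."""
    mech = tuple(sorted(mechanism))
    state = tuple(v for _, v in sorted(zip(mechanism, mech_state)))
    cause = mice(net, mech, state, CAUSE, config)
    if cause.phi <= PHI_PRECISION:
        return None
    effect = mice(net, mech, state, EFFECT, config)
    if effect.phi <= PHI_PRECISION:
        return None
    return Distinction(mech, state, cause, effect, min(cause.phi, effect.phi))
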