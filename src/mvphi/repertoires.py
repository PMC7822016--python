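"""Cause and effect repertoires.

A *mechanism* (a subset of elements in a fixed current state) constrains
the past and future states of a *purview* (another subset of elements).
The effect repertoire is the distribution over next purview states given
the mechanism state, with all non-mechanism inputs marginalized under the
uniform (maximum-entropy perturbation) distribution.  The cause repertoire
is the Bayesian inversion under a uniform prior over prior system states.

Conventions
-----------
* Mechanisms and purviews are tuples of node indices; they are sorted
  internally, and mechanism state tuples are aligned with the sorted
  mechanism.
* Repertoire distributions are flat arrays over the purview's joint
  states in little-endian order (first purview node varies fastest).
* The effect repertoire over several purview nodes is the product of the
  single-node effect repertoires ("virtual elements"): joint next-state
  correlations induced by shared marginalized inputs are deliberately not
  tracked, matching the causal (interventional) reading of the TPM.
* The cause repertoire factorizes over mechanism nodes before
  normalization: each mechanism node contributes the likelihood of each
  purview state, likelihoods are multiplied across mechanism nodes, and
  the product is normalized.  For multi-node mechanisms this differs from
  a joint Bayesian inversion of the whole mechanism.
* A mechanism state that no prior purview state can produce has an
  all-zero likelihood; the cause repertoire is then *null* (the mechanism
  specifies no cause, and phi = 0 downstream).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np

from . import states as st
from .exceptions import ValidationError
from .network import Network

__all__ = [
    "Repertoire",
    "effect_repertoire",
    "cause_repertoire",
    "repertoire",
    "unconstrained_repertoire",
]

CAUSE = "cause"
EFFECT = "effect"


@dataclasses.dataclass(frozen=True)
class Repertoire:
    """A probability distribution over the states of a purview.

    ``dist`` is flat in little-endian purview-state order.  The empty
    purview has the scalar distribution ``[1.0]``.  A null repertoire
    (unreachable mechanism state on the cause side) has ``null=True`` and
    an all-zero ``dist``.
    """

    purview: Tuple[int, ...]
    radices: Tuple[int, ...]
    dist: np.ndarray
    null: bool = False

    def __post_init__(self):
        self.dist.setflags(write=False)

    def multidim(self) -> np.ndarray:
        return st.reshape_to_md(self.dist, self.radices)

    def state_tuple(self, index: int) -> Tuple[int, ...]:
        return st.decode_state(index, self.radices)

    def allclose(self, other: "Repertoire", tol: float = 1e-9) -> bool:
        return (
            self.purview == other.purview
            and self.null == other.null
            and np.allclose(self.dist, other.dist, atol=tol, rtol=0)
        )


def _norm_mechanism(
    net: Network, mechanism: Sequence[int], mech_state: Sequence[int]
) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    if len(mechanism) != len(mech_state):
        raise ValidationError("mech_state length must match mechanism size")
    pairs = sorted(zip(mechanism, mech_state))
    mech = tuple(i for i, _ in pairs)
    if len(set(mech)) != len(mech):
        raise ValidationError(f"duplicate nodes in mechanism {mechanism}")
    if any(i < 0 or i >= net.n for i in mech):
        raise ValidationError(f"mechanism {mechanism} not a subset of nodes")
    state = tuple(int(v) for _, v in pairs)
    for i, v in zip(mech, state):
        if not 0 <= v < net.radices[i]:
            raise ValidationError(
                f"state {v} out of range for node {i} ({net.radices[i]} states)"
            )
    return mech, state


def _norm_purview(net: Network, purview: Sequence[int]) -> Tuple[int, ...]:
    p = tuple(sorted(purview))
    if len(set(p)) != len(p) or any(i < 0 or i >= net.n for i in p):
        raise ValidationError(f"purview {purview} not a valid node subset")
    return p


def _effect_node_dist(
    net: Network,
    node: int,
    mechanism: Tuple[int, ...],
    mech_state: Tuple[int, ...],
) -> np.ndarray:
    """Next-state distribution of one purview node given the mechanism
    state, non-mechanism inputs uniformly marginalized (cached)."""
    key = (EFFECT, node, mechanism, mech_state)
    out = net._cache.get(key)
    if out is None:
        md = net.conditional_md(node)  # radices + (S_node,)
        pos = {i: k for k, i in enumerate(mechanism)}
        idx = tuple(
            mech_state[pos[j]] if j in pos else slice(None) for j in range(net.n)
        ) + (slice(None),)
        sub = md[idx]
        out = sub.reshape(-1, net.radices[node]).mean(axis=0)
        out.setflags(write=False)
        net._cache[key] = out
    return out


def _cause_likelihood(
    net: Network,
    node: int,
    value: int,
    purview: Tuple[int, ...],
) -> np.ndarray:
    """Likelihood of each purview prior state for one mechanism node
    being found in ``value``, marginalized (summed) over non-purview prior
    elements (cached).  Multi-dim over purview radices."""
    key = (CAUSE, node, value, purview)
    out = net._cache.get(key)
    if out is None:
        L = net.conditional_md(node)[..., value]  # over prior radices
        drop = tuple(j for j in range(net.n) if j not in purview)
        out = L.sum(axis=drop) if drop else L
        out = np.ascontiguousarray(out)
        out.setflags(write=False)
        net._cache[key] = out
    return out


def _effect_dist(
    net: Network,
    mech: Tuple[int, ...],
    mstate: Tuple[int, ...],
    purv: Tuple[int, ...],
) -> np.ndarray:
    """Fast path: flat effect distribution (inputs pre-sorted and valid)."""
    key = ("ed", mech, mstate, purv)
    dist = net._cache.get(key)
    if dist is None:
        if not purv:
            dist = np.ones(1)
        else:
            dist = None
            for z in purv:
                dz = _effect_node_dist(net, z, mech, mstate)
                if dist is None:
                    dist = dz
                else:
                    dist = (dist[:, None] * dz[None, :]).ravel(order="F")
        net._cache[key] = dist
    return dist


def effect_repertoire(
    net: Network,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    purview: Sequence[int],
) -> Repertoire:
    """Distribution over next purview states given the mechanism state."""
    mech, mstate = _norm_mechanism(net, mechanism, mech_state)
    purv = _norm_purview(net, purview)
    key = ("rep", EFFECT, mech, mstate, purv)
    rep = net._cache.get(key)
    if rep is None:
        radices = tuple(net.radices[i] for i in purv)
        rep = Repertoire(purv, radices, _effect_dist(net, mech, mstate, purv))
        net._cache[key] = rep
    return rep


def _cause_dist(
    net: Network,
    mech: Tuple[int, ...],
    mstate: Tuple[int, ...],
    purv: Tuple[int, ...],
) -> np.ndarray:
    """Fast path: flat cause distribution (all-zero iff null)."""
    key = ("cd", mech, mstate, purv)
    dist = net._cache.get(key)
    if dist is None:
        radices = tuple(net._radices[i] for i in purv)
        if not purv:
            dist = np.ones(1)
        elif not mech:
            size = st.num_states(radices)
            dist = np.full(size, 1.0 / size)
        else:
            prod = _cause_likelihood(net, mech[0], mstate[0], purv)
            for i, v in zip(mech[1:], mstate[1:]):
                prod = prod * _cause_likelihood(net, i, v, purv)
            flat = prod.ravel(order="F") if prod.ndim > 1 else prod
            total = flat.sum()
            if total <= 0:
                dist = np.zeros_like(flat)
            else:
                dist = flat / total
        net._cache[key] = dist
    return dist


def cause_repertoire(
    net: Network,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    purview: Sequence[int],
) -> Repertoire:
    """Distribution over prior purview states given the mechanism state
    (uniform prior; see module docstring for the factorization)."""
    mech, mstate = _norm_mechanism(net, mechanism, mech_state)
    purv = _norm_purview(net, purview)
    key = ("rep", CAUSE, mech, mstate, purv)
    rep = net._cache.get(key)
    if rep is None:
        radices = tuple(net.radices[i] for i in purv)
        dist = _cause_dist(net, mech, mstate, purv)
        null = bool(mech) and bool(purv) and float(dist.sum()) == 0.0
        rep = Repertoire(purv, radices, dist, null=null)
        net._cache[key] = rep
    return rep


def repertoire(
    net: Network,
    direction: str,
    mechanism: Sequence[int],
    mech_state: Sequence[int],
    purview: Sequence[int],
) -> Repertoire:
    if direction == CAUSE:
        return cause_repertoire(net, mechanism, mech_state, purview)
    if direction == EFFECT:
        return effect_repertoire(net, mechanism, mech_state, purview)
    raise ValidationError(f"unknown direction {direction!r}")


def unconstrained_repertoire(
    net: Network, direction: str, purview: Sequence[int]
) -> Repertoire:
    """Repertoire with an empty mechanism: uniform on the cause side, the
    fully marginalized next-state distribution on the effect side."""
    return repertoire(net, direction, (), (), purview)
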