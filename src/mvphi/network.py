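"""State-by-state TPM representation and causal-model primitives.

The central object is :class:`Network`: an ordered list of elements with
per-element state counts and an ``S x S`` row-stochastic transition
probability matrix (TPM) over joint states, in little-endian state order
(see :mod:`mvphi.states`).

The TPM of a well-formed causal model factorizes into per-element
conditionals (no instantaneous causation)::

    Pr(s_t | s_{t-1}) = prod_i Pr(s_{i,t} | s_{t-1})

This module provides that factorization, the conditional-independence
check, adjacency inference, unidirectional system cuts and effective
information.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import states as st
from .exceptions import ValidationError

__all__ = [
    "NodeSpec",
    "Network",
    "NodeConditionals",
    "SystemCut",
    "ValidationReport",
    "validate_network",
    "node_conditionals",
    "check_conditional_independence",
    "infer_adjacency",
    "tpm_from_conditionals",
    "apply_cut",
    "condition_on_external",
    "effective_information",
]

#: Absolute tolerance within which TPM rows must sum to one on input.  Rows
#: within this tolerance are renormalized exactly; rows outside it are
#: rejected (silent renormalization would hide data errors).
ROW_SUM_TOL = 1e-6

#: Default absolute tolerance for the conditional-independence check.
CI_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class NodeSpec:
    """An element of the network: a label and its number of states."""

    label: str
    num_states: int

    def __post_init__(self):
        if self.num_states < 2:
            raise ValidationError(
                f"node {self.label!r}: num_states must be >= 2, got {self.num_states}"
            )


@dataclasses.dataclass(frozen=True)
class SystemCut:
    """A unidirectional bipartition of the system.

    Connections from ``from_part`` to ``to_part`` are severed; all other
    connections (within each part and from ``to_part`` back to
    ``from_part``) remain intact.
    """

    from_part: Tuple[int, ...]
    to_part: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "from_part", tuple(sorted(self.from_part)))
        object.__setattr__(self, "to_part", tuple(sorted(self.to_part)))
        if not self.from_part or not self.to_part:
            raise ValidationError("both parts of a system cut must be non-empty")
        if set(self.from_part) & set(self.to_part):
            raise ValidationError("cut parts must be disjoint")

    def validate_for(self, n: int) -> None:
        if sorted(self.from_part + self.to_part) != list(range(n)):
            raise ValidationError(
                f"cut {self} is not a bipartition of nodes 0..{n - 1}"
            )

    def __str__(self) -> str:
        return f"{list(self.from_part)} -/-> {list(self.to_part)}"


class Network:
    """A discrete dynamical system with multi-valued elements.

    Parameters
    ----------
    tpm
        ``S x S`` row-stochastic matrix over joint states, little-endian
        state order on both axes.
    num_states_per_node
        Per-element state counts ``(S_1, ..., S_n)``; ``S = prod S_i``.
    node_labels
        Optional element labels (unique).  Defaults to ``n0, n1, ...``.
    adjacency
        Optional ``n x n`` binary matrix with ``adjacency[j, i] = 1`` iff
        element ``j`` is a parent of element ``i``.  Checked against the
        inferred adjacency by :func:`validate_network`.
    validate
        If true (default), reject negative entries and rows whose sums
        deviate from 1 by more than ``ROW_SUM_TOL``.
    """

    def __init__(
        self,
        tpm,
        num_states_per_node: Sequence[int],
        node_labels: Optional[Sequence[str]] = None,
        adjacency=None,
        validate: bool = True,
    ):
        radices = tuple(int(r) for r in num_states_per_node)
        if not radices:
            raise ValidationError("a network needs at least one node")
        nodes = []
        if node_labels is None:
            node_labels = [f"n{i}" for i in range(len(radices))]
        if len(node_labels) != len(radices):
            raise ValidationError("node_labels length must match num_states_per_node")
        if len(set(node_labels)) != len(node_labels):
            raise ValidationError("node labels must be unique")
        for lab, r in zip(node_labels, radices):
            nodes.append(NodeSpec(str(lab), r))

        S = st.num_states(radices)
        tpm = np.array(tpm, dtype=float)
        if tpm.ndim != 2 or tpm.shape[0] != tpm.shape[1]:
            raise ValidationError(
                f"TPM must be square, got shape {tpm.shape}; expected {S} x {S}"
            )
        if tpm.shape[0] != S:
            raise ValidationError(
                f"TPM side {tpm.shape[0]} does not match the state space: "
                f"prod(num_states_per_node) = {S}"
            )
        if validate:
            if (tpm < 0).any():
                raise ValidationError("TPM contains negative entries")
            sums = tpm.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
            if bad.size:
                raise ValidationError(
                    f"TPM rows {bad[:5].tolist()} sum to {sums[bad[:5]].tolist()}, "
                    f"not 1 (tolerance {ROW_SUM_TOL})"
                )
            tpm = tpm / sums[:, None]
        tpm.setflags(write=False)

        self.nodes: Tuple[NodeSpec, ...] = tuple(nodes)
        self._radices: Tuple[int, ...] = radices
        self.tpm: np.ndarray = tpm
        self.adjacency = None if adjacency is None else np.asarray(adjacency, dtype=int)
        self._cache: dict = {}
        self._conditionals: Optional[List[np.ndarray]] = None

    # -- basic properties -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def radices(self) -> Tuple[int, ...]:
        return self._radices

    @property
    def S(self) -> int:
        return self.tpm.shape[0]

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(node.label for node in self.nodes)

    def node_index(self, label: str) -> int:
        for i, node in enumerate(self.nodes):
            if node.label == label:
                return i
        raise KeyError(label)

    def __repr__(self) -> str:
        sig = ", ".join(f"{node.label}:{node.num_states}" for node in self.nodes)
        return f"Network({sig}; S={self.S})"

    # -- factorization ----------------------------------------------------

    def conditional(self, i: int) -> np.ndarray:
        """``(S, S_i)`` table ``Pr(s_{i,t} = j | s_{t-1} = h)`` for node i."""
        if self._conditionals is None:
            self._conditionals = _compute_conditionals(self.tpm, self.radices)
        return self._conditionals[i]

    def conditional_md(self, i: int) -> np.ndarray:
        """Node i's conditional with the prior state unpacked to one axis
        per element: shape ``radices + (S_i,)``."""
        key = ("cond_md", i)
        arr = self._cache.get(key)
        if arr is None:
            cond = self.conditional(i)
            arr = cond.reshape(self.radices + (self.radices[i],), order="F")
            arr.setflags(write=False)
            self._cache[key] = arr
        return arr


def _compute_conditionals(tpm: np.ndarray, radices: Sequence[int]) -> List[np.ndarray]:
    S = tpm.shape[0]
    out = []
    # Next-state axis unpacked per element, little-endian.
    md = tpm.reshape((S,) + tuple(radices), order="F")
    n = len(radices)
    for i in range(n):
        axes = tuple(1 + j for j in range(n) if j != i)
        cond = md.sum(axis=axes)
        cond.setflags(write=False)
        out.append(cond)
    return out


@dataclasses.dataclass
class NodeConditionals:
    """Per-node next-state conditionals ``Pr(s_{i,t} | s_{t-1})``."""

    tables: List[np.ndarray]  # node i: shape (S, S_i)
    radices: Tuple[int, ...]
    labels: Tuple[str, ...]

    def reconstruct_tpm(self) -> np.ndarray:
        """Product over nodes; equals the stored TPM iff the model is
        conditionally independent."""
        return tpm_from_conditionals(self.tables, self.radices)


def node_conditionals(net: Network) -> NodeConditionals:
    """Factorize the TPM into per-node conditionals (column marginals of
    each row over the node's next states)."""
    return NodeConditionals(
        tables=[net.conditional(i) for i in range(net.n)],
        radices=net.radices,
        labels=net.labels,
    )


def tpm_from_conditionals(
    tables: Sequence[np.ndarray], radices: Sequence[int]
) -> np.ndarray:
    """Assemble a state-by-state TPM as the product of per-node
    conditionals (little-endian column order)."""
    S = st.num_states(radices)
    out = np.ones((S, 1))
    for cond in tables:
        # next-state index grows little-endian: existing block varies fastest,
        # the newly appended node gets the largest stride so far
        out = (out[:, None, :] * cond[:, :, None]).reshape(S, -1)
    if out.shape[1] != S:
        raise ValidationError("conditional tables inconsistent with radices")
    return out


def check_conditional_independence(
    net: Network, tol: float = CI_TOL
) -> Tuple[bool, float]:
    """Check the Markov factorization of the TPM.

    Returns ``(ok, max_deviation)`` where the deviation is the largest
    absolute difference between a TPM entry and the corresponding product
    of per-node conditionals.
    """
    product = tpm_from_conditionals(
        [net.conditional(i) for i in range(net.n)], net.radices
    )
    dev = float(np.abs(product - net.tpm).max())
    return dev <= tol, dev


def infer_adjacency(net: Network, tol: float = CI_TOL) -> np.ndarray:
    """Infer the directed adjacency matrix from the TPM.

    ``A[j, i] = 1`` iff node ``j`` is a parent of node ``i``: there exist
    two prior states differing only in ``j``'s value for which node ``i``'s
    conditional distributions differ.
    """
    n = net.n
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        md = net.conditional_md(i)  # radices + (S_i,)
        for j in range(n):
            spread = md.max(axis=j) - md.min(axis=j)
            if spread.max() > tol:
                A[j, i] = 1
    return A


@dataclasses.dataclass
class ValidationReport:
    """Outcome of :func:`validate_network`; empty iff the model is valid."""

    row_sum_violations: List[int]
    negative_entries: List[Tuple[int, int]]
    conditional_independence_deviation: float
    conditional_independence_ok: bool
    adjacency_mismatches: List[Tuple[int, int]]

    @property
    def valid(self) -> bool:
        return (
            not self.row_sum_violations
            and not self.negative_entries
            and self.conditional_independence_ok
            and not self.adjacency_mismatches
        )

    def __str__(self) -> str:
        if self.valid:
            return "valid"
        lines = []
        if self.row_sum_violations:
            lines.append(f"rows not summing to 1: {self.row_sum_violations}")
        if self.negative_entries:
            lines.append(f"negative entries at: {self.negative_entries[:10]}")
        if not self.conditional_independence_ok:
            lines.append(
                "TPM does not factorize into per-node conditionals "
                f"(max deviation {self.conditional_independence_deviation:.3g})"
            )
        if self.adjacency_mismatches:
            lines.append(
                f"declared adjacency disagrees with TPM at (parent, child): "
                f"{self.adjacency_mismatches}"
            )
        return "; ".join(lines)


def validate_network(net: Network, ci_tol: float = CI_TOL) -> ValidationReport:
    """Full structural validation of a network (see :class:`ValidationReport`)."""
    sums = net.tpm.sum(axis=1)
    row_bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL).tolist()
    neg = [tuple(ix) for ix in np.argwhere(net.tpm < 0)]
    ok, dev = check_conditional_independence(net, ci_tol)
    mismatches: List[Tuple[int, int]] = []
    if net.adjacency is not None:
        inferred = infer_adjacency(net)
        for j, i in np.argwhere(inferred != net.adjacency):
            mismatches.append((int(j), int(i)))
    return ValidationReport(
        row_sum_violations=row_bad,
        negative_entries=neg,
        conditional_independence_deviation=dev,
        conditional_independence_ok=ok,
        adjacency_mismatches=mismatches,
    )


def apply_cut(net: Network, cut: SystemCut) -> Network:
    """Sever all connections from ``cut.from_part`` into ``cut.to_part``.

    Each severed input is replaced by independent maximum-entropy noise:
    for every node in ``to_part`` the conditional is averaged uniformly
    over the states of the ``from_part`` elements.  Connections within each
    part and from ``to_part`` to ``from_part`` are untouched.  The cut is
    idempotent and never introduces new parents.
    """
    cut.validate_for(net.n)
    to_set = set(cut.to_part)
    tables = []
    for i in range(net.n):
        if i in to_set:
            md = net.conditional_md(i)
            mean = md.mean(axis=tuple(cut.from_part), keepdims=True)
            md = np.broadcast_to(mean, md.shape)
            tables.append(md.reshape(net.S, net.radices[i], order="F"))
        else:
            tables.append(net.conditional(i))
    tpm = tpm_from_conditionals(tables, net.radices)
    return Network(tpm, net.radices, node_labels=net.labels, validate=False)


def condition_on_external(
    net: Network, subsystem: Sequence[int], state: Sequence[int]
) -> Network:
    """Restrict the model to ``subsystem`` with all external elements
    frozen in their current state (background conditions).

    External inputs are conditioned on the frozen values; external outputs
    are dropped.  Node indices in the returned network are local to the
    subsystem (labels are preserved).
    """
    subsystem = tuple(sorted(subsystem))
    if not subsystem:
        raise ValidationError("subsystem must be non-empty")
    if any(i < 0 or i >= net.n for i in subsystem):
        raise ValidationError("subsystem indices out of range")
    external = [j for j in range(net.n) if j not in subsystem]
    sub_radices = tuple(net.radices[i] for i in subsystem)
    S_sub = st.num_states(sub_radices)
    tables = []
    for i in subsystem:
        md = net.conditional_md(i)
        idx = tuple(
            int(state[j]) if j in external else slice(None) for j in range(net.n)
        ) + (slice(None),)
        sub = md[idx]
        tables.append(np.ascontiguousarray(sub.reshape(S_sub, net.radices[i], order="F")))
    tpm = tpm_from_conditionals(tables, sub_radices)
    return Network(
        tpm,
        sub_radices,
        node_labels=[net.labels[i] for i in subsystem],
        validate=False,
    )


def effective_information(net: Network) -> float:
    """Mutual information across one system update under a uniform input
    distribution, in bits.  Bounded by ``log2(S)``."""
    P = net.tpm

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    marginal = P.mean(axis=0)
    h_cond = float(np.mean([entropy(row) for row in P]))
    return max(entropy(marginal) - h_cond, 0.0)
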