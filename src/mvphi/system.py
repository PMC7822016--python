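"""System-level analysis: cause-effect structures, cuts, Phi, SIA.

The cause-effect structure (CES) of a system in a state is the set of
distinctions specified by all mechanisms with phi > 0.  Integrated
information Phi is the total small-phi lost from the CES under the
minimum information partition: the unidirectional bipartition cut whose
severed connections destroy the least phi.  Cuts are assumed not to
create new distinctions, so only the mechanisms of the intact CES are
re-evaluated under each cut (their purviews are re-searched).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import states as st
from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import StateUnreachableError, ValidationError
from .mechanism import (
    CAUSE,
    EFFECT,
    PHI_PRECISION,
    Distinction,
    compute_distinction,
    mice,
)
from .network import Network, SystemCut, apply_cut, condition_on_external

__all__ = [
    "CES",
    "SIAResult",
    "compute_ces",
    "enumerate_system_cuts",
    "ces_phi_under_cut",
    "sia",
    "major_complex",
]


@dataclasses.dataclass(frozen=True)
class CES:
    """A cause-effect structure: the distinctions of a system in a state."""

    distinctions: Tuple[Distinction, ...]

    def __iter__(self):
        return iter(self.distinctions)

    def __len__(self) -> int:
        return len(self.distinctions)

    @property
    def sum_phi(self) -> float:
        return float(sum(d.phi for d in self.distinctions))

    @property
    def mean_phi(self) -> Optional[float]:
        """Mean phi over distinctions; ``None`` for an empty CES."""
        if not self.distinctions:
            return None
        return self.sum_phi / len(self.distinctions)

    def mechanisms(self) -> List[Tuple[int, ...]]:
        return [d.mechanism for d in self.distinctions]

    def to_dict(self, labels: Optional[Sequence[str]] = None) -> dict:
        def names(nodes):
            return [labels[i] for i in nodes] if labels else list(nodes)

        return {
            "sum_phi": self.sum_phi,
            "n_distinctions": len(self),
            "distinctions": [
                {
                    "mechanism": names(d.mechanism),
                    "mech_state": list(d.mech_state),
                    "phi": d.phi,
                    "cause": {
                        "purview": names(d.cause.purview),
                        "phi": d.cause.phi,
                        "specified_state": list(d.cause.specified_state or []),
                    },
                    "effect": {
                        "purview": names(d.effect.purview),
                        "phi": d.effect.phi,
                        "specified_state": list(d.effect.specified_state or []),
                    },
                }
                for d in self.distinctions
            ],
        }


def _all_mechanisms(n: int) -> List[Tuple[int, ...]]:
    out = []
    for size in range(1, n + 1):
        out.extend(itertools.combinations(range(n), size))
    return out


def compute_ces(
    net: Network,
    state: Sequence[int],
    config: RunConfig = DEFAULT_CONFIG,
    mechanisms: Optional[Sequence[Tuple[int, ...]]] = None,
) -> CES:
    """Distinctions of every mechanism with phi > 0, in canonical
    (size, lexicographic) mechanism order."""
    state = tuple(int(v) for v in state)
    if len(state) != net.n:
        raise ValidationError("state length must match the number of nodes")
    if mechanisms is None:
        mechanisms = _all_mechanisms(net.n)
    found = []
    for mech in mechanisms:
        d = compute_distinction(net, mech, st.substate(state, mech), config)
        if d is not None:
            found.append(d)
    return CES(tuple(found))


def enumerate_system_cuts(n: int) -> List[SystemCut]:
    """All ``2^n - 2`` ordered (unidirectional) bipartition cuts, in
    deterministic (size of from-part, lexicographic) order."""
    if n < 2:
        return []
    cuts = []
    nodes = set(range(n))
    for size in range(1, n):
        for from_part in itertools.combinations(range(n), size):
            to_part = tuple(sorted(nodes - set(from_part)))
            cuts.append(SystemCut(from_part, to_part))
    return cuts


def _mechanism_phi(
    net: Network,
    mechanism: Tuple[int, ...],
    mech_state: Tuple[int, ...],
    config: RunConfig,
) -> float:
    """min(cause phi, effect phi) of one mechanism on the given network."""
    cause = mice(net, mechanism, mech_state, CAUSE, config)
    if cause.phi <= PHI_PRECISION:
        return 0.0
    effect = mice(net, mechanism, mech_state, EFFECT, config)
    return float(min(cause.phi, effect.phi))


def ces_phi_under_cut(
    net: Network,
    state: Sequence[int],
    ces: CES,
    cut: SystemCut,
    config: RunConfig = DEFAULT_CONFIG,
) -> Tuple[float, Dict[Tuple[int, ...], float]]:
    """Total phi lost from the CES under a system cut.

    Each intact distinction's mechanism is re-evaluated on the cut network
    (purviews re-searched in both directions); a destroyed distinction
    contributes its full phi.  No new mechanisms are searched (cuts cannot
    create distinctions).  Returns ``(loss, phi-under-cut per mechanism)``.
    """
    cut_net = apply_cut(net, cut)
    loss = 0.0
    cut_phis: Dict[Tuple[int, ...], float] = {}
    for d in ces:
        phi_cut = _mechanism_phi(cut_net, d.mechanism, d.mech_state, config)
        cut_phis[d.mechanism] = phi_cut
        loss += abs(d.phi - phi_cut)
    return float(loss), cut_phis


@dataclasses.dataclass(frozen=True)
class SIAResult:
    """Outcome of a system irreducibility analysis.

    Node indices inside ``ces`` and ``mip_cut`` are local to the analyzed
    subsystem; ``subsystem`` holds the parent-network indices and
    ``labels`` the (globally meaningful) element labels.
    """

    subsystem: Tuple[int, ...]
    state: Tuple[int, ...]
    big_phi: float
    mip_cut: Optional[SystemCut]
    ces: CES
    partitioned_phis: Dict[Tuple[int, ...], float]
    labels: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "subsystem": list(self.subsystem),
            "labels": list(self.labels),
            "state": list(self.state),
            "big_phi": self.big_phi,
            "mip_cut": None
            if self.mip_cut is None
            else {
                "from_part": list(self.mip_cut.from_part),
                "to_part": list(self.mip_cut.to_part),
            },
            "ces": self.ces.to_dict(self.labels or None),
            "partitioned_phis": {
                ",".join(map(str, mech)): phi
                for mech, phi in self.partitioned_phis.items()
            },
        }


def _check_reachable(net: Network, state: Tuple[int, ...]) -> None:
    idx = st.encode_state(state, net.radices)
    if net.tpm[:, idx].max() <= 0:
        raise StateUnreachableError(
            f"state {state} has an all-zero TPM column (no transition leads "
            "to it); choose a state that occurs in the TPM, e.g. a row's "
            "successor state"
        )


def sia(
    net: Network,
    state: Sequence[int],
    config: RunConfig = DEFAULT_CONFIG,
    require_reachable: bool = True,
) -> SIAResult:
    """System irreducibility analysis of the full node set.

    Phi is the minimum over all unidirectional bipartition cuts of the
    phi lost from the intact CES; ties go to the first cut in enumeration
    order.  A single-element system admits no cut and has Phi = 0.
    """
    state = tuple(int(v) for v in state)
    if len(state) != net.n:
        raise ValidationError("state length must match the number of nodes")
    st.encode_state(state, net.radices)  # range check
    if require_reachable:
        _check_reachable(net, state)
    ces = compute_ces(net, state, config)
    subsystem = tuple(range(net.n))
    if net.n == 1:
        return SIAResult(subsystem, state, 0.0, None, ces, {}, net.labels)
    cuts = enumerate_system_cuts(net.n)
    best_loss = np.inf
    best_cut = cuts[0]
    best_phis: Dict[Tuple[int, ...], float] = {}
    for cut in cuts:
        loss, cut_phis = ces_phi_under_cut(net, state, ces, cut, config)
        if loss < best_loss - 1e-15:
            best_loss = loss
            best_cut = cut
            best_phis = cut_phis
            if best_loss <= PHI_PRECISION:
                best_loss = 0.0
                break
    return SIAResult(
        subsystem, state, float(best_loss), best_cut, ces, best_phis, net.labels
    )


def major_complex(
    net: Network,
    state: Sequence[int],
    config: RunConfig = DEFAULT_CONFIG,
) -> SIAResult:
    """The subsystem with maximal Phi.

    Every non-empty node subset is analyzed with the external elements
    frozen in their current state (background conditions).  Ties are
    broken toward the larger subsystem, then lexicographically.
    Subsystems whose conditioned TPM cannot reach their state are skipped.
    """
    state = tuple(int(v) for v in state)
    subsets = sorted(
        (s for size in range(1, net.n + 1) for s in itertools.combinations(range(net.n), size)),
        key=lambda s: (-len(s), s),
    )
    best: Optional[SIAResult] = None
    for subset in subsets:
        if len(subset) == net.n:
            sub_net = net
        else:
            sub_net = condition_on_external(net, subset, state)
        sub_state = st.substate(state, subset)
        try:
            result = sia(sub_net, sub_state, config)
        except StateUnreachableError:
            continue
        result = dataclasses.replace(result, subsystem=subset)
        if best is None or result.big_phi > best.big_phi + PHI_PRECISION:
            best = result
    if best is None:
        raise StateUnreachableError(
            f"state {state} is unreachable in every candidate subsystem"
        )
    return best
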