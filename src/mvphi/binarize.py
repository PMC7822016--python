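"""Binarization of multi-valued evolution functions, and coarse-graining.

Multi-valued logical regulatory models are routinely translated into
Boolean models.  Three translations are implemented for deterministic
evolution functions:

* **Van Ham**: one Boolean variable per activation threshold; value ``k``
  of an ``m``-state component is encoded as ``k`` ones followed by
  ``m - 1 - k`` zeros.  The mapping is one-to-one but *partial*: binary
  states that are not of this thresholded form are non-admissible and get
  no successor.
* **Fauré-Kaji**: for *asymptotic* evolution functions (every component
  either keeps its level, rises to its maximum or falls to zero), the
  constituents of a component are functionally equivalent; any binary
  state is read through the bit-sum of each constituent group, and the
  component's target is written as all-zeros, all-ones, or bits-unchanged.
  The result is total, and coarse-graining it by bit sums reconstructs the
  original function exactly.
* **Tonello**: a stepwise implementation -- each component moves one level
  toward its target per update, re-encoded in threshold (Van Ham) form.
  Total for any deterministic function.  The construction here follows the
  published p53-Mdm2 worked example and is best-effort beyond it; the
  worked example is pinned by a golden-file test.

Coarse-graining goes the other way: micro elements are grouped into macro
elements via a state mapping, micro TPM rows are averaged uniformly within
a macro state and columns are summed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import states as st
from .exceptions import ValidationError
from .network import Network

__all__ = [
    "EvolutionFunction",
    "BinarizationResult",
    "is_asymptotic",
    "van_ham",
    "faure_kaji",
    "tonello",
    "binarize",
    "coarse_grain",
    "count_deterministic_completions",
    "probabilistic_binarization",
]

State = Tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class EvolutionFunction:
    """A deterministic (possibly partial) update map over mixed radices.

    ``table[h]`` is the flat index of the successor of state index ``h``,
    or ``None`` where the map is undefined (partial functions arise from
    the Van Ham binarization).
    """

    radices: Tuple[int, ...]
    table: Tuple[Optional[int], ...]
    labels: Tuple[str, ...] = ()

    def __post_init__(self):
        S = st.num_states(self.radices)
        if len(self.table) != S:
            raise ValidationError(
                f"table has {len(self.table)} entries, expected {S}"
            )
        for h, t in enumerate(self.table):
            if t is not None and not 0 <= t < S:
                raise ValidationError(f"successor index {t} of state {h} out of range")
        if self.labels and len(self.labels) != len(self.radices):
            raise ValidationError("labels length must match radices")

    @property
    def is_total(self) -> bool:
        return all(t is not None for t in self.table)

    @property
    def n(self) -> int:
        return len(self.radices)

    def successor(self, state: Sequence[int]) -> Optional[State]:
        t = self.table[st.encode_state(state, self.radices)]
        return None if t is None else st.decode_state(t, self.radices)

    def defined_states(self):
        for h, t in enumerate(self.table):
            if t is not None:
                yield st.decode_state(h, self.radices)

    @classmethod
    def from_pairs(
        cls,
        radices: Sequence[int],
        pairs: Mapping[State, State],
        labels: Sequence[str] = (),
    ) -> "EvolutionFunction":
        radices = tuple(radices)
        table: list = [None] * st.num_states(radices)
        for s, t in pairs.items():
            table[st.encode_state(s, radices)] = st.encode_state(t, radices)
        return cls(radices, tuple(table), tuple(labels))

    def to_network(self, labels: Optional[Sequence[str]] = None) -> Network:
        """Deterministic state-by-state TPM (exact 0/1 entries)."""
        if not self.is_total:
            raise ValidationError(
                "cannot build a TPM from a partial evolution function: "
                "successors missing for "
                f"{[h for h, t in enumerate(self.table) if t is None]}"
            )
        S = st.num_states(self.radices)
        tpm = np.zeros((S, S))
        for h, t in enumerate(self.table):
            tpm[h, t] = 1.0
        return Network(
            tpm, self.radices, node_labels=labels or (self.labels or None)
        )


def is_asymptotic(f: EvolutionFunction) -> Tuple[bool, Optional[Tuple[State, int]]]:
    """Whether every component's target is always 0, its current value, or
    its maximum.  Returns ``(ok, first violating (state, component))``."""
    for state in f.defined_states():
        target = f.successor(state)
        for j, (v, t, r) in enumerate(zip(state, target, f.radices)):
            if t not in (0, v, r - 1):
                return False, (state, j)
    return True, None


# ---------------------------------------------------------------------------
# Van Ham encoding helpers


def _constituent_labels(f: EvolutionFunction) -> Tuple[str, ...]:
    labels = f.labels or tuple(f"n{i}" for i in range(f.n))
    out = []
    for lab, r in zip(labels, f.radices):
        if r == 2:
            out.append(lab)
        else:
            out.extend(f"{lab}{k}" for k in range(1, r))
    return tuple(out)


def _groups(radices: Sequence[int]) -> Tuple[Tuple[int, ...], ...]:
    """Constituent bit positions per original component."""
    groups = []
    pos = 0
    for r in radices:
        groups.append(tuple(range(pos, pos + r - 1)))
        pos += r - 1
    return tuple(groups)


def _vh_bits(value: int, m: int) -> Tuple[int, ...]:
    """Threshold encoding: ``value`` ones followed by zeros (m-1 bits)."""
    return tuple(1 if k < value else 0 for k in range(m - 1))


def _vh_encode(state: Sequence[int], radices: Sequence[int]) -> State:
    bits: list = []
    for v, r in zip(state, radices):
        bits.extend(_vh_bits(v, r))
    return tuple(bits)


@dataclasses.dataclass(frozen=True)
class BinarizationResult:
    """A Boolean translation of a multi-valued evolution function.

    ``state_map`` sends each multi-valued state to its (admissible) binary
    image; restricted to ``admissible`` states it is a bijection.  The
    Van Ham function is partial (defined on admissible states only);
    Fauré-Kaji and Tonello functions are total.
    """

    method: str
    binary_function: EvolutionFunction
    state_map: Dict[State, State]
    admissible: frozenset
    source_radices: Tuple[int, ...]

    @property
    def inverse_state_map(self) -> Dict[State, State]:
        return {b: m for m, b in self.state_map.items()}

    def map_state(self, state: Sequence[int]) -> State:
        return self.state_map[tuple(state)]


def _binarize_common(f: EvolutionFunction):
    if not f.is_total:
        raise ValidationError("binarization requires a total evolution function")
    groups = _groups(f.radices)
    nbits = sum(r - 1 for r in f.radices)
    bin_radices = (2,) * nbits
    state_map = {s: _vh_encode(s, f.radices) for s in st.all_states(f.radices)}
    admissible = frozenset(state_map.values())
    return groups, bin_radices, state_map, admissible


def van_ham(f: EvolutionFunction) -> BinarizationResult:
    """Threshold (one-bit-per-level) binarization; partial on the
    non-admissible binary states."""
    groups, bin_radices, state_map, admissible = _binarize_common(f)
    table: list = [None] * st.num_states(bin_radices)
    for s in st.all_states(f.radices):
        b = state_map[s]
        succ = state_map[f.successor(s)]
        table[st.encode_state(b, bin_radices)] = st.encode_state(succ, bin_radices)
    fn = EvolutionFunction(bin_radices, tuple(table), _constituent_labels(f))
    return BinarizationResult("van_ham", fn, state_map, admissible, f.radices)


def faure_kaji(f: EvolutionFunction) -> BinarizationResult:
    """Total binarization for asymptotic functions via functionally
    equivalent constituents (bit-sum reading)."""
    ok, violation = is_asymptotic(f)
    if not ok:
        state, comp = violation
        raise ValidationError(
            "Faure-Kaji binarization requires an asymptotic evolution "
            f"function; component {comp} of state {state} moves to an "
            "intermediate level"
        )
    groups, bin_radices, state_map, admissible = _binarize_common(f)
    table = []
    for b in st.all_states(bin_radices):
        coarse = tuple(sum(b[k] for k in g) for g in groups)
        target = f.successor(coarse)
        new_bits: list = []
        for j, g in enumerate(groups):
            t, c, r = target[j], coarse[j], f.radices[j]
            if t == 0:
                new_bits.extend([0] * len(g))
            elif t == r - 1:
                new_bits.extend([1] * len(g))
            elif t == c:
                new_bits.extend(b[k] for k in g)
            else:  # pragma: no cover - excluded by the asymptotic check
                raise AssertionError("non-asymptotic target slipped through")
        table.append(st.encode_state(tuple(new_bits), bin_radices))
    fn = EvolutionFunction(bin_radices, tuple(table), _constituent_labels(f))
    return BinarizationResult("faure_kaji", fn, state_map, admissible, f.radices)


def tonello(f: EvolutionFunction) -> BinarizationResult:
    """Total stepwise binarization: each component moves one level toward
    its target per update, re-encoded in threshold form."""
    groups, bin_radices, state_map, admissible = _binarize_common(f)
    table = []
    for b in st.all_states(bin_radices):
        coarse = tuple(sum(b[k] for k in g) for g in groups)
        target = f.successor(coarse)
        new_bits: list = []
        for j, g in enumerate(groups):
            t, c = target[j], coarse[j]
            step = c + (0 if t == c else (1 if t > c else -1))
            new_bits.extend(_vh_bits(step, f.radices[j]))
        table.append(st.encode_state(tuple(new_bits), bin_radices))
    fn = EvolutionFunction(bin_radices, tuple(table), _constituent_labels(f))
    return BinarizationResult("tonello", fn, state_map, admissible, f.radices)


_METHODS = {"van_ham": van_ham, "faure_kaji": faure_kaji, "tonello": tonello}


def binarize(f: EvolutionFunction, method: str) -> BinarizationResult:
    """Dispatch by method name (``van_ham``, ``faure_kaji``, ``tonello``)."""
    key = method.replace("-", "_").lower()
    if key not in _METHODS:
        raise ValidationError(
            f"unknown binarization method {method!r}; expected one of {sorted(_METHODS)}"
        )
    return _METHODS[key](f)


def count_deterministic_completions(result: BinarizationResult) -> int:
    """Number of deterministic TPM completions of a partial (Van Ham)
    binarization: each missing row can point to any binary state."""
    S = st.num_states(result.binary_function.radices)
    missing = sum(1 for t in result.binary_function.table if t is None)
    return S**missing


# ---------------------------------------------------------------------------
# coarse-graining


def coarse_grain(
    net: Network,
    grouping: Sequence[Sequence[int]],
    state_maps: Sequence[Mapping[State, int]],
    macro_labels: Optional[Sequence[str]] = None,
) -> Network:
    """Aggregate micro elements into macro elements.

    ``grouping`` partitions the micro node indices into macro elements (in
    macro node order); ``state_maps[g]`` maps each joint micro state tuple
    of group ``g`` to a macro value.  Macro TPM rows are uniform averages
    over the micro states of a macro state; columns are summed.
    """
    groups = [tuple(g) for g in grouping]
    flat = [i for g in groups for i in g]
    if sorted(flat) != list(range(net.n)):
        raise ValidationError("grouping must partition the micro nodes")
    macro_radices = []
    for g, smap in zip(groups, state_maps):
        micro_radices = tuple(net.radices[i] for i in g)
        missing = [s for s in st.all_states(micro_radices) if tuple(s) not in smap]
        if missing:
            raise ValidationError(
                f"state_map for group {g} is not total; missing {missing[:4]}"
            )
        values = set(smap.values())
        r = max(values) + 1
        if min(values) < 0 or len(values) != r:
            raise ValidationError(
                f"state_map values for group {g} must cover 0..max contiguously"
            )
        macro_radices.append(r)
    macro_radices = tuple(macro_radices)

    # micro flat index -> macro flat index
    micro_to_macro = np.empty(net.S, dtype=int)
    for h, micro in enumerate(st.all_states(net.radices)):
        macro = tuple(
            smap[st.substate(micro, g)] for g, smap in zip(groups, state_maps)
        )
        micro_to_macro[h] = st.encode_state(macro, macro_radices)

    S_macro = st.num_states(macro_radices)
    agg_cols = np.zeros((net.S, S_macro))
    for h in range(net.S):
        np.add.at(agg_cols[h], micro_to_macro, net.tpm[h])
    macro_tpm = np.zeros((S_macro, S_macro))
    counts = np.zeros(S_macro)
    for h in range(net.S):
        macro_tpm[micro_to_macro[h]] += agg_cols[h]
        counts[micro_to_macro[h]] += 1
    if (counts == 0).any():
        raise ValidationError("some macro state has no micro pre-image")
    macro_tpm /= counts[:, None]
    return Network(macro_tpm, macro_radices, node_labels=macro_labels)


# ---------------------------------------------------------------------------
# experimental


def probabilistic_binarization(f: EvolutionFunction) -> Network:
    """Conjectural probabilistic binarization (experimental).

    Instead of privileging the threshold encoding, a component's target
    value ``v`` is mapped onto *all* bit patterns of its constituent group
    with ``v`` ones, with equal probability (a ternary value 1 becomes
    (0,1) or (1,0) with probability 1/2 each).  Current states are read by
    bit sums.  Returns a probabilistic binary network whose coarse-graining
    by bit sums reproduces ``f``.  This generalizes beyond asymptotic
    functions but is a conjecture, not an established construction.
    """
    from itertools import combinations

    groups, bin_radices, state_map, admissible = _binarize_common(f)
    S_bin = st.num_states(bin_radices)
    # Bits within a group are exchangeable but *correlated* (exactly v of
    # them are 1), so the result generally violates per-element conditional
    # independence and is not suitable for causal analysis as-is; it is
    # provided for coarse-graining demonstrations.
    tpm = np.zeros((S_bin, S_bin))
    for h, b in enumerate(st.all_states(bin_radices)):
        coarse = tuple(sum(b[k] for k in g) for g in groups)
        target = f.successor(coarse)
        group_dists = []
        for j, g in enumerate(groups):
            v = target[j]
            patterns = [
                tuple(1 if k in ones else 0 for k in range(len(g)))
                for ones in combinations(range(len(g)), v)
            ]
            group_dists.append(patterns)

        def fill(j, bits_so_far, w):
            if j == len(groups):
                tpm[h, st.encode_state(tuple(bits_so_far), bin_radices)] += w
                return
            for pat in group_dists[j]:
                fill(j + 1, bits_so_far + list(pat), w / len(group_dists[j]))

        fill(0, [], 1.0)
    return Network(tpm, bin_radices, node_labels=_constituent_labels(f))
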