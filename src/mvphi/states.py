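"""Mixed-radix indexing of joint system states.

A network of ``n`` elements where element ``i`` has ``S_i`` states has
``S = S_1 * S_2 * ... * S_n`` joint states.  Rows and columns of a
state-by-state TPM, as well as repertoire entries, are indexed by a single
integer obtained from the state tuple with a **little-endian** mixed-radix
code: element 0 varies fastest, i.e.::

    index = v_0 + v_1 * S_0 + v_2 * S_0 * S_1 + ...

This convention is fixed throughout the package and its file formats.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

from .exceptions import ValidationError

State = Tuple[int, ...]


def num_states(radices: Sequence[int]) -> int:
    """Total number of joint states for the given per-element state counts."""
    s = 1
    for r in radices:
        s *= int(r)
    return s


def strides(radices: Sequence[int]) -> Tuple[int, ...]:
    """Little-endian strides: element 0 has stride 1."""
    out = []
    s = 1
    for r in radices:
        out.append(s)
        s *= int(r)
    return tuple(out)


def encode_state(state: Sequence[int], radices: Sequence[int]) -> int:
    """Map a state tuple to its little-endian mixed-radix index.

    Raises
    ------
    ValidationError
        If the tuple length does not match the radices or a value is out of
        range.
    """
    if len(state) != len(radices):
        raise ValidationError(
            f"state {tuple(state)} has {len(state)} values, expected {len(radices)}"
        )
    idx = 0
    stride = 1
    for v, r in zip(state, radices):
        v = int(v)
        if not 0 <= v < r:
            raise ValidationError(
                f"state value {v} out of range for an element with {r} states"
            )
        idx += v * stride
        stride *= int(r)
    return idx


def decode_state(index: int, radices: Sequence[int]) -> State:
    """Inverse of :func:`encode_state`."""
    index = int(index)
    if index < 0:
        raise ValidationError(f"negative state index {index}")
    values = []
    for r in radices:
        values.append(index % r)
        index //= r
    if index:
        raise ValidationError("state index out of range for the given radices")
    return tuple(values)


def all_states(radices: Sequence[int]) -> Iterator[State]:
    """Iterate over all joint states in index order (element 0 fastest)."""
    ranges = [range(r) for r in reversed(radices)]
    for rev in itertools.product(*ranges):
        yield rev[::-1]


def reshape_to_md(flat: np.ndarray, radices: Sequence[int]) -> np.ndarray:
    """View a flat little-endian state-indexed array as a multi-dim array.

    Axis ``i`` of the result corresponds to element ``i``.
    """
    return np.reshape(np.asarray(flat), tuple(radices), order="F")


def flatten_md(md: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_to_md` (little-endian ravel)."""
    return np.ravel(md, order="F")


def substate(state: Sequence[int], nodes: Iterable[int]) -> State:
    """Restrict a full state tuple to the given node indices (in order)."""
    return tuple(state[i] for i in nodes)
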