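"""File formats.

TPM TSV
    First header line: tab-separated node labels.  Second header line:
    per-node state counts.  Then ``S`` rows of ``S`` probabilities.
    Rows and columns are in little-endian state order (first node varies
    fastest).  Deterministic TPMs are written with exact ``0``/``1``
    integers.

Network JSON
    ``{"format_version": 1, "nodes": [{"label", "num_states"}, ...],
    "tpm": [[...], ...]}``.

Truth-table TSV (evolution functions)
    Header line with ``n`` time-t column names and the same names
    suffixed with ``'``; then one row per state: ``n`` state values at t
    and either ``n`` values at t+1, a single ``-`` (successor undefined;
    partial functions), or a single ``=`` (successor copied from a
    reference function supplied to the reader).

A small import shim accepts binary *state-by-node* matrices
(``S x n`` with ``P(node = 1 | row)``) and converts them to
state-by-state form.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np

from . import states as st
from .binarize import EvolutionFunction
from .exceptions import ValidationError
from .network import Network, tpm_from_conditionals

__all__ = [
    "read_tpm_tsv",
    "write_tpm_tsv",
    "read_network_json",
    "write_network_json",
    "read_truth_table",
    "write_truth_table",
    "read_network",
    "state_by_node_to_network",
]


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def write_tpm_tsv(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(net.labels) + "\n")
        fh.write("\t".join(str(r) for r in net.radices) + "\n")
        for row in net.tpm:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_tpm_tsv(path) -> Network:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValidationError(f"{path}: expected two header lines plus TPM rows")
    labels = lines[0].split("\t")
    try:
        radices = [int(x) for x in lines[1].split("\t")]
    except ValueError as exc:
        raise ValidationError(f"{path}:2: state counts must be integers") from exc
    if len(radices) != len(labels):
        raise ValidationError(f"{path}:2: {len(radices)} state counts for {len(labels)} labels")
    S = st.num_states(radices)
    if len(lines) - 2 != S:
        raise ValidationError(
            f"{path}: expected {S} TPM rows (product of state counts), got {len(lines) - 2}"
        )
    rows = []
    for k, ln in enumerate(lines[2:], start=3):
        try:
            row = [float(x) for x in ln.split("\t")]
        except ValueError as exc:
            raise ValidationError(f"{path}:{k}: non-numeric TPM entry") from exc
        if len(row) != S:
            raise ValidationError(f"{path}:{k}: expected {S} entries, got {len(row)}")
        rows.append(row)
    return Network(np.array(rows), radices, node_labels=labels)


def write_network_json(net: Network, path) -> None:
    data = {
        "format_version": 1,
        "nodes": [
            {"label": node.label, "num_states": node.num_states} for node in net.nodes
        ],
        "tpm": net.tpm.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_network_json(path) -> Network:
    with open(path) as fh:
        data = json.load(fh)
    try:
        labels = [n["label"] for n in data["nodes"]]
        radices = [int(n["num_states"]) for n in data["nodes"]]
        tpm = np.array(data["tpm"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed network JSON: {exc}") from exc
    return Network(tpm, radices, node_labels=labels)


def read_network(path) -> Network:
    """Dispatch on extension: ``.json`` or TSV (default)."""
    path = str(path)
    if path.endswith(".json"):
        return read_network_json(path)
    return read_tpm_tsv(path)


def write_truth_table(
    f: EvolutionFunction, path, labels: Optional[Sequence[str]] = None
) -> None:
    labels = list(labels or f.labels or (f"n{i}" for i in range(f.n)))
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\t" + "\t".join(f"{l}'" for l in labels) + "\n")
        for state in st.all_states(f.radices):
            succ = f.successor(state)
            left = "\t".join(str(v) for v in state)
            if succ is None:
                fh.write(left + "\t-\n")
            else:
                fh.write(left + "\t" + "\t".join(str(v) for v in succ) + "\n")


def read_truth_table(
    path, reference: Optional[EvolutionFunction] = None
) -> EvolutionFunction:
    """Read a truth-table TSV.

    ``-`` marks an undefined successor; ``=`` copies the successor from
    ``reference`` (error if none is given).  Radices are inferred from the
    maximum value seen per column; every state must appear exactly once.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if len(header) % 2:
        raise ValidationError(f"{path}:1: header must list t and t+1 columns")
    n = len(header) // 2
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) < n:
            raise ValidationError(f"{path}:{k}: fewer than {n} state columns")
        try:
            state = tuple(int(c) for c in cells[:n])
        except ValueError as exc:
            raise ValidationError(f"{path}:{k}: non-integer state value") from exc
        rest = [c for c in cells[n:] if c != ""]
        if rest == ["-"]:
            succ = None
        elif rest == ["="]:
            if reference is None:
                raise ValidationError(
                    f"{path}:{k}: '=' requires a reference function"
                )
            succ = "="
        else:
            if len(rest) != n:
                raise ValidationError(
                    f"{path}:{k}: expected {n} successor values, '-' or '='"
                )
            try:
                succ = tuple(int(c) for c in rest)
            except ValueError as exc:
                raise ValidationError(f"{path}:{k}: non-integer successor") from exc
        rows.append((state, succ))
    radices = [
        max(max(s[j] for s, _ in rows), max((t[j] for _, t in rows if isinstance(t, tuple)), default=0)) + 1
        for j in range(n)
    ]
    radices = [max(r, 2) for r in radices]
    S = st.num_states(radices)
    if len(rows) != S:
        raise ValidationError(
            f"{path}: {len(rows)} rows for a state space of {S}; every state "
            "must appear exactly once"
        )
    table: list = [None] * S
    seen = set()
    for state, succ in rows:
        h = st.encode_state(state, radices)
        if h in seen:
            raise ValidationError(f"{path}: duplicate state {state}")
        seen.add(h)
        if succ == "=":
            ref_succ = reference.successor(state)
            if ref_succ is None:
                raise ValidationError(
                    f"{path}: '=' at state {state} but the reference is undefined there"
                )
            table[h] = st.encode_state(ref_succ, radices)
        elif succ is not None:
            table[h] = st.encode_state(succ, radices)
    labels = tuple(header[:n])
    return EvolutionFunction(tuple(radices), tuple(table), labels)


def state_by_node_to_network(
    matrix, node_labels: Optional[Sequence[str]] = None
) -> Network:
    """Import shim for binary state-by-node TPMs.

    ``matrix`` is ``S x n`` with ``matrix[h, i] = P(node i is 1 | prior
    state h)``, rows in little-endian order.  Only binary elements can be
    represented this way; the result is the state-by-state product form.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("state-by-node matrix must be 2-D")
    S, n = matrix.shape
    if S != 2**n:
        raise ValidationError(
            f"state-by-node form requires S = 2^n (binary nodes); got S={S}, n={n}"
        )
    tables = [np.stack([1 - matrix[:, i], matrix[:, i]], axis=1) for i in range(n)]
    tpm = tpm_from_conditionals(tables, (2,) * n)
    return Network(tpm, (2,) * n, node_labels=node_labels)
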