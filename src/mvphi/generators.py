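"""Network generators and in-paper model fixtures.

Random deterministic networks are labeled by *classes*: the digits of a
class label give the per-node state counts (``"222"`` = three binary
nodes, ``"44"`` = two quaternary nodes).  A label like ``"44(2222)"``
denotes a class that shares its TPMs with the class in parentheses --
the same matrices read with a different node decomposition.

Also provided: the p53-Mdm2 regulatory model (ternary p53 plus two binary
Mdm2 species) and a three-neuron toy circuit in ternary (0, 1 or 2 spikes
per bin) and binary (firing or not) readings.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from . import states as st
from .binarize import EvolutionFunction
from .exceptions import ValidationError
from .network import Network, tpm_from_conditionals

__all__ = [
    "ClassLabel",
    "random_deterministic_tpm",
    "random_deterministic_net",
    "random_asymptotic_function",
    "p53_evolution_function",
    "p53_model",
    "ternary_neuron_model",
    "binary_neuron_model",
]


@dataclasses.dataclass(frozen=True)
class ClassLabel:
    """A random-network class: per-node state counts, optionally sharing
    TPMs with another class of equal total state count."""

    digits: Tuple[int, ...]
    shared_tpm_source: Optional["ClassLabel"] = None

    def __post_init__(self):
        if not self.digits or any(d < 2 for d in self.digits):
            raise ValidationError("every class digit must be >= 2")
        if self.shared_tpm_source is not None:
            if st.num_states(self.digits) != st.num_states(
                self.shared_tpm_source.digits
            ):
                raise ValidationError(
                    "shared-TPM classes must have the same total state count"
                )

    @classmethod
    def parse(cls, text: Union[str, "ClassLabel"]) -> "ClassLabel":
        """Parse labels like ``"222"``, ``"2235"`` or ``"44(2222)"``."""
        if isinstance(text, ClassLabel):
            return text
        m = re.fullmatch(r"(\d+)(?:\((\d+)\))?", text.strip())
        if not m:
            raise ValidationError(f"cannot parse class label {text!r}")
        digits = tuple(int(c) for c in m.group(1))
        source = None
        if m.group(2):
            source = cls(tuple(int(c) for c in m.group(2)))
        return cls(digits, source)

    @property
    def n(self) -> int:
        return len(self.digits)

    @property
    def S(self) -> int:
        return st.num_states(self.digits)

    def __str__(self) -> str:
        base = "".join(map(str, self.digits))
        if self.shared_tpm_source:
            return f"{base}({self.shared_tpm_source})"
        return base


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_deterministic_tpm(S: int, seed) -> np.ndarray:
    """An ``S x S`` 0/1 TPM with one uniformly drawn successor per row."""
    rng = _rng(seed)
    succ = rng.integers(0, S, size=S)
    tpm = np.zeros((S, S))
    tpm[np.arange(S), succ] = 1.0
    return tpm


def random_deterministic_net(label, seed) -> Network:
    """A random deterministic network of the given class.

    For a shared-TPM class the matrix is drawn exactly as for its source
    class (the draw depends only on ``S``), then read with this class's
    radices.
    """
    label = ClassLabel.parse(label)
    tpm = random_deterministic_tpm(label.S, seed)
    return Network(tpm, label.digits)


def random_asymptotic_function(radices: Sequence[int], seed) -> EvolutionFunction:
    """A random asymptotic evolution function: for every state, each
    component's target is drawn uniformly from the *set*
    ``{0, current value, max value}`` (duplicates collapse)."""
    rng = _rng(seed)
    radices = tuple(int(r) for r in radices)
    table = []
    for state in st.all_states(radices):
        target = []
        for v, r in zip(state, radices):
            options = sorted({0, v, r - 1})
            target.append(options[rng.integers(len(options))])
        table.append(st.encode_state(tuple(target), radices))
    return EvolutionFunction(radices, tuple(table))


# ---------------------------------------------------------------------------
# p53-Mdm2 regulatory model


#: Asymptotic evolution function of the p53-Mdm2 model: P (active p53,
#: ternary), Mc (cytoplasmic Mdm2, binary), Mn (nuclear Mdm2, binary).
#: Mn degrades P; P activates Mc and inhibits Mn; Mc shuttles into Mn.
_P53_TABLE = {
    (0, 0, 0): (2, 0, 1),
    (1, 0, 0): (2, 0, 0),
    (2, 0, 0): (2, 1, 0),
    (0, 1, 0): (2, 0, 1),
    (1, 1, 0): (2, 0, 1),
    (2, 1, 0): (2, 1, 1),
    (0, 0, 1): (0, 0, 1),
    (1, 0, 1): (0, 0, 0),
    (2, 0, 1): (0, 1, 0),
    (0, 1, 1): (0, 0, 1),
    (1, 1, 1): (0, 0, 1),
    (2, 1, 1): (0, 1, 1),
}


def p53_evolution_function() -> EvolutionFunction:
    """The p53-Mdm2 evolution function (radices (3, 2, 2); order P, Mc, Mn)."""
    return EvolutionFunction.from_pairs(
        (3, 2, 2), _P53_TABLE, labels=("P", "Mc", "Mn")
    )


def p53_model() -> Network:
    """The p53-Mdm2 model as a deterministic 12x12 network."""
    return p53_evolution_function().to_network()


# ---------------------------------------------------------------------------
# three-neuron circuit


def _neuron_conditionals(p_burst: float, radix: int) -> list:
    """Per-neuron next-state conditionals for the 3-neuron circuit.

    A neuron fires on the next step iff it is currently silent (state 0;
    otherwise it is refractory) and at least one *other* neuron is active
    (state >= 1).  A firing neuron emits two spikes with probability
    ``p_burst`` (ternary reading); the binary reading merges one and two
    spikes into "firing".
    """
    if not 0.0 <= p_burst <= 1.0:
        raise ValidationError("p_burst must be a probability")
    radices = (radix,) * 3
    S = st.num_states(radices)
    tables = []
    for i in range(3):
        cond = np.zeros((S, radix))
        for h, state in enumerate(st.all_states(radices)):
            refractory = state[i] >= 1
            input_active = any(state[j] >= 1 for j in range(3) if j != i)
            if refractory or not input_active:
                cond[h, 0] = 1.0
            elif radix == 2:
                cond[h, 1] = 1.0
            else:
                cond[h, 1] = 1.0 - p_burst
                cond[h, 2] = p_burst
        tables.append(cond)
    return tables


def ternary_neuron_model(p_burst: float = 0.2) -> Network:
    """Three mutually excitatory neurons with refractoriness; states count
    spikes per time bin (0, 1 or 2)."""
    tables = _neuron_conditionals(p_burst, 3)
    tpm = tpm_from_conditionals(tables, (3, 3, 3))
    return Network(tpm, (3, 3, 3), node_labels=("N1", "N2", "N3"))


def binary_neuron_model(p_burst: float = 0.2) -> Network:
    """Binary reading of the same circuit: firing vs silent.  The burst
    probability drops out (one or two spikes both count as firing)."""
    tables = _neuron_conditionals(p_burst, 2)
    tpm = tpm_from_conditionals(tables, (2, 2, 2))
    return Network(tpm, (2, 2, 2), node_labels=("N1", "N2", "N3"))
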