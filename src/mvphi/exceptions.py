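"""Exception types."""


class ValidationError(ValueError):
    """An input violates a structural invariant (shapes, ranges, stochasticity)."""


class StateUnreachableError(ValidationError):
    """The requested system state has no predecessor under the TPM.

    A state with an all-zero TPM column cannot be the outcome of any
    transition, so its causes are undefined at the system level.  Choose a
    state that actually occurs in the TPM, e.g. the successor listed in one
    of its rows.
    """


class ConditionalIndependenceError(ValidationError):
    """The TPM does not factorize into per-node conditionals."""
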