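"""Analysis configuration.

The defaults fix the analysis variant implemented here: tripartitions at
the mechanism level, the absolute intrinsic difference (AID) as the
repertoire measure, system-level integration evaluated as the sum of
small-phi lost under the minimum system cut, and the assumption that cuts
cannot create new distinctions.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import yaml

from .exceptions import ValidationError


@dataclasses.dataclass(frozen=True)
class RunConfig:
    partition_type: str = "TRI"
    measure: str = "AID"
    phi_difference_for_ces_distance: bool = True
    cuts_cannot_create_new_concepts: bool = True
    #: absolute tolerance for conditional-independence validation
    tolerance: float = 1e-10
    #: optional cap on individual AID terms; ``None`` leaves terms with a
    #: partitioned probability of zero at +inf (full determination destroyed)
    phi_cap: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.partition_type != "TRI":
            raise ValidationError(
                f"unsupported partition_type {self.partition_type!r}; only 'TRI' "
                "tripartitions are implemented (config hook reserved)"
            )
        if self.measure != "AID":
            raise ValidationError(
                f"unsupported measure {self.measure!r}; only 'AID' is implemented"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = RunConfig()
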