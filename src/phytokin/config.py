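"""Run-level configuration shared by the CLI and the pipeline driver."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """All pipeline tunables with their documented defaults.

    n_ler_for_mean: intervals averaged into the per-plant mean LER.
    time_weighted: use total growth over total time instead of the
        arithmetic mean of interval rates.
    interval_in_cm: grid spacing of the fitted cell-length profile.
    bw_multiplier: scaling applied to each computed plug-in bandwidth.
    alternative_bw: final bandwidth (cm) for plants whose selection failed.
    mature_fraction: fraction of the maximum fitted length marking the
        growth-zone end.
    integration_rule: quadrature for the cell-density integral.
    derivative_method: how the profile's first derivative is estimated.
    seed: seed for any simulated input.
    """

    n_ler_for_mean: int = 2
    time_weighted: bool = False
    interval_in_cm: float = 0.1
    bw_multiplier: float = 1.0
    alternative_bw: float = 0.5
    mature_fraction: float = 0.95
    integration_rule: str = "trapezoid"
    derivative_method: str = "finite_difference"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def replace(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI precedence)."""
        kept = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **kept)
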