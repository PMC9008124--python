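"""Randomized parameter fixtures for property testing.

Parameters are drawn log-uniformly within a bracket around the default
values (a factor of 10 each way by default), which preserves the structural
properties -- positivity, the FcRn conservation law, mass-action form --
while exercising widely different timescale separations.
"""

from __future__ import annotations

import numpy as np

from .model import DEFAULT_PARAMETERS, ParameterSet

__all__ = ["generate_fixture"]


def generate_fixture(seed: int, spread: float = 10.0,
                     ranges: dict | None = None) -> ParameterSet:
    """Reproducible pseudo-random parameter set.

    ``spread`` scales the default bracket (each parameter between value/spread
    and value*spread); ``ranges`` overrides the bracket per parameter with
    explicit (lo, hi) pairs.  ``spread=1`` returns the defaults exactly.
    """
    rng = np.random.default_rng(seed)
    values = {}
    for name, default in DEFAULT_PARAMETERS.items():
        if ranges and name in ranges:
            lo, hi = ranges[name]
        else:
            lo, hi = default / spread, default * spread
        if not (0 < lo <= hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        u = rng.uniform(np.log(lo), np.log(hi))
        # degenerate brackets return the endpoint exactly (no exp/log round-trip)
        values[name] = lo if lo == hi else float(np.exp(u))
    return ParameterSet(**values)
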