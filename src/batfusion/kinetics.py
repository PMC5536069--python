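"""Timescale feasibility of a propagated β→α transition for fast exocytosis.

α-helical folding of a ~20-residue motif occurs in the sub-microsecond
range; the check asks whether, even slowed substantially in the membrane
milieu, the transition still completes within the latency of synchronous
synaptic vesicle exocytosis (~50 µs after the Ca²⁺ rise).  Times are in
microseconds.  No helix–coil statistical mechanics or zippering rate model
is attempted — the argument is a bound, not a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["KineticsParams", "FeasibilityResult", "KineticsError",
           "effective_transition_time", "feasibility"]


class KineticsError(ValueError):
    """Raised for non-positive kinetic parameters."""


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the timescale argument (all µs except the factor).

    base_fold_time     : upper bound on the folding time of a ~20-residue
                         helix (1.0 µs encodes "sub-microsecond" conservatively).
    slowdown_factor    : multiplicative penalty for folding inside a
                         membrane rather than in solution.
    exocytosis_latency : time from the Ca²⁺ rise to exocytosis that the
                         transition must fit within.
    """

    base_fold_time: float = 1.0
    slowdown_factor: float = 20.0
    exocytosis_latency: float = 50.0

    def __post_init__(self) -> None:
        for name in ("base_fold_time", "slowdown_factor", "exocytosis_latency"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"{name} must be strictly positive")


class FeasibilityResult(NamedTuple):
    feasible: bool
    margin: float  # latency / effective transition time


def effective_transition_time(params: KineticsParams = KineticsParams()) -> float:
    """Slowed β→α transition time: ``base_fold_time × slowdown_factor`` (µs)."""
    return params.base_fold_time * params.slowdown_factor


def feasibility(params: KineticsParams = KineticsParams()) -> FeasibilityResult:
    """Whether the slowed transition fits within the exocytosis latency.

    Feasible iff ``effective_transition_time <= exocytosis_latency``
    (boundary inclusive); ``margin`` is latency divided by the effective
    time, so margin ≥ 1 ⇔ feasible.
    """
    eff = effective_transition_time(params)
    return FeasibilityResult(
        feasible=eff <= params.exocytosis_latency,
        margin=params.exocytosis_latency / eff,
    )
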