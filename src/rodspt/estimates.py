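"""Closed-form back-of-envelope estimates: filament counts and stoichiometry.

Exact arithmetic; no internal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class FilamentModel:
    """Idealized cytoskeletal filament: two protofilaments, 5 nm repeat."""

    monomers_per_cell: float
    filament_length: float = 0.100   # um
    repeat: float = 0.005            # um per monomer along a protofilament
    protofilaments: int = 2

    @property
    def monomers_per_filament(self) -> float:
        return self.filament_length / self.repeat * self.protofilaments


@dataclass
class StoichiometryModel:
    """RodA : PBP2 stoichiometry under overexpression and CRISPRi depletion."""

    wildtype_ratio: float = 1.35     # RodA : PBP2 in wildtype
    overexpression_fold: float = 3.0
    residual_fraction: float = 0.1   # relative residual expression after repression
    doubling_time: float = 90.0      # min
    bound_fraction: float = 0.19

    def __post_init__(self) -> None:
        if not 0.0 < self.residual_fraction <= 1.0:
            raise ValueError("residual fraction must lie in (0, 1]")
        if min(self.wildtype_ratio, self.overexpression_fold,
               self.doubling_time) <= 0:
            raise ValueError("model quantities must be positive")


def filament_count(model: FilamentModel) -> float:
    """Number of filaments per cell = monomers per cell / monomers per filament."""
    if model.repeat <= 0:
        raise ValueError("repeat length must be positive")
    return model.monomers_per_cell / model.monomers_per_filament


def roda_depletion_ratio(model: StoichiometryModel, t: float):
    """RodA:PBP2 ratio at time t after repression, and the per-bound ratio.

    The initial ratio is wildtype_ratio / overexpression_fold; repression
    dilutes it as ``(1 - f) 2^(-t / t_d) + f`` towards the residual floor f.
    The per-bound-enzyme ratio divides by the bound fraction b.

    Returns ``(ratio, ratio_per_bound)``.
    """
    if model.bound_fraction <= 0:
        raise ValueError("bound fraction must be positive")
    ratio0 = model.wildtype_ratio / model.overexpression_fold
    decay = ((1.0 - model.residual_fraction)
             * 2.0 ** (-t / model.doubling_time) + model.residual_fraction)
    ratio = ratio0 * decay
    return ratio, ratio / model.bound_fraction


def steady_state_per_bound_ratio(ratio: float, bound_fraction: float) -> float:
    """Per-bound-enzyme ratio from a measured number ratio and bound fraction."""
    if bound_fraction <= 0:
        raise ValueError("bound fraction must be positive")
    return ratio / bound_fraction
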