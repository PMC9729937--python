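"""Two-population growth under single or fractionated chemotherapy.

Chemosensitive (``N_s``) and chemoresistant (``N_r``) cells grow
exponentially over one scaled treatment interval (t = 1).  A single dose x
multiplies the sensitive population by its Hill viability V(x); resistant
cells are unaffected by drug at the doses modelled.  Splitting the same
cumulative dose x into n equal administrations within the same interval
gives the closed form

    N_s' = V(x/n)^n * e^{a_s} * N_s        N_r' = e^{a_r} * N_r

Growth is applied once per full interval.  Note that compounding growth per
sub-interval, (V(x/n) * e^{a_s/n})^n, is algebraically identical, so the
closed form is not an approximation of interleaving.  Populations are
real-valued and deterministic (no demographic noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dose_response import HillParams, viability

__all__ = [
    "GrowthParams",
    "PopulationState",
    "DosingRegimen",
    "EmptyPopulationError",
    "apply_single_dose",
    "simulate_regimen",
    "fraction_resistant",
]

#: Default ratio of resistant to sensitive growth rate (resistant clones
#: grow at ~20% of the sensitive rate, as measured from colony expansion).
DEFAULT_RESISTANT_GROWTH_RATIO = 0.2


class EmptyPopulationError(ValueError):
    """Raised when a fraction is requested of an empty population."""


@dataclass(frozen=True)
class GrowthParams:
    """Log-growth increments per unit (scaled) interval for each population."""

    a_sensitive: float
    a_resistant: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a_sensitive) and math.isfinite(self.a_resistant)):
            raise ValueError("growth rates must be finite")

    @classmethod
    def from_ratio(
        cls, a_sensitive: float, resistant_ratio: float = DEFAULT_RESISTANT_GROWTH_RATIO
    ) -> "GrowthParams":
        """Resistant rate as a fraction of the sensitive rate (default 0.2)."""
        return cls(a_sensitive=a_sensitive, a_resistant=resistant_ratio * a_sensitive)


@dataclass(frozen=True)
class PopulationState:
    """Sensitive and resistant cell counts (real-valued, non-negative)."""

    n_sensitive: float
    n_resistant: float

    def __post_init__(self) -> None:
        if self.n_sensitive < 0 or self.n_resistant < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def total(self) -> float:
        return self.n_sensitive + self.n_resistant


@dataclass(frozen=True)
class DosingRegimen:
    """A cumulative dose split into n equal administrations in one interval.

    The total treatment interval is the same regardless of ``n_doses``; only
    the per-administration dose (``cumulative_dose / n_doses``) changes.
    """

    cumulative_dose: float
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.cumulative_dose < 0:
            raise ValueError("cumulative dose must be >= 0")
        if int(self.n_doses) != self.n_doses or self.n_doses < 1:
            raise ValueError("n_doses must be an integer >= 1")

    @property
    def per_dose(self) -> float:
        return self.cumulative_dose / self.n_doses


def apply_single_dose(
    state: PopulationState,
    dose: float,
    growth: GrowthParams,
    curve: HillParams,
) -> PopulationState:
    """One interval of growth with a single dose: N_s' = V(x) e^{a_s} N_s."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return PopulationState(
        n_sensitive=viability(dose, curve)
        * math.exp(growth.a_sensitive)
        * state.n_sensitive,
        n_resistant=math.exp(growth.a_resistant) * state.n_resistant,
    )


def simulate_regimen(
    state: PopulationState,
    regimen: DosingRegimen,
    growth: GrowthParams,
    curve: HillParams,
    repeats: int = 1,
) -> PopulationState:
    """Apply a fractionated regimen over one interval (closed form).

    N_s' = V(x/n)^n * e^{a_s} * N_s and N_r' = e^{a_r} * N_r, reducing to
    :func:`apply_single_dose` at n = 1.  ``repeats`` composes the
    one-interval regimen over several consecutive intervals.
    """
    if int(repeats) != repeats or repeats < 1:
        raise ValueError("repeats must be an integer >= 1")
    surv = viability(regimen.per_dose, curve) ** regimen.n_doses
    for _ in range(int(repeats)):
        state = PopulationState(
            n_sensitive=surv * math.exp(growth.a_sensitive) * state.n_sensitive,
            n_resistant=math.exp(growth.a_resistant) * state.n_resistant,
        )
    return state


def fraction_resistant(state: PopulationState) -> float:
    """Resistant share N_r / (N_s + N_r) of a non-empty population."""
    if state.total <= 0:
        raise EmptyPopulationError("fraction undefined for empty population")
    return state.n_resistant / state.total
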