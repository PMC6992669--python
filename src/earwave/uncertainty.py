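"""Error budget for the dosimetric/thermal chain.

The budget combines symmetric fractional SDs of the independent inputs
(literature permittivities, the temperature adjustment, thermal
properties, meshing) by root-sum-square, and then adds the asymmetric
SAR bounds obtained from permittivity-perturbation reruns of the
solver.  SAR and temperature scale with the *square* of the field, so
a field change ``g`` maps to a power change ``(1+g)^2 - 1`` before
entering the budget.  The asymmetric part is added linearly per side
(a deliberate, conservative choice: the perturbation bounds are
worst-case excursions rather than independent SDs, so quadrature would
understate them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import InvalidInputError

#: default symmetric components, as (name, fractional SD)
DEFAULT_COMPONENTS = (
    ("permittivity_literature", 0.08),
    ("temperature_adjustment", 0.02),
    ("thermal_properties", 0.05),
    ("fdtd_meshing", 0.03),
)


@dataclass(frozen=True)
class ErrorBudget:
    """Symmetric fractional SDs plus asymmetric field-perturbation bounds.

    ``field_perturbation`` is the (positive, negative) fractional change
    of the computed field under the permittivity perturbations (e.g.
    (+0.055, -0.221)); it is squared into power terms when combined.
    """

    components: tuple[tuple[str, float], ...] = DEFAULT_COMPONENTS
    field_perturbation: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.components and self.field_perturbation is None:
            raise InvalidInputError("budget needs at least one component")
        for name, frac in self.components:
            if frac < 0:
                raise InvalidInputError(f"component {name!r} has negative SD")


def square_for_power(field_change: float) -> float:
    """Map a fractional field change to a fractional power/SAR change.

    power_change = (1 + field_change)^2 - 1; requires field_change > -1.
    """
    if field_change <= -1.0:
        raise InvalidInputError("field change must be > -1")
    return (1.0 + field_change) ** 2 - 1.0


def combine_budget(budget: ErrorBudget) -> tuple[float, float]:
    """Total (positive, negative) fractional bounds of the budget.

    Root-sum-square of the symmetric components, plus the squared
    field-perturbation bounds added linearly per side.  Returns
    (positive_total, negative_total) with the negative total <= 0.
    Monotone: adding a component never shrinks either bound.
    """
    rss = math.sqrt(sum(frac**2 for _, frac in budget.components))
    pos, neg = rss, -rss
    if budget.field_perturbation is not None:
        fp_pos, fp_neg = budget.field_perturbation
        pos += abs(square_for_power(fp_pos))
        neg -= abs(square_for_power(fp_neg))
    return pos, neg


def perturbation_harness(
    scenario: Callable[[float, float], float],
    fraction: float = 0.10,
) -> tuple[float, float]:
    """Field-change fractions under +/- permittivity perturbations.

    ``scenario(scale_real, scale_imag)`` must rerun the exposure with
    eps' and eps'' multiplied by the given factors and return the peak
    |E| at the observation sensor.  Returns the fractional field
    changes (positive_perturbation, negative_perturbation) relative to
    the unperturbed run; a zero perturbation returns exactly (0, 0)
    because the solver is deterministic.
    """
    if fraction < 0:
        raise InvalidInputError("fraction must be >= 0")
    base = scenario(1.0, 1.0)
    if base <= 0:
        raise InvalidInputError("unperturbed scenario returned a non-positive field")
    up = scenario(1.0 + fraction, 1.0 + fraction)
    down = scenario(1.0 - fraction, 1.0 - fraction)
    return (up - base) / base, (down - base) / base
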