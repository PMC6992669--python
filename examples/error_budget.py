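"""Uncertainty budget of the dosimetric/thermal chain.

Reruns the 1-D membrane exposure with the tissue permittivities scaled
by +/-10 %, squares the resulting field changes into SAR/thermal
bounds, and combines them with the symmetric input uncertainties
(literature permittivities 8 %, temperature adjustment 2 %, thermal
properties 5 %, meshing 3 %) into asymmetric totals.
"""

from earwave.fixtures import stack_field_scenario
from earwave.uncertainty import (
    ErrorBudget,
    combine_budget,
    perturbation_harness,
    square_for_power,
)

scenario = stack_field_scenario(90e9)
up, down = perturbation_harness(scenario, fraction=0.10)
print(f"membrane |E| change at +10 % permittivity: {100*up:+.1f} %")
print(f"membrane |E| change at -10 % permittivity: {100*down:+.1f} %")

pos_field, neg_field = max(up, down), min(up, down)
print(f"squared into SAR: {100*square_for_power(pos_field):+.1f} % / "
      f"{100*square_for_power(neg_field):+.1f} %")

budget = ErrorBudget(field_perturbation=(pos_field, neg_field))
pos, neg = combine_budget(budget)
print(f"\ntotal temperature-rise bounds: {100*pos:+.0f} % / {100*neg:+.0f} %")
print("(symmetric inputs combined by root-sum-square, the asymmetric "
      "field-perturbation bounds added per side)")
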