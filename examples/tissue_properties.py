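"""Derived EM properties of the ear tissues across the 30-90 GHz band.

Loads the 37 degC tissue permittivity table and prints, per tissue and
band frequency, the equivalent conductivity sigma = eps0*eps''*2*pi*f,
the complex refractive index (n, kappa), the 1/e field penetration
depth delta = c/(omega*kappa) and the power absorption coefficient
alpha = 2/delta.  Note how the stratum-corneum index falls and the
fibrous-tissue absorption rises with frequency: together they let more
of a higher-frequency pulse enter the canal and deposit in the eardrum.
"""

from earwave.dielectrics import derived_properties, load_tissue_table

table = load_tissue_table()
print(f"{'tissue':<18}{'f/GHz':>6}{'sigma S/m':>11}{'n':>7}{'kappa':>7}"
      f"{'delta/mm':>10}{'alpha 1/m':>11}")
for tissue in table.tissues:
    for f in table.frequencies:
        p = derived_properties(table.get(tissue, f))
        print(f"{tissue:<18}{f/1e9:>6.0f}{p.conductivity:>11.1f}{p.n_real:>7.2f}"
              f"{p.kappa:>7.2f}{p.delta_field*1e3:>10.3f}{p.alpha_power:>11.0f}")
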