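"""Closed-form ear-canal analytics: waveguide cutoff and diffraction.

The canal behaves as a lossy elliptical waveguide: below the TE11
cutoff f = 1.841*c/(2*pi*a) of its narrowest radius no mode
propagates.  The entrance also diffracts the incident beam; the width
of the first-order minimum at the membrane, Y = lambda*D/(2*R), shows
how much wider than the canal the central diffraction lobe is — the
dominant loss mechanism at 30 GHz.
"""

from scipy.constants import c as C0

from earwave.phantom import diffraction_first_minimum, waveguide_cutoff

a_horizontal = 3.5e-3  # narrowest canal radius, m
depth = 25e-3  # canal depth to the membrane, m

cutoff = waveguide_cutoff(a_horizontal)
print(f"TE11 cutoff for a = {a_horizontal*1e3:.1f} mm: {cutoff/1e9:.1f} GHz")
print("-> the whole 30-90 GHz band propagates down the canal\n")

for f in (30e9, 60e9, 90e9):
    lam = C0 / f
    y = diffraction_first_minimum(lam, depth, a_horizontal)
    print(f"{f/1e9:.0f} GHz (lambda {lam*1e3:.1f} mm): first diffraction minimum "
          f"width at the membrane {y*1e3:.1f} mm")
print("\nThe lobe shrinks toward the canal size as frequency rises, so less"
      "\nenergy is diffracted away from the canal mouth at 60-90 GHz.")
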