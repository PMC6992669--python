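parameter,value,description
eps_static_a0,87.740,Static permittivity polynomial in T/degC (Malmberg & Maryott 1956)
eps_static_a1,-0.40008,Linear coefficient of static permittivity polynomial
eps_static_a2,9.398e-4,Quadratic coefficient of static permittivity polynomial
eps_static_a3,-1.410e-6,Cubic coefficient of static permittivity polynomial
eps_inf_b0,5.77,High-frequency permittivity limit at 0 degC (Kaatze 1989)
eps_inf_b1,-0.0274,Linear temperature coefficient of the high-frequency limit per degC
tau_prefactor_s,3.745e-15,Relaxation-time Arrhenius prefactor in seconds (Kaatze 1989)
tau_activation_k,2295.7,Relaxation-time activation temperature in kelvin
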