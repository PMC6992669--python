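tissue,density_kg_m3,heat_capacity_j_kg_k,thermal_conductivity_w_m_c,blood_flow_m3_kg_s
stratum_corneum,1300,1800,0.4,0
epidermis,1060,3600,0.6,0
fibrous_tissue,1151,3000,0.6,6.3e-8
mucous_membrane,1125,3150,0.51,2.0e-7
blood,1057,3600,0.52,0
air,1.13,1005,0.0026,0
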