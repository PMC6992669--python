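tissue,frequency_ghz,eps_real,eps_imag
bone_cartilage,30,5.5,1.4
dermis,30,19.0,16.0
epidermis,30,16.0,12.5
stratum_corneum,30,10.0,6.0
fibrous_tissue,30,18.0,18.5
mucous_membrane,30,31.0,30.6
bone_cartilage,60,4.0,1.2
dermis,60,10.0,11.0
epidermis,60,10.0,10.0
stratum_corneum,60,5.0,4.0
fibrous_tissue,60,10.0,15.0
mucous_membrane,60,11.5,20.0
bone_cartilage,90,3.2,1.0
dermis,90,6.0,8.0
epidermis,90,5.5,6.0
stratum_corneum,90,3.4,3.0
fibrous_tissue,90,7.0,13.0
mucous_membrane,90,8.0,15.0
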