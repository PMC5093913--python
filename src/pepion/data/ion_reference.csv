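ion,shannon_radius_pm,hydration_enthalpy_kJ_mol,ld50_low_mg_kg,ld50_high_mg_kg,citation
Ca,100,-1592.4,2301,2301,"radius/enthalpy/LD50 as quoted in source paper"
Sr,118,-1445.0,1253,1253,"LD50 as quoted in source paper; radius/enthalpy supplemented from standard Shannon (1976) and Smith (1977) tabulations"
Ba,135,-1304.0,100,300,"LD50 range as quoted in source paper; radius/enthalpy supplemented from standard Shannon (1976) and Smith (1977) tabulations"
Cd,95,-1806.0,107,107,"LD50 as quoted in source paper; radius/enthalpy supplemented from standard Shannon (1976) and Smith (1977) tabulations"
Pb,98,-1479.9,1947,1947,"radius/enthalpy/LD50 as quoted in source paper (printed octahedral radius 98 pm)"
Hg,102,-1824.0,47,47,"LD50 as quoted in source paper; radius/enthalpy supplemented from standard Shannon (1976) and Smith (1977) tabulations"
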