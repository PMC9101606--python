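element,kind,value,nominal_units,source
Pb,PTWI,25,ug/kg bw/week,JECFA provisional tolerable weekly intake
Cd,TWI,2.5,ug/kg bw/week,EFSA tolerable weekly intake
As,PTWI,3.0,ug/kg bw/week,JECFA provisional tolerable weekly intake (total As)
Hg,TWI,4,ug/kg bw/week,EFSA tolerable weekly intake (inorganic Hg)
Cr,PTWI,0.7,mg/kg bw/week,provisional tolerable weekly intake
Fe,PMTWI,5.6,mg/kg bw/week,from PMTDI 0.8 mg/kg bw/day
Co,MTWI,700,ug/kg bw/week,from MTDI 100 ug/kg bw/day
Ni,TWI,19.6,ug/kg bw/week,from TDI 2.8 ug/kg bw/day
Cu,PTWI,3.5,mg/kg bw/week,from PMTDI 0.5 mg/kg bw/day
Zn,PMTWI,7,mg/kg bw/week,from PMTDI 1 mg/kg bw/day
Se,PTWI,66,ug/kg bw/week,provisional tolerable weekly intake
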