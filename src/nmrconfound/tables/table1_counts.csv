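center,PHT,PA,PPGL,CS
FRPA1,17,40,26,0
FRPA2,0,0,0,11
GBGL2,49,0,0,0
GYDR,20,8,19,1
GYLU,0,0,1,0
GYMU,0,0,4,0
GYWU,0,0,1,0
IRGA,0,0,0,3
ITPD,0,2,4,14
ITPD3,0,8,0,1
ITTU3,20,46,2,3
NLNI,0,0,6,0
PLWW,0,0,31,0
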