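metabolite,ppm,Initial,A,B,C
Alanine,1.457,-0.19975,-0.07187,0,0
Creatine,3.917,0,0,,0.019157
Creatinine,4.041,0,0,0.177419,0
Dimethyl sulfone,3.137,0,0,,0.109629
Dimethylamine,2.695,0,0,-0.03439,0
Dimethylglycine,2.91,0,0,0.04487,0.027703
Formate,8.441,-0.01988,-0.01755,0.023133,0
Glutamine,2.433,0.148614,0.135957,,0
Glutamate,2.325,-0.12554,-0.14981,,0
Glucose,5.220,0.039396,0.0097,,0.147391
Glycine,3.548,-0.0108,0,,0
Glycerol,3.555,0,0,,0.091654
Lactate,4.108,0.025885,0,,-0.08734
Lysine,2.997,0,0,0.03347,0
Methionine,2.122,0.052659,0.02404,,0
Methanol,3.346,0.062726,0.050343,,0.04658
Proline,1.996,-0.02291,-0.00628,-0.13954,-0.01636
Pyruvate,2.356,0.312859,0.32791,,0.197295
Threonine,4.240,0,0,0.040696,0
Tyrosine,7.168,0,0,-0.0194,0
Valine,0.981,0,0,0,-0.00058
Unknown 3.162,3.162,0.009448,0.017788,0.236056,0
Unknown 3.262,3.262,0,0,-0.15528,-0.05692
Unknown 3.284,3.284,-0.03909,-0.02878,,0
Unknown 3.612,3.612,0,0,-0.11482,0
Unknown 3.670,3.670,0,0,-0.12957,0
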