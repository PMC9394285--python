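metabolite,ppm_peaks,reasons,direction
Acetylcarnitine,3.177,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,down
Creatine,3.021;3.917,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
Dimethyl sulfone,3.137,PLSDA_SAMPLE_AGE,up
Glucose,5.220;5.227,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,down
Glutamate,2.047;2.060;2.075;2.095;2.103;2.108;2.113;2.122;2.132;2.140;2.145;2.325;2.332;2.341;2.356,FRPA1_PHT;PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
Glutamine,2.095;2.103;2.108;2.113;2.122;2.132;2.140;2.145;2.418;2.428;2.433;2.444;2.449;2.460,FRPA1_PHT;PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,down
Glycerol,3.555;3.567,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
Glycine,3.548,PLSDA_SAMPLE_AGE,down
Lactate,1.321;1.307;4.080;4.094;4.108;4.121,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
Methanol,3.346,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,down
Methionine,2.122,FRPA1_PHT;PLSDA_SAMPLE_AGE,down
Ornithine,3.041;3.057,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
Pyruvate,2.356,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,down
Unknown 3.284,3.284,PLSDA_CLUSTER;PLSDA_SAMPLE_AGE,up
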