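name,x,y,z
Fp1,-0.029437,0.083917,-0.006990
Fpz,0.000112,0.088247,-0.001713
Fp2,0.029872,0.084896,-0.007080
F7,-0.070263,0.042474,-0.011420
F3,-0.050244,0.053111,0.042192
Fz,0.000312,0.058512,0.066462
F4,0.051836,0.054305,0.040814
F8,0.073043,0.044422,-0.012000
FC5,-0.077215,0.018643,0.024460
FC1,-0.034062,0.026011,0.079987
FC2,0.034784,0.026438,0.078808
FC6,0.079534,0.019936,0.024438
T7,-0.084161,-0.016019,-0.009346
C3,-0.065358,-0.011632,0.064358
Cz,0.000401,-0.009167,0.100244
C4,0.067118,-0.010900,0.063580
T8,0.085080,-0.015020,-0.009490
CP5,-0.079592,-0.046551,0.030949
CP1,-0.035513,-0.047292,0.091315
CP2,0.038384,-0.047073,0.090695
CP6,0.083322,-0.046101,0.031206
P7,-0.072434,-0.073453,-0.002487
P3,-0.053007,-0.078788,0.055940
Pz,0.000325,-0.081115,0.082615
P4,0.055667,-0.078560,0.056561
P8,0.073056,-0.073068,-0.002540
POz,0.000216,-0.102178,0.050608
O1,-0.029413,-0.112449,0.008839
Oz,0.000108,-0.114892,0.014657
O2,0.029843,-0.112156,0.008800
AF7,-0.054840,0.068572,-0.010590
AF3,-0.033701,0.076837,0.021227
AF4,0.035712,0.077726,0.021956
AF8,0.055743,0.069657,-0.010755
F5,-0.064466,0.048035,0.016921
F1,-0.027496,0.056931,0.060342
F2,0.029514,0.057602,0.059540
F6,0.067914,0.049830,0.016367
FC3,-0.060182,0.022716,0.055544
FCz,0.000376,0.027390,0.088668
FC4,0.062293,0.023723,0.055630
C5,-0.080280,-0.013760,0.029160
C1,-0.036158,-0.009984,0.089752
C2,0.037672,-0.009624,0.088412
C6,0.083456,-0.012776,0.029208
CP3,-0.063556,-0.047009,0.065624
CP4,0.066612,-0.046637,0.065580
P5,-0.067272,-0.076291,0.028382
P1,-0.028620,-0.080525,0.075436
P2,0.031920,-0.080487,0.076716
P6,0.067888,-0.075904,0.028091
PO5,-0.048424,-0.099341,0.021599
PO3,-0.036511,-0.100853,0.037167
PO4,0.036782,-0.100849,0.036397
PO6,0.049820,-0.099446,0.021727
FT7,-0.080775,0.014120,-0.011135
FT8,0.081815,0.015417,-0.011330
TP7,-0.084830,-0.046022,-0.007056
TP8,0.085549,-0.045545,-0.007130
PO7,-0.054840,-0.097528,0.002792
PO8,0.055667,-0.097625,0.002730
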