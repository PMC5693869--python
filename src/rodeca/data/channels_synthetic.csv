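# synthetic stand-in fixture (not measured data): 18-channel metadata emulating a 12-excitation x 3-filter autofluorescence microscope
index,ex_nm,bandwidth_nm,filter_id,qe,f
1,334.0,10.0,A450,0.4,0.417443
2,365.0,10.0,A450,0.4155,0.440082
3,375.0,10.0,A450,0.4205,0.368774
4,385.0,10.0,A450,0.4255,0.291771
5,395.0,10.0,A450,0.4305,0.230144
6,405.0,10.0,A450,0.4355,0.194764
7,405.0,10.0,B520,0.4505,0.537684
8,415.0,10.0,B520,0.4555,0.679011
9,435.0,10.0,B520,0.4655,0.936325
10,455.0,10.0,B520,0.4755,1.0
11,475.0,10.0,B520,0.4855,0.812081
12,495.0,10.0,B520,0.4955,0.500094
13,405.0,10.0,C587,0.4655,0.231516
14,425.0,10.0,C587,0.4755,0.373569
15,435.0,10.0,C587,0.4805,0.428768
16,455.0,10.0,C587,0.4905,0.459356
17,475.0,10.0,C587,0.5005,0.373169
18,495.0,10.0,C587,0.5105,0.229812
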