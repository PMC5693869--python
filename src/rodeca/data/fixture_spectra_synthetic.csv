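# synthetic stand-in fixture (not measured data): normalized fluorophore channel spectra with qualitative shapes of common cellular fluorophores
index,free NADH,bound NADH,FAD,porphyrin,Cyt c,lipofuscin
1,1.0,0.837429,0.000165,0.0,0.010036,0.060362
2,0.836998,1.0,0.003047,0.0,0.155865,0.115642
3,0.608468,0.855484,0.00647,0.0,0.28502,0.13473
4,0.389364,0.659527,0.012532,0.0,0.454387,0.152669
5,0.219321,0.458206,0.022145,0.0,0.631544,0.168258
6,0.108745,0.286878,0.035699,0.0,0.765257,0.180358
7,0.035661,0.034903,0.364182,0.00122,0.946608,0.774144
8,0.015564,0.019693,0.535569,0.001092,1.0,0.807081
9,0.002022,0.004588,0.879362,0.000381,0.739498,0.807081
10,0.000158,0.000705,1.0,4.4e-05,0.315921,0.722208
11,7e-06,7.1e-05,0.787611,2e-06,0.077969,0.578299
12,0.0,5e-06,0.429638,0.0,0.011117,0.414369
13,0.000511,0.000135,0.097453,1.0,0.158297,0.945959
14,8.6e-05,3.9e-05,0.192268,0.607371,0.154013,1.0
15,2.9e-05,1.8e-05,0.235311,0.312411,0.123663,0.986207
16,2e-06,3e-06,0.267593,0.036005,0.05283,0.882497
17,0.0,0.0,0.210759,0.00137,0.013038,0.706648
18,0.0,0.0,0.114968,1.7e-05,0.001859,0.506336
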