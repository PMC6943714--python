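peptide_id,scan,kd_mdm2_nM,ddg_mdm2,kd_mdmx_nM,ddg_mdmx,escore_ddg,yscore_ddg,boltzmann_ddg
WT,wt,18.6,,12.5,,,,
L1A,ala,19.3,0.03,9.6,-0.16,0.2,-0.30,1.2
T2A,ala,155.3,1.73,,,-0.2,-0.91,1.3
F3A,ala,9585.9,5.09,4873,3.53,1.8,27.28,7.8
E5A,ala,29.8,0.38,45.6,0.75,0.0,1.81,-1.4
Y6A,ala,51.5,0.83,130.3,1.37,0.7,9.42,0.4
W7A,ala,5145.9,4.58,11161,4.02,3.8,36.41,11.6
Q8A,ala,32.6,0.46,57.1,0.88,0.3,1.71,-1.0
L9A,ala,15.8,-0.13,13.4,0.00,0.2,0.42,-0.7
Cba10A,ala,413.7,2.53,94.7,1.18,0.8,10.74,7.1
S12A,ala,20.4,0.08,43.9,0.73,0.2,-2.29,1.3
L1dL,d,27.5,0.23,21.8,0.31,0.0,-1.90,-1.3
T2dT,d,217.8,1.46,,,0.3,-2.24,-2.6
F3dF,d,6385.1,3.47,7397,3.77,-0.2,-4.04,5.7
E5dE,d,36.8,0.41,,,-0.5,-2.44,1.5
Y6dY,d,365.1,1.77,921.2,2.53,0.7,5.91,0.7
W7dW,d,32.9,0.34,63.4,0.94,0.2,-1.73,2.2
Q8dQ,d,26.5,0.20,36.6,0.62,0.2,-0.93,2.3
L9dL,d,32.2,0.32,38.8,0.65,0.0,-1.08,-2.5
Cba10dCba,d,3809.5,3.17,805.1,2.45,1.3,8.21,3.5
S12dS,d,10.7,-0.31,36.9,0.62,-0.5,-2.45,0.1
A13dA,d,17.2,-0.05,34.9,0.59,0.3,-0.69,0.0
A14dA,d,18.4,-0.02,4.9,-0.57,-0.3,4.31,-1.9
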