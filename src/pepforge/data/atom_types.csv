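type,rmin_half,epsilon,dg_ref,volume,lambda
CT,1.908,0.1094,0.52,23.7,3.5
CA_AROM,1.908,0.086,0.08,18.4,3.5
C,1.908,0.086,0.0,14.7,3.5
N,1.824,0.17,-5.95,4.4,3.5
N2,1.824,0.17,-10.0,11.2,6.0
N3,1.824,0.17,-20.0,11.2,6.0
O,1.661,0.21,-5.33,10.8,3.5
OH,1.721,0.2104,-5.92,10.8,3.5
O2,1.661,0.21,-10.0,10.8,6.0
S,2.0,0.25,-3.24,14.7,3.5
H,0.6,0.0157,0.0,0.0,3.5
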