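pdb_id,description,n_aa,n_nonstandard,min_rmsd,cluster_size,best25,best100,best500
1ycr,L-alpha-helix (p53 17-29),13,0,1.29,9547,2.9,2.2,2.1
2axi,N-C cyclic beta-hairpin,10,1,0.77,744,1.4,1.3,1.3
2gv2,L-alpha-helix,8,4,1.17,3595,1.9,1.4,1.4
3eqs,L-alpha-helix,11,0,0.75,11112,1.7,1.7,1.4
3g03,L-alpha-helix,11,0,0.94,9175,2.5,2.1,1.4
3iux,Stingin-2 disulfide bonds,18,0,1.34,4721,2.3,2.2,1.7
3iwy,D-alpha-helix,12,12,0.95,8074,2.1,1.8,1.5
3jzo,L-alpha-helix,12,0,1.02,7743,2.6,2.2,1.3
3jzs,L-alpha-helix,12,0,0.92,5368,2.6,2.6,1.5
3lnj,D-alpha-helix,11,11,0.88,3091,2.8,1.5,1.0
3tpx,D-alpha-helix,11,11,0.88,4784,2.4,1.7,1.1
3v3b,Stapled alpha-helix,13,2,1.40,3674,2.5,2.3,1.8
4n5t,Stapled alpha-helix,14,3,1.44,4310,2.6,2.0,1.5
4ud7,Stapled alpha-helix,14,2,1.32,6484,3.2,2.5,1.5
4umn,Stapled alpha-helix,11,2,1.54,3201,2.2,1.9,1.7
5afg,Stapled alpha-helix,12,2,1.36,4354,2.4,1.5,1.5
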