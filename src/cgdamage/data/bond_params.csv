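pair_type,r_e_angstrom,d_e_ev,bond_order
C-C,1.54,3.61,single
C-O,1.43,3.73,single
O-O,1.48,1.50,single
P-O,1.64,3.47,single
P=O,1.50,5.64,double
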