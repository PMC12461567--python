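site,d_rsb_angstrom,d_beta_angstrom,five_site_rule,consensus_residue
152,9.9,9.6,N,F
155,15.4,10.0,N,T
158,18.1,9.9,N,I
197,16.4,9.8,Y,A
302,12.3,3.2,Y,F
310,12.1,2.5,Y,S
311,16.6,8.7,N,T
329,9.4,16.4,N,N
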