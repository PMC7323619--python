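substrate_id,mechanism,h_label,rel_gibbs_kcal,pd_c_angstrom,stable,group_offset_kcal
t2e1,PA,H1,0.0,2.1,1,0.0
t2e1,SEAR,H1,0.0,2.1,1,-7.0
t2e2,PA,H1,0.0,2.1,1,0.0
t2e2,SEAR,H1,0.0,2.1,1,-7.0
t2e2,SEAR,H2,0.5,2.1,1,-7.0
t2e3,PA,H1,0.0,2.1,1,0.0
t2e3,PA,H2,0.7,2.1,1,0.0
t2e3,SEAR,H2,0.0,2.1,1,3.0
t2e3,SEAR,H3,0.9,2.1,1,3.0
t2e4,PA,H1,1.9,2.1,1,0.0
t2e4,PA,H5,9.8,2.1,1,0.0
t2e4,PA,H6,0.0,2.1,1,0.0
t2e4,SEAR,H1,0.0,2.1,1,3.0
t2e4,SEAR,H2,3.9,2.1,1,3.0
t2e4,SEAR,H3,2.9,2.1,1,3.0
t2e4,SEAR,H4,2.9,2.1,1,3.0
t2e4,SEAR,H5,4.2,2.1,1,3.0
t2e5,PA,H1,0.0,2.1,1,0.0
t2e5,PA,H2,2.7,2.1,1,0.0
t2e5,PA,H3,9.7,2.1,1,0.0
t2e5,PA,H4,6.2,2.1,1,0.0
t2e5,SEAR,H1,0.0,9.99,0,0.0
t2e5,SEAR,H2,0.0,9.99,0,0.0
t2e5,SEAR,H3,0.0,9.99,0,0.0
t2e5,SEAR,H4,0.0,9.99,0,0.0
t2e6,PA,H1,0.2,2.1,1,0.0
t2e6,PA,H2,0.0,2.1,1,0.0
t2e6,PA,H3,0.3,2.1,1,0.0
t2e6,PA,H4,0.9,2.1,1,0.0
t2e6,PA,H5,2.6,2.1,1,0.0
t2e6,SEAR,H2,0.0,2.1,1,-2.5
t2e6,SEAR,H3,2.7,2.1,1,-2.5
t2e7,PA,H1,0.0,2.1,1,0.0
t2e7,PA,H2,2.8,2.1,1,0.0
t2e7,PA,H3,10.0,2.1,1,0.0
t2e7,SEAR,H1,0.0,9.99,0,0.0
t2e7,SEAR,H2,0.0,9.99,0,0.0
t2e7,SEAR,H3,0.0,9.99,0,0.0
t2e8,PA,H1,0.0,2.1,1,0.0
t2e8,PA,H2,0.8,2.1,1,0.0
t2e8,PA,H3,5.5,2.1,1,0.0
t2e8,PA,H4,4.3,2.1,1,0.0
t2e8,PA,H5,6.0,2.1,1,0.0
t2e8,SEAR,H1,0.1,2.1,1,3.0
t2e8,SEAR,H2,0.0,2.1,1,3.0
t2e8,SEAR,H3,14.9,2.1,1,3.0
t2e8,SEAR,H4,15.0,2.1,1,3.0
t2e8,SEAR,H5,15.8,2.1,1,3.0
t3e1,PA,H1,0.0,2.3005,1,0.0
t3e1,SEAR,H1,0.0,2.3005,1,-3.0777
t3e2,PA,H1,0.0,2.3778,1,0.0
t3e2,SEAR,H1,0.0,2.3778,1,1.6369
t3e2,SEAR,H2,26.0,2.3778,1,1.6369
t3e2,SEAR,H3,27.5,2.3778,1,1.6369
t3e3,PA,H1,0.0,2.1345,1,0.0
t3e3,PA,H2,1.9,2.1345,1,0.0
t3e3,PA,H3,7.6,2.1345,1,0.0
t3e3,SEAR,H1,0.0,2.1345,1,-1.4558
t3e3,SEAR,H2,3.2,2.1345,1,-1.4558
t3e4,PA,H1,0.0,2.1,1,0.0
t3e4,SEAR,H1,0.0,9.99,0,0.0
t3e6,PA,H1,0.0,2.168,1,0.0
t3e6,PA,H2,2.6,2.168,1,0.0
t3e6,PA,H3,2.2,2.168,1,0.0
t3e6,PA,H4,2.5,2.168,1,0.0
t3e6,PA,H5,2.2,2.168,1,0.0
t3e6,PA,H6,2.8,2.168,1,0.0
t3e6,SEAR,H1,0.0,2.168,1,21.9298
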