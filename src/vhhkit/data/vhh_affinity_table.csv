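variant_id,kd_nm,kon,koff,emax_nm,r2,yield_mg_per_l,sec_purity_pct
VHH1-v1.0,0.2,1.1E+06,2.7E-04,0.13,0.99,66.5,87.2
VHH1-v1.1,0.3,1.0E+06,2.9E-04,0.13,0.99,58.8,89.5
VHH1-v1.2,0.3,1.1E+06,3.2E-04,0.12,1.00,41.9,85.3
VHH1-v1.3,1.1,8.8E+05,9.4E-04,0.12,0.99,38.3,85.4
VHH1-v1.4,0.5,1.1E+06,6.2E-04,0.12,0.99,86.3,76.8
VHH1-v1.5,0.9,1.1E+06,9.7E-04,0.10,0.98,87.3,73.0
VHH1-v1.6,0.8,1.1E+06,8.7E-04,0.14,0.99,74.1,63.8
VHH1-v1.7,0.5,1.0E+06,5.5E-04,0.09,0.99,80.7,65.0
VHH1-v1.8,1.1,1.1E+06,1.3E-03,0.10,0.99,70.0,73.0
VHH1-v1.9,1.1,8.7E+05,9.3E-04,0.10,0.98,68.4,69.8
VHH1-v1.10,nb,nb,nb,nb,nb,85.2,64.4
VHH2-v1.0,2.9,2.3E+05,6.6E-04,0.17,1.00,98.2,89.1
VHH2-v1.1,2.9,2.7E+05,7.9E-04,0.18,1.00,104.7,89.5
VHH2-v1.2,2.1,3.5E+05,7.4E-04,0.15,1.00,120.2,89.5
VHH2-v1.3,10.0,9.3E+04,9.3E-04,0.13,1.00,43.1,97.3
VHH2-v1.4,nb,nb,nb,nb,nb,26.1,100.0
VHH2-v1.5,2.9,3.8E+05,1.1E-03,0.11,0.99,86.6,95.7
VHH2-v1.6,27.6,4.6E+04,1.3E-03,0.07,0.98,77.6,94.0
VHH2-v1.7,9.8,1.1E+05,1.1E-03,0.10,0.99,63.1,96.9
VHH2-v1.8,6.6,1.3E+05,8.4E-04,0.10,0.99,109.9,94.4
VHH2-v1.9,nb,nb,nb,nb,nb,37.5,98.1
VHH2-v1.10,nb,nb,nb,nb,nb,42.3,97.9
VHH2-v1.11,4.7,1.6E+05,7.4E-04,0.16,0.99,100.1,93.5
VHH2-v1.12,4.2,1.3E+05,5.5E-04,0.14,0.99,118.6,93.3
VHH2-v1.13,nb,nb,nb,nb,nb,98.6,95.8
VHH2-v1.14,nb,nb,nb,nb,nb,82.1,95.9
VHH2-v1.15,12.3,5.8E+04,7.2E-04,0.07,0.99,21.5,99.1
VHH2-v1.16,4.7,8.7E+04,4.1E-04,0.11,0.99,86.1,97.8
VHH2-v1.17,nb,nb,nb,nb,nb,18.0,100.0
VHH2-v1.18,nb,nb,nb,nb,nb,91.9,97.1
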