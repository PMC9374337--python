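construct,uniprot,name,n_cells,abundance,loneliness,mw_kda,tag_mw_kda,oligomeric_state,complex_mass_kda,d_mean,d_sd,heterologous
1,VUXFR,mEos3.2,30,,,0.0,25.7,1,25.7,11.4,1.6,False
3,P00934,ThrC,31,11109,0.350,47.1,25.7,1,72.8,7.8,1.1,False
8,90AC62,GrxC,26,6170,89.400,9.1,25.7,1,34.8,10.3,1.3,False
9,P05793,IlvC,22,29065,36.200,54.0,25.7,4,318.9,2.9,0.5,False
11,P08997,AceB,28,8308,10.400,60.2,25.7,1,85.9,6.9,1.1,False
12,P0A6A8,AcpP,38,28863,0.120,8.6,25.7,1,34.3,9.6,1.6,False
13,P0ACC3,ErpA,22,3460,0.100,12.1,25.7,2,75.5,7.8,1.1,False
15,P0AA25,TrxA,33,18242,0.025,11.8,25.7,1,37.5,8.7,1.8,False
16,P07813,LeuS,20,1505,0.005,97.2,25.7,1,122.9,4.1,0.8,False
19,P08200,Icd,23,24591,1.020,45.7,25.7,2,142.8,5.0,0.9,False
15_hvo,A0A558GCJ2,TrxA2_hvo,23,,,12.1,25.7,1,37.8,8.1,1.2,True
15_lla,A0A089XQE8,TrxA_lla,24,,,11.7,25.7,1,37.4,6.6,1.3,True
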