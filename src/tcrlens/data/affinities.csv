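label,system,tcr,pdb,kd_nM,on_rate,off_rate
1G4_wt,1G4-A2-SLL,wild-type,2BNR,13300,12000,0.049
1G4_c5c1,1G4-A2-SLL,1G4_c5c1,2PYE,81.6,17800,0.0015
1G4_c49c50,1G4-A2-SLL,1G4_c49c50,2F53,1,180000,0.00024
1G4_c58c61,1G4-A2-SLL,1G4_c58c61,2P5E,0.048,570000,0.00003
DMF5_wt,DMF5-A2-ELA,wild-type,3QDG,29000,,
DMF5_YW,DMF5-A2-ELA,DMF5_YW,4L3E,24,,
MEL5_wt_ELA,MEL5-A2-ELA,wild-type,3HG1,18000,,
MEL5_a24b17_ELA,MEL5-A2-ELA,MEL5_a24b17,4JFF,0.61,79000,0.0001
MEL5_wt_EAA,MEL5-A2-EAA,wild-type,4QOK,8400,,
MEL5_a24b17_EAA,MEL5-A2-EAA,MEL5_a24b17,6TMO,0.75,280000,0.00021
MEL5_wt_AAG,MEL5-A2-AAG,wild-type,6EQA,14200,,
MEL5_a24b17_AAG,MEL5-A2-AAG,MEL5_a24b17,6EQB,26.2,74000,0.0019
A6_wt,A6-A2-LLF,wild-type,1AO7,3200,23000,0.074
A6_c134,A6-A2-LLF,A6_c134,4FTV,4,45000,0.00018
ILA1_wt,ILA1-A2-ILA,wild-type,5MEN,34000,3490,0.13
ILA1_a1b1,ILA1-A2-ILA,ILA1_a1b1,4MNQ,2,80000,0.00016
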