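species,wing_edf,wing_beta,wing_se,wing_df,wing_t,wing_p,colour_edf,colour_beta,colour_se,colour_df,colour_t,colour_p
Buff-rumped thornbill,1,-0.00613,0.006,107,-0.29,0.771,2.86,-0.00154,0.004,103,-0.35,0.726
Yellow thornbill,1,-0.00037,0.005,96,-0.08,0.940,1,-0.00172,0.005,94,-0.35,0.725
Yellow-rumped thornbill,0.99,-0.00212,0.004,130,-0.49,0.626,1,0.00772,0.005,126,1.57,0.119
Weebill,1,0.00282,0.003,153,0.97,0.336,1,-0.01089,0.003,145,-3.52,0.001
White-throated gerygone,3.81,-0.03041,0.005,75,-5.67,0.001,4.41,-0.00732,0.005,71,-1.39,0.168
Spotted pardalote,1,-0.00423,0.004,137,-1.11,0.270,1,0.01844,0.009,130,2.06,0.042
Yellow-tinted honeyeater,1,-0.00225,0.011,59,-0.21,0.833,1,-0.03524,0.010,57,-3.66,0.001
White-plumed honeyeater,1.69,-0.01949,0.007,133,-2.89,0.004,1.53,-0.02224,0.004,130,-5.18,0.001
Singing honeyeater,1.8,0.00478,0.007,110,0.64,0.521,1,0.00519,0.005,103,1.02,0.308
Yellow-throated miner,1,-0.01499,0.011,130,-1.31,0.193,1,0.00315,0.004,128,0.86,0.392
Yellow-tufted honeyeater,1,-0.00728,0.011,124,-0.63,0.527,1.98,0.00964,0.008,121,1.28,0.204
Lewin's honeyeater,1,0.00167,0.008,92,0.21,0.831,1,-0.00489,0.004,88,-1.26,0.211
New Holland honeyeater,1,-0.00728,0.008,134,-0.86,0.392,1,0.01083,0.005,127,1.98,0.050
White-naped honeyeater,2.22,-0.01110,0.008,103,-1.39,0.169,1,0.01530,0.005,98,2.91,0.004
White-eared honeyeater,1,-0.02009,0.007,113,-2.75,0.007,2.89,0.00024,0.005,108,0.05,0.962
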