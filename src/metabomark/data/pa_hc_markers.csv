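metabolite,pathway,ratio_pa_hc,p_value,q_value,auc,vip_total,vip_ratio
Ornithine isomer,unknown,0.15,7.82e-3,2.67e-2,0.84,1.85,4.28
C20 sphingenine,Sphingoid bases,6.54,2.03e-2,3.92e-2,0.75,1.81,2.82
Tyrosine,Tyrosine metabolism,0.37,2.64e-2,4.98e-2,0.83,1.63,1.84
SM(d18:1/24:1),Sphingomyelins,14.52,3.28e-3,2.67e-2,0.87,1.26,1.08
Eicosatrienoic acid,Unsaturated fatty acid biosynthesis,16.18,3.48e-4,4.67e-3,0.88,1.07,1.53
Docosatetraenoic acid,Unsaturated fatty acid biosynthesis,20.32,9.11e-4,6.15e-3,0.92,1.02,1.01
Arachidonic acid,Fatty acids and conjugates,18.05,4.79e-3,1.94e-2,0.88,0.99,2.91
Octadecenoylsphingenine,Ceramides,11.88,5.31e-5,1.08e-3,0.94,0.89,1.21
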